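"""Shared fixtures: template geometry, rendered frames, and one segmented
two-speaker session reused by the slower integration tests."""

from __future__ import annotations

import pytest

from vtmod import fpca, segmentation, synthetic
from vtmod.core import ImageSeries


@pytest.fixture(scope="session")
def template_outline():
    return synthetic.make_vocal_tract_contour()


@pytest.fixture(scope="session")
def reference_frame():
    return synthetic.reference_frame()


@pytest.fixture(scope="session")
def static_mask():
    return synthetic.static_structure_mask()


@pytest.fixture(scope="session")
def small_cohort():
    """Two speakers with weak vs strong larynx modulation."""
    return [
        synthetic.SpeakerProfile(
            "weak", sex="female", modulation_amplitude=0.2, frame_noise_sd=5.0
        ),
        synthetic.SpeakerProfile(
            "strong", sex="female", modulation_amplitude=0.8, frame_noise_sd=5.0
        ),
    ]


@pytest.fixture(scope="session")
def cohort_session(small_cohort):
    """Simulated + fully segmented session for the two-speaker cohort."""
    design = synthetic.TrialDesign.rtmri(n_trials_per_condition=1, frames_per_trial=2)
    frames, gts = [], []
    start = 0
    for k, prof in enumerate(small_cohort):
        s, gt = synthetic.simulate_speaker_session(
            prof, design, seed=100 + k, frame_index_start=start
        )
        start += len(s)
        frames.extend(s.frames)
        gts.append(gt)
    series = ImageSeries(frames)
    gt = synthetic.GroundTruth.concat(gts)
    result = segmentation.segment_series(
        series, synthetic.reference_frame(), synthetic.static_structure_mask()
    )
    return series, gt, result


@pytest.fixture(scope="session")
def session_curves(cohort_session):
    series, gt, result = cohort_session
    labels = gt.frames.set_index("frame_index")
    curves = []
    for o in result.outlines:
        row = labels.loc[o.frame_index]
        curves.append(
            fpca.resample_contour(
                o,
                100,
                labels={
                    "frame_index": o.frame_index,
                    "speaker_id": row["speaker_id"],
                    "word": row["word"],
                    "vt_condition": row["vt_condition"],
                },
            )
        )
    return curves
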