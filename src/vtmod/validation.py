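"""Whole-pipeline validation benchmarks.

Each function regenerates its inputs from the synthetic module, runs the
relevant pipeline stage(s), and returns the measured quantity.  The test
suite asserts on these numbers and the acceptance script reports them;
problem sizes are chosen so the full battery runs in minutes on one CPU
(the methods note records the sizes used).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import acoustics, fpca, perception, segmentation, skill, synthetic
from .core import ImageSeries, RigidTransform


def design_counts() -> dict[str, int]:
    """Printed design sizes: audio-session trials, modified stimuli, and
    perception stimuli per sex (the latter on a complete 20-speaker cohort)."""
    audio_trials = len(acoustics.enumerate_trials("audio"))
    modified = 2 * sum(
        c.axis != "baseline" for c in acoustics.build_stimulus_grid("full")
    )
    profiles = synthetic.make_cohort(20, seed=7)
    takes = []
    for k, p in enumerate(profiles):
        t, _ = synthetic.simulate_acoustic_session(
            p, session="rtmri", n_takes=2, noise_cv=0.02, seed=700 + k
        )
        takes.extend(t)
    skills = pd.DataFrame(
        {
            "speaker_id": [p.speaker_id for p in profiles],
            "sex": [p.sex for p in profiles],
            "vt_skill": [p.modulation_amplitude for p in profiles],
        }
    )
    grouped = skill.rank_and_group(skills, n_per_group=5)
    stim = perception.assemble_stimulus_set(grouped, takes)
    per_sex = stim.groupby("voice_sex").size()
    return {
        "audio_trials": audio_trials,
        "modified_stimuli": modified,
        "stimuli_per_sex_female": int(per_sex["female"]),
        "stimuli_per_sex_male": int(per_sex["male"]),
    }


def extreme_upshift_modulation_st() -> float:
    """Semitone modulation of the grid's extreme upward target vs baseline."""
    base = acoustics.AcousticTake(
        "s", "bead", acoustics.ConditionLabel(), 0, 220.0, 500.0, 1500.0, 2500.0, 3500.0
    )
    up = acoustics.apply_grid_to_baseline(base, acoustics.ConditionLabel(4, 4))
    return float(acoustics.semitone_modulation(up.f1_hz, base.f1_hz))


def fpca_oracle_max_rel_err(n_curves: int = 200, n_points: int = 100, seed: int = 0) -> float:
    """Max relative eigenvalue deviation between the fPCA fit and a
    brute-force eigendecomposition of the explicit discrete covariance."""
    _, curves, _ = synthetic.sample_shape_dataset(n_curves, seed=seed, n_points=n_points)
    model = fpca.fit_fpca(curves, 5)
    X = np.stack([c.concat() for c in curves])
    brute = np.sort(np.linalg.eigvalsh(np.cov(X.T, bias=False)))[::-1][:5]
    return float(np.max(np.abs(model.eigenvalues - brute) / brute))


def planted_mode_recovery(n_curves: int = 500, seed: int = 0) -> tuple[float, float]:
    """(max |share error|, min |score-parameter correlation|) over the five
    planted deformation modes."""
    shares = np.asarray(synthetic.DEFAULT_VARIANCE_SHARES)
    z, curves, _ = synthetic.sample_shape_dataset(n_curves, seed=seed)
    model = fpca.fit_fpca(curves, 5)
    S = fpca.project_scores(model, curves).filter(like="fPC").to_numpy()
    R = np.corrcoef(S.T, z.T)[:5, 5:]
    match = np.abs(R).argmax(axis=1)
    if sorted(match) != [0, 1, 2, 3, 4]:
        return 1.0, 0.0
    share_err = float(np.abs(model.variance_proportions - shares[match]).max())
    min_r = float(np.abs(R).max(axis=1).min())
    return share_err, min_r


def segmentation_fidelity(
    n_frames: int = 100, noise_sd: float = 0.0, seed: int = 0
) -> dict[str, float]:
    """Mean Dice and mean Hausdorff (mm) of the full segmentation chain on
    one simulated speaker session of ``n_frames`` noiseless frames."""
    frames_per_trial = 2
    n_trials = max(n_frames // (10 * frames_per_trial), 1)
    prof = synthetic.SpeakerProfile(
        "bench", modulation_amplitude=0.6, frame_noise_sd=noise_sd
    )
    design = synthetic.TrialDesign.rtmri(
        n_trials_per_condition=n_trials, frames_per_trial=frames_per_trial
    )
    series, gt = synthetic.simulate_speaker_session(prof, design, seed=seed)
    result = segmentation.segment_series(
        series, synthetic.reference_frame(), synthetic.static_structure_mask()
    )
    dices, hds = [], []
    for k, f in enumerate(series):
        gt_air = synthetic.rasterize_air_mask(gt.outlines[f.frame_index])
        dices.append(segmentation.dice_coefficient(result.air_masks[k], gt_air))
        hds.append(
            segmentation.outline_hausdorff_mm(
                result.outlines[k], gt.outlines[f.frame_index]
            )
        )
    return {
        "n_frames": len(series),
        "dice_mean": float(np.mean(dices)),
        "hausdorff_mean_mm": float(np.mean(hds)),
    }


def planted_motion_recovery(seed: int = 0, n_motions: int = 5) -> dict[str, float]:
    """Worst-case rigid-registration error over planted head motions."""
    rng = np.random.default_rng(seed)
    outline = synthetic.make_vocal_tract_contour()
    reference = synthetic.reference_frame()
    static = synthetic.static_structure_mask()
    rot_errs, trans_errs = [], []
    for k in range(n_motions):
        motion = RigidTransform(
            float(rng.uniform(-5, 5)),
            (float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5))),
        )
        frame = synthetic.render_frame(
            outline, rigid=motion, noise_sd=5.0, seed=int(rng.integers(2**31 - 1))
        )
        est = segmentation.estimate_rigid_transform(frame, reference, static)
        truth = motion.inverse()
        rot_errs.append(abs(est.rotation_deg - truth.rotation_deg))
        trans_errs.append(
            float(
                np.max(np.abs(np.asarray(est.translation_mm) - truth.translation_mm))
            )
        )
    return {
        "rotation_err_max_deg": float(max(rot_errs)),
        "translation_err_max_mm": float(max(trans_errs)),
    }


def skill_recovery_spearman(
    n_speakers: int = 20, seed: int = 0
) -> tuple[float, int]:
    """Spearman rho between planted modulation amplitude and the vocal-tract
    skill score computed from segmented, fPCA-scored frames."""
    profiles = synthetic.make_cohort(n_speakers, seed=seed)
    design = synthetic.TrialDesign.rtmri(n_trials_per_condition=1, frames_per_trial=2)
    rng = np.random.default_rng(seed)
    frames, gts, start = [], [], 0
    for p in profiles:
        s, gt = synthetic.simulate_speaker_session(
            p, design, seed=int(rng.integers(2**31 - 1)), frame_index_start=start
        )
        start += len(s)
        frames.extend(s.frames)
        gts.append(gt)
    series = ImageSeries(frames)
    gt = synthetic.GroundTruth.concat(gts)
    result = segmentation.segment_series(
        series, synthetic.reference_frame(), synthetic.static_structure_mask()
    )
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
                    "vt_condition": row["vt_condition"],
                },
            )
        )
    model = fpca.fit_fpca(curves, 5)
    refs = synthetic.canonical_deformations(100)
    k = fpca.identify_component(model, refs["shorten"])
    model = fpca.orient_components(model, {k: refs["shorten"]})
    scores = fpca.project_scores(model, curves)
    vt = skill.vt_skill_score(scores, component=k + 1)
    amp = {p.speaker_id: p.modulation_amplitude for p in profiles}
    vt["amp"] = vt["speaker_id"].map(amp)
    rho = stats.spearmanr(vt["amp"], vt["vt_skill"]).statistic
    return float(rho), n_speakers


def avtl_recovery_max_err_pct(lengths_cm=None) -> float:
    """Worst relative aVTL error (percent) on noiseless tube formants."""
    lengths_cm = lengths_cm if lengths_cm is not None else np.linspace(12.0, 20.0, 17)
    errs = []
    for L in lengths_cm:
        take = synthetic.simulate_formants(float(L), coloring=False, noise_cv=0.0)
        errs.append(abs(acoustics.compute_avtl(take) - L) / L)
    return float(100.0 * max(errs))


def correlation_calibration(
    n_rep: int = 500, n: int = 52, r2: float = 0.6, seed: int = 0
) -> float:
    """Mean fitted R^2 over replicate cohorts planted at population R^2."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_rep, n))
    eps = rng.standard_normal((n_rep, n))
    y = np.sqrt(r2) * x + np.sqrt(1 - r2) * eps
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    return float(np.mean(r**2))


def permutation_type_i_rate(
    n_rep: int = 10_000, n: int = 52, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical rejection rate of the one-sided correlation test under the
    null (independently permuted pairings)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_rep, n))
    y = rng.standard_normal((n_rep, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    df = n - 2
    t = r * np.sqrt(df / (1 - r**2))
    p = stats.t.sf(t, df)
    return float(np.mean(p < alpha))


def _cohort_trials(effects, n_listeners_per_sex, seed, n_speakers=20):
    profiles = synthetic.make_cohort(n_speakers, seed=seed)
    takes = []
    rng = np.random.default_rng(seed)
    for p in profiles:
        t, _ = synthetic.simulate_acoustic_session(
            p, session="rtmri", n_takes=2, noise_cv=0.02,
            seed=int(rng.integers(2**31 - 1)),
        )
        takes.extend(t)
    skills = pd.DataFrame(
        {
            "speaker_id": [p.speaker_id for p in profiles],
            "sex": [p.sex for p in profiles],
            "vt_skill": [p.modulation_amplitude for p in profiles],
        }
    )
    grouped = skill.rank_and_group(skills, n_per_group=5)
    stim = perception.assemble_stimulus_set(grouped, takes)
    return synthetic.simulate_perception_ratings(
        stim, effects, n_listeners=2 * n_listeners_per_sex,
        seed=int(rng.integers(2**31 - 1)),
    )


def perception_recovery(
    n_listeners_per_sex: int = 80, n_rep: int = 20, seed: int = 0
) -> dict[str, float]:
    """Bias of the estimated small/large-vs-baseline height contrasts
    relative to the planted generative effects, plus the zero-noise
    exactness of the fixed-effect fit."""
    effects = synthetic.RatingEffects()
    planted = {}
    for sex in ("female", "male"):
        for grp in ("good", "poor"):
            for vt in ("small", "large"):
                planted[(sex, grp, f"{vt} - baseline")] = effects.cell_mean(
                    sex, grp, vt, 0.0
                ) - effects.cell_mean(sex, grp, "baseline", 0.0)
    rng = np.random.default_rng(seed)
    sums: dict = {k: 0.0 for k in planted}
    for rep in range(n_rep):
        trials = _cohort_trials(
            effects, n_listeners_per_sex, int(rng.integers(2**31 - 1))
        )
        design = perception.build_height_design(trials)
        fit = perception.fit_height_model(design, backend="ols")
        got = fit.contrasts.set_index(["voice_sex", "skill_group", "contrast"])
        for k in planted:
            sums[k] += float(got.loc[k, "estimate_cm"])
    biases = [
        abs(sums[k] / n_rep - planted[k]) / abs(planted[k]) for k in planted
    ]
    # zero-noise, zero-random-effect case: exact interpolation
    null_eff = synthetic.RatingEffects()
    for attr in (
        "listener_sd_cm", "speaker_intercept_sd_cm", "speaker_f0_slope_sd",
        "speaker_vt_slope_sd_cm", "residual_sd_cm",
    ):
        setattr(null_eff, attr, 0.0)
    trials = _cohort_trials(null_eff, 4, seed + 1)
    design = perception.build_height_design(trials)
    fit = perception.fit_height_model(design, backend="ols")
    got = fit.contrasts.set_index(["voice_sex", "skill_group", "contrast"])
    exact_err = max(
        abs(float(got.loc[k, "estimate_cm"]) - planted[k]) for k in planted
    )
    return {
        "max_bias_fraction": float(max(biases)),
        "zero_noise_max_err_cm": float(exact_err),
        "n_listeners_per_sex": n_listeners_per_sex,
        "n_rep": n_rep,
    }
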