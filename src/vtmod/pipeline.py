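"""End-to-end pipeline orchestration with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acoustics, fpca, io, perception, segmentation, skill, synthetic


@dataclass
class PipelineConfig:
    """Parameters of one full synthetic-cohort run."""

    out_dir: str = "vtmod_run"
    seed: int = 0
    n_speakers: int = 6
    n_listeners: int = 2
    n_trials_per_condition: int = 1
    frames_per_trial: int = 2
    frame_noise_sd: float = 5.0
    variance_quantile: float = segmentation.DEFAULT_VARIANCE_QUANTILE
    n_points: int = 100
    n_components: int = 5
    n_per_group: int = 1
    n_takes: int = 3
    acoustic_noise_cv: float = 0.02
    avtl_c_cm_s: float = acoustics.SPEED_OF_SOUND_CM_S
    session: str = "rtmri"
    backend: str = "ols"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.n_speakers < 2 * self.n_per_group * 2:
            raise ValueError(
                "n_speakers too small for the requested grouping (need "
                f">= {4 * self.n_per_group})"
            )
        if self.session not in ("rtmri", "full"):
            raise ValueError("session must be 'rtmri' or 'full'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    failed_stage: str | None = None

    def record(self, name: str, seconds: float, outputs: dict[str, str]) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(seconds, 3), "outputs": outputs}
        )

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2))
        tmp.replace(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """simulate -> segment -> fpca -> acoustics -> scores -> perception.

    Every stage writes its outputs (delimited text / NIfTI) under the
    configured directory before the next stage starts; the manifest
    records per-stage wall time and output checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    rng = np.random.default_rng(config.seed)

    def finish_stage(name: str, t0: float, paths: list[Path]) -> None:
        manifest.record(name, time.time() - t0, {p.name: _sha256(p) for p in paths})
        manifest.write(out / "manifest.json")

    try:
        # --- simulate ---------------------------------------------------
        t0 = time.time()
        profiles = synthetic.make_cohort(config.n_speakers, seed=config.seed)
        for p in profiles:
            p.frame_noise_sd = config.frame_noise_sd
        design = synthetic.TrialDesign.rtmri(
            n_trials_per_condition=config.n_trials_per_condition,
            frames_per_trial=config.frames_per_trial,
        )
        all_series = []
        gts = []
        start = 0
        for p in profiles:
            s, gt = synthetic.simulate_speaker_session(
                p, design, seed=int(rng.integers(2**31 - 1)), frame_index_start=start
            )
            start += len(s)
            all_series.append(s)
            gts.append(gt)
        series = synthetic.ImageSeries([f for s in all_series for f in s])
        gt = synthetic.GroundTruth.concat(gts)
        takes = []
        for p in profiles:
            t, _ = synthetic.simulate_acoustic_session(
                p,
                session=config.session,
                n_takes=config.n_takes,
                noise_cv=config.acoustic_noise_cv,
                seed=int(rng.integers(2**31 - 1)),
            )
            takes.extend(t)
        io.write_image_series(series, out / "series.nii.gz", out / "labels.tsv")
        io.write_table(io.takes_to_table(takes), out / "takes.tsv")
        io.write_table(gt.frames, out / "ground_truth_frames.tsv")
        finish_stage(
            "simulate", t0, [out / "labels.tsv", out / "takes.tsv", out / "ground_truth_frames.tsv"]
        )

        # --- segment ----------------------------------------------------
        t0 = time.time()
        reference = synthetic.reference_frame()
        static = synthetic.static_structure_mask()
        result = segmentation.segment_series(
            series, reference, static, variance_quantile=config.variance_quantile
        )
        io.write_outlines(result.outlines, out / "outlines.tsv")
        finish_stage("segment", t0, [out / "outlines.tsv"])

        # --- fpca -------------------------------------------------------
        t0 = time.time()
        labels = gt.frames.set_index("frame_index")
        curves = []
        for o in result.outlines:
            row = labels.loc[o.frame_index]
            curves.append(
                fpca.resample_contour(
                    o,
                    config.n_points,
                    labels={
                        "frame_index": o.frame_index,
                        "speaker_id": row["speaker_id"],
                        "word": row["word"],
                        "vt_condition": row["vt_condition"],
                    },
                )
            )
        model = fpca.fit_fpca(curves, config.n_components)
        refs = synthetic.canonical_deformations(config.n_points)
        length_k = fpca.identify_component(model, refs["shorten"])
        tongue_k = fpca.identify_component(model, refs["front"])
        model = fpca.orient_components(
            model, {tongue_k: refs["front"], length_k: refs["shorten"]}
        )
        scores = fpca.project_scores(model, curves)
        io.save_fpca_model(model, out / "fpca_model")
        io.write_table(scores, out / "fpc_scores.tsv")
        io.write_table(fpca.variance_explained(model), out / "variance_explained.tsv")
        finish_stage("fpca", t0, [out / "fpc_scores.tsv", out / "variance_explained.tsv"])

        # --- acoustics --------------------------------------------------
        t0 = time.time()
        modulations = acoustics.modulation_table(takes)
        io.write_table(modulations, out / "modulations.tsv")
        finish_stage("acoustics", t0, [out / "modulations.tsv"])

        # --- scores -----------------------------------------------------
        t0 = time.time()
        vt = skill.vt_skill_score(scores, component=length_k + 1)
        meta = gt.frames.groupby("speaker_id").first().reset_index()
        sex_map = {p.speaker_id: p.sex for p in profiles}
        vt["sex"] = vt["speaker_id"].map(sex_map)
        grouped = skill.rank_and_group(vt, n_per_group=config.n_per_group)
        assoc_rows = []
        for measure in skill.MEASURES:
            ac = skill.acoustic_skill_score(modulations, measure)
            merged = grouped.merge(ac, on="speaker_id")
            res = skill.skill_acoustic_association(
                merged["vt_skill"], merged["acoustic_skill_st"], measure=measure
            )
            assoc_rows.append(
                {
                    "measure": measure,
                    "r": res.r,
                    "r_squared": res.r_squared,
                    "t": res.t_statistic,
                    "df": res.df,
                    "p_one_sided": res.p_value,
                }
            )
        io.write_table(grouped, out / "skills.tsv")
        io.write_table(pd.DataFrame(assoc_rows), out / "associations.tsv")
        finish_stage("scores", t0, [out / "skills.tsv", out / "associations.tsv"])

        # --- perception -------------------------------------------------
        t0 = time.time()
        stimuli = perception.assemble_stimulus_set(grouped, takes)
        trials = synthetic.simulate_perception_ratings(
            stimuli,
            synthetic.RatingEffects(),
            n_listeners=config.n_listeners,
            seed=int(rng.integers(2**31 - 1)),
        )
        design_m = perception.build_height_design(trials)
        fit = perception.fit_height_model(design_m, backend=config.backend)
        io.write_table(trials, out / "perception_trials.tsv")
        io.write_table(fit.coefficients, out / "height_coefficients.tsv")
        io.write_table(fit.contrasts, out / "height_contrasts.tsv")
        finish_stage(
            "perception",
            t0,
            [out / "perception_trials.tsv", out / "height_coefficients.tsv"],
        )
    except Exception:
        manifest.failed_stage = (
            ["simulate", "segment", "fpca", "acoustics", "scores", "perception"][
                len(manifest.stages)
            ]
        )
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
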