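"""File formats: NIfTI image series, delimited-text tables, model archives.

Image series are stored as a standard neuroimaging volume (frames stacked
on the third axis, pixel size in the header zooms) with a sidecar
tab-separated label table.  All tabular outputs are tab-separated text
with documented headers; fPCA models are directories of delimited-text
grids plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .acoustics import AcousticTake, ConditionLabel
from .core import ImageFrame, ImageSeries, PixelMask, VTOutline
from .fpca import FPCAModel, ParametrizedCurve

LABEL_COLUMNS = ["frame_index", "speaker_id", "word", "vt_condition"]


# ---------------------------------------------------------------------------
# image series


def write_image_series(series: ImageSeries, nii_path, labels_path) -> None:
    data = np.stack([f.intensities for f in series], axis=-1)
    px = series.pixel_size_mm
    img = nib.Nifti1Image(data, affine=np.diag([px, px, 1.0, 1.0]))
    img.header.set_zooms((px, px, 1.0))
    nib.save(img, str(nii_path))
    labels = pd.DataFrame(
        [
            {
                "frame_index": f.frame_index,
                "speaker_id": f.speaker_id,
                "word": f.word,
                "vt_condition": f.vt_condition,
            }
            for f in series
        ]
    )
    labels.to_csv(labels_path, sep="\t", index=False)


def read_image_series(nii_path, labels_path) -> ImageSeries:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    px = float(img.header.get_zooms()[0])
    labels = pd.read_csv(labels_path, sep="\t", keep_default_na=False)
    frames = []
    for k in range(data.shape[-1]):
        row = labels.iloc[k]
        frames.append(
            ImageFrame(
                data[..., k],
                px,
                frame_index=int(row["frame_index"]),
                speaker_id=str(row["speaker_id"]),
                word=str(row["word"]),
                vt_condition=str(row["vt_condition"]),
            )
        )
    return ImageSeries(frames)


def write_mask(mask: PixelMask, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_mask(path, kind: str = "static_structures") -> PixelMask:
    img = nib.load(str(path))
    return PixelMask(np.asarray(img.dataobj) > 0, kind=kind)


# ---------------------------------------------------------------------------
# contours


def outlines_to_table(outlines: Sequence[VTOutline]) -> pd.DataFrame:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.points):
            rows.append(
                {
                    "frame_index": o.frame_index,
                    "point_index": i,
                    "x_mm": x,
                    "y_mm": y,
                    "closed": int(o.closed),
                }
            )
    return pd.DataFrame(rows)


def table_to_outlines(df: pd.DataFrame) -> list[VTOutline]:
    outlines = []
    for fi, g in df.groupby("frame_index", sort=True):
        g = g.sort_values("point_index")
        outlines.append(
            VTOutline(
                g[["x_mm", "y_mm"]].to_numpy(),
                closed=bool(g["closed"].iloc[0]),
                frame_index=int(fi),
            )
        )
    return outlines


def write_outlines(outlines: Sequence[VTOutline], path) -> None:
    outlines_to_table(outlines).to_csv(path, sep="\t", index=False)


def read_outlines(path) -> list[VTOutline]:
    return table_to_outlines(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# acoustic takes


def takes_to_table(takes: Sequence[AcousticTake]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "speaker_id": t.speaker_id,
                "word": t.word,
                "f0_shift_st": t.condition.f0_shift_st,
                "vtl_shift_st": t.condition.vtl_shift_st,
                "take_index": t.take_index,
                "f0_hz": t.f0_hz,
                "f1_hz": t.f1_hz,
                "f2_hz": t.f2_hz,
                "f3_hz": t.f3_hz,
                "f4_hz": t.f4_hz,
            }
            for t in takes
        ]
    )


def table_to_takes(df: pd.DataFrame) -> list[AcousticTake]:
    return [
        AcousticTake(
            speaker_id=str(r.speaker_id),
            word=str(r.word),
            condition=ConditionLabel(int(r.f0_shift_st), int(r.vtl_shift_st)),
            take_index=int(r.take_index),
            f0_hz=float(r.f0_hz),
            f1_hz=float(r.f1_hz),
            f2_hz=float(r.f2_hz),
            f3_hz=float(r.f3_hz),
            f4_hz=float(r.f4_hz),
        )
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


# ---------------------------------------------------------------------------
# fPCA model archive


def save_fpca_model(model: FPCAModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n = model.n_points
    pd.DataFrame(
        {"point_index": np.arange(n), "x_mm": model.mean_curve.points[:, 0], "y_mm": model.mean_curve.points[:, 1]}
    ).to_csv(d / "mean_curve.tsv", sep="\t", index=False)
    rows = []
    for k in range(model.n_components):
        for i in range(n):
            rows.append(
                {
                    "component": k + 1,
                    "point_index": i,
                    "x": model.eigenfunctions[k, i, 0],
                    "y": model.eigenfunctions[k, i, 1],
                }
            )
    pd.DataFrame(rows).to_csv(d / "eigenfunctions.tsv", sep="\t", index=False)
    manifest = {
        "n_points": n,
        "n_components": model.n_components,
        "closed": model.mean_curve.closed,
        "eigenvalues_mm2": [float(v) for v in model.eigenvalues],
        "total_variance_mm2": model.total_variance,
        "sign_convention": [list(map(str, c)) for c in model.sign_convention],
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_fpca_model(directory) -> FPCAModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    mean = pd.read_csv(d / "mean_curve.tsv", sep="\t").sort_values("point_index")
    eig = pd.read_csv(d / "eigenfunctions.tsv", sep="\t")
    n = manifest["n_points"]
    K = manifest["n_components"]
    funcs = np.zeros((K, n, 2))
    for k in range(K):
        g = eig[eig["component"] == k + 1].sort_values("point_index")
        funcs[k, :, 0] = g["x"].to_numpy()
        funcs[k, :, 1] = g["y"].to_numpy()
    return FPCAModel(
        mean_curve=ParametrizedCurve(
            mean[["x_mm", "y_mm"]].to_numpy(), closed=bool(manifest["closed"])
        ),
        eigenfunctions=funcs,
        eigenvalues=np.asarray(manifest["eigenvalues_mm2"], dtype=float),
        total_variance=float(manifest["total_variance_mm2"]),
        sign_convention=[tuple(c) for c in manifest.get("sign_convention", [])],
    )


# ---------------------------------------------------------------------------
# table validation

TABLE_SCHEMAS = {
    "acoustic_takes": {
        "columns": [
            "speaker_id", "word", "f0_shift_st", "vtl_shift_st", "take_index",
            "f0_hz", "f1_hz", "f2_hz", "f3_hz", "f4_hz",
        ],
    },
    "contours": {"columns": ["frame_index", "point_index", "x_mm", "y_mm", "closed"]},
    "fpc_scores": {"columns": ["frame_index", "speaker_id", "word", "vt_condition"]},
    "modulations": {
        "columns": [
            "speaker_id", "word", "f0_shift_st", "vtl_shift_st", "vt_condition",
            "take_index", "measure", "modulation_st",
        ],
    },
    "skills": {"columns": ["speaker_id", "vt_skill"]},
    "perception_trials": {
        "columns": [
            "listener_id", "voice_sex", "speaker_id", "skill_group",
            "vt_condition", "f0_modulation_st", "rating_cm",
        ],
    },
}


def validate_tables(path, schema_name: str) -> list[str]:
    """Header, type and invariant checks for a delimited table.

    Returns a list of human-readable violations (empty when valid).
    """
    if schema_name not in TABLE_SCHEMAS:
        raise KeyError(
            f"unknown schema {schema_name!r}; valid: {sorted(TABLE_SCHEMAS)}"
        )
    try:
        df = read_table(path)
    except OSError as e:
        raise OSError(f"cannot read {path}: {e}") from e
    schema = TABLE_SCHEMAS[schema_name]
    report: list[str] = []
    for col in schema["columns"]:
        if col not in df.columns:
            report.append(f"missing column {col!r}")
    if report:
        return report
    if schema_name == "acoustic_takes":
        for r in df.itertuples():
            freqs = [r.f0_hz, r.f1_hz, r.f2_hz, r.f3_hz, r.f4_hz]
            if any(f <= 0 for f in freqs):
                report.append(f"row {r.Index}: non-positive frequency")
            if not (r.f1_hz < r.f2_hz < r.f3_hz < r.f4_hz):
                report.append(f"row {r.Index}: formants not strictly increasing")
    elif schema_name == "perception_trials":
        from .perception import SLIDER_RANGE_CM

        for r in df.itertuples():
            lo, hi = SLIDER_RANGE_CM.get(r.voice_sex, (None, None))
            if lo is None:
                report.append(f"row {r.Index}: unknown voice_sex {r.voice_sex!r}")
            elif not lo <= r.rating_cm <= hi:
                report.append(
                    f"row {r.Index}: rating {r.rating_cm} outside {r.voice_sex} range"
                )
    elif schema_name == "contours":
        for fi, g in df.groupby("frame_index"):
            if len(g) < 20:
                report.append(f"frame {fi}: outline has fewer than 20 points")
    return report
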