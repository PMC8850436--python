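"""Perceived-height experiment: stimulus assembly, slider mapping, and the
mixed model relating height judgements to voice modulation.

Listeners judge speaker height on a slider spanning the 1st-99th height
percentile of the voice's sex (145-180 cm for female voices, 155-190 cm
for male).  Stimuli are representative tokens from the 5 best and 5 worst
vocal-tract modulators of each sex, in the baseline and the four extreme
(+-4 st) conditions.  Ratings are modelled with fixed effects of skill
group x vocal-tract condition x f0 modulation x voice sex, a random
listener intercept, and random speaker intercepts and slopes.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import patsy

from .acoustics import AcousticTake, select_representative_token

SLIDER_RANGE_CM = {"female": (145.0, 180.0), "male": (155.0, 190.0)}

FIXED_FORMULA = (
    "rating_cm ~ C(skill_group, Treatment('poor'))"
    " * C(vt_condition, Treatment('baseline'))"
    " * f0_modulation_st"
    " * C(voice_sex, Treatment('female'))"
)


def percentile_to_cm(percentile: float, sex: str) -> float:
    """Linear slider map: percentile 1 -> lower anchor, 99 -> upper anchor."""
    if not 1.0 <= percentile <= 99.0:
        raise ValueError("percentile must be between 1 and 99")
    lo, hi = SLIDER_RANGE_CM[sex]
    return lo + (percentile - 1.0) / 98.0 * (hi - lo)


def cm_to_percentile(cm: float, sex: str) -> float:
    lo, hi = SLIDER_RANGE_CM[sex]
    if not lo <= cm <= hi:
        raise ValueError(f"height {cm} outside the {sex} slider range")
    return 1.0 + (cm - lo) / (hi - lo) * 98.0


def assemble_stimulus_set(
    grouped_skills: pd.DataFrame, takes: Sequence[AcousticTake]
) -> pd.DataFrame:
    """One representative token per (speaker, word, condition) cell.

    Uses the good/poor speakers from the ranked skill table and the five
    rtMRI conditions x 2 words; with 5 + 5 speakers per sex this yields
    100 stimuli per sex.  Missing cells raise an error naming them.
    """
    chosen = grouped_skills[grouped_skills["group"].isin(["good", "poor"])]
    by_cell: dict[tuple, list[AcousticTake]] = {}
    for t in takes:
        key = (t.speaker_id, t.word, t.condition.f0_shift_st, t.condition.vtl_shift_st)
        by_cell.setdefault(key, []).append(t)
    conditions = [(0, 0), (4, 4), (-4, -4), (4, -4), (-4, 4)]
    rows = []
    missing = []
    for spk_row in chosen.itertuples():
        for word in ("bead", "bard"):
            for f0s, vtls in conditions:
                cell = by_cell.get((spk_row.speaker_id, word, f0s, vtls))
                if not cell:
                    missing.append((spk_row.speaker_id, word, f"f0{f0s:+d}_vtl{vtls:+d}"))
                    continue
                tok = select_representative_token(cell)
                rows.append(
                    {
                        "speaker_id": tok.speaker_id,
                        "voice_sex": spk_row.sex,
                        "skill_group": spk_row.group,
                        "word": tok.word,
                        "vt_condition": tok.condition.vt_condition,
                        "f0_modulation_st": float(tok.condition.f0_shift_st),
                        "take_index": tok.take_index,
                        "f0_hz": tok.f0_hz,
                        "f1_hz": tok.f1_hz,
                        "f2_hz": tok.f2_hz,
                    }
                )
    if missing:
        raise ValueError(f"missing stimulus cells: {missing}")
    return pd.DataFrame(rows)


@dataclass
class HeightDesign:
    """Fixed/random design of the perceived-height model."""

    trials: pd.DataFrame
    fixed_formula: str
    X: np.ndarray
    column_names: list[str]
    dropped_columns: list[str] = field(default_factory=list)
    design_info: object | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def build_height_design(
    trials: pd.DataFrame, fixed_formula: str = FIXED_FORMULA
) -> HeightDesign:
    """Construct the fixed-effect design matrix with treatment coding
    (baseline condition, poor group and female voices as references).

    On the five stimulus conditions actually used, f0 modulation is zero
    everywhere except in modulated vt conditions, so the full interaction
    design is rank-deficient; aliased columns are detected by pivoted QR
    and dropped, and their names recorded.
    """
    for colname in ("listener_id", "speaker_id"):
        if trials[colname].nunique() < 2:
            raise ValueError(f"need at least 2 levels of {colname}")
    for f in ("skill_group", "vt_condition", "voice_sex"):
        if trials[f].nunique() < 1:
            raise ValueError(f"factor {f} has no levels")
    y, X = patsy.dmatrices(fixed_formula, trials, return_type="dataframe")
    names = list(X.columns)
    Xv = X.to_numpy()
    # pivoted QR rank detection
    q, r, piv = _qr_pivot(Xv)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * abs(r[0, 0])))
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    return HeightDesign(
        trials=trials.reset_index(drop=True),
        fixed_formula=fixed_formula,
        X=Xv[:, keep],
        column_names=[names[i] for i in keep],
        dropped_columns=dropped,
        design_info=X.design_info,
    )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


@dataclass
class HeightFit:
    """Coefficients and derived contrasts of a fitted height model."""

    coefficients: pd.DataFrame  # term, estimate, se
    contrasts: pd.DataFrame
    backend: str
    converged: bool
    random_effects: pd.DataFrame | None = None

    def coef(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])


_R_TEMPLATE = """
suppressMessages(library(lme4))
d <- read.csv("{data}", check.names = FALSE)
xcols <- grep("^x[0-9]+$", names(d), value = TRUE)
form <- as.formula(paste(
  "rating_cm ~ 0 +", paste(xcols, collapse = " + "),
  "+ (1 | listener_id) + (1 + f0_modulation_st + vt_condition | speaker_id)"))
fit <- lmer(form, data = d, REML = TRUE,
            control = lmerControl(check.conv.singular = "ignore"))
fe <- fixef(fit)
se <- sqrt(diag(as.matrix(vcov(fit))))
out <- data.frame(term = names(fe), estimate = as.numeric(fe), se = as.numeric(se))
write.csv(out, "{out}", row.names = FALSE)
"""


def fit_height_model(design: HeightDesign, backend: str = "auto") -> HeightFit:
    """Fit the perceived-height model.

    backend="lme4" delegates the restricted-maximum-likelihood fit of the
    crossed-random-effects model (listener intercepts; speaker intercepts
    plus f0 and vt-condition slopes) to R's lme4 through a subprocess.
    backend="ols" fits the fixed effects only; on balanced designs its
    point estimates coincide with the mixed-model ones and it is the
    fast choice for simulation studies.  "auto" tries lme4 and falls
    back to OLS.
    """
    if backend == "auto":
        try:
            return fit_height_model(design, "lme4")
        except (OSError, RuntimeError):
            return fit_height_model(design, "ols")
    if backend == "ols":
        import statsmodels.api as sm

        model = sm.OLS(design.trials["rating_cm"].to_numpy(), design.X)
        res = model.fit()
        coefs = pd.DataFrame(
            {"term": design.column_names, "estimate": res.params, "se": res.bse}
        )
        fit = HeightFit(
            coefficients=coefs,
            contrasts=pd.DataFrame(),
            backend="ols",
            converged=True,
        )
    elif backend == "lme4":
        with tempfile.TemporaryDirectory() as td:
            data = design.trials[
                ["rating_cm", "listener_id", "speaker_id", "f0_modulation_st", "vt_condition"]
            ].copy()
            for j in range(design.X.shape[1]):
                data[f"x{j}"] = design.X[:, j]
            data_path = Path(td) / "trials.csv"
            out_path = Path(td) / "fixef.csv"
            data.to_csv(data_path, index=False)
            script = _R_TEMPLATE.format(data=data_path, out=out_path)
            script_path = Path(td) / "fit.R"
            script_path.write_text(script)
            proc = subprocess.run(
                ["Rscript", "--vanilla", str(script_path)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0 or not out_path.exists():
                raise RuntimeError(
                    f"lme4 fit failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
                )
            fe = pd.read_csv(out_path)
        name_map = {f"x{j}": design.column_names[j] for j in range(design.X.shape[1])}
        fe["term"] = fe["term"].map(lambda t: name_map.get(t, t))
        fit = HeightFit(
            coefficients=fe[["term", "estimate", "se"]],
            contrasts=pd.DataFrame(),
            backend="lme4",
            converged=True,
        )
    else:
        raise ValueError("backend must be 'auto', 'lme4' or 'ols'")
    fit.contrasts = _condition_contrasts(design, fit)
    return fit


def _predict_cell(design: HeightDesign, fit: HeightFit, cell: dict) -> float:
    """Fixed-effect prediction for one factor cell via the design info."""
    df = pd.DataFrame([{**cell, "rating_cm": 0.0}])
    X = patsy.dmatrix(design.design_info, df, return_type="dataframe")
    x = X[design.column_names].to_numpy()[0]
    return float(x @ fit.coefficients["estimate"].to_numpy())


def _condition_contrasts(design: HeightDesign, fit: HeightFit) -> pd.DataFrame:
    """Small/large vs baseline contrasts per skill group and voice sex.

    Modulated cells are averaged over their two f0 directions (+-4 st),
    mirroring how the conditions co-occur in the stimulus grid.
    """
    rows = []
    groups = design.trials["skill_group"].unique()
    sexes = design.trials["voice_sex"].unique()
    for sex in sexes:
        for grp in groups:
            base = _predict_cell(
                design,
                fit,
                {"skill_group": grp, "voice_sex": sex, "vt_condition": "baseline", "f0_modulation_st": 0.0},
            )
            for vt in ("small", "large"):
                vals = [
                    _predict_cell(
                        design,
                        fit,
                        {"skill_group": grp, "voice_sex": sex, "vt_condition": vt, "f0_modulation_st": f0},
                    )
                    for f0 in (-4.0, 4.0)
                ]
                rows.append(
                    {
                        "voice_sex": sex,
                        "skill_group": grp,
                        "contrast": f"{vt} - baseline",
                        "estimate_cm": float(np.mean(vals) - base),
                    }
                )
    return pd.DataFrame(rows)
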