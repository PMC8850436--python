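"""Per-speaker vocal-size modulation skill scores and their acoustic coupling.

The vocal-tract modulation skill score of a speaker is the difference in
median length-component (fPC) scores between small-voice and large-voice
imitation frames,

    vt_skill = median(score_small) - median(score_large),

so a positive score means the speaker shortened the tract when imitating
a small voice and lengthened it for a large one.  Acoustic skill scores
apply the same small-minus-large median difference to per-take semitone
modulations of f0, F1-F4 or aVTL.  Speakers are ranked within sex and the
top/bottom n form the good/poor modulator groups used in the perception
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("f0", "F1", "F2", "F3", "F4", "aVTL")


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association between two per-speaker skill measures."""

    measure: str
    r: float
    n: int
    t_statistic: float
    p_value: float
    one_sided: bool = True

    @property
    def r_squared(self) -> float:
        return self.r**2

    @property
    def df(self) -> int:
        return self.n - 2


def vt_skill_score(
    scores: pd.DataFrame, component: int = 2, score_prefix: str = "fPC"
) -> pd.DataFrame:
    """Median component score in small minus large conditions, per speaker.

    ``scores`` is a score table with speaker_id, vt_condition and fPC
    columns; frames are pooled across words and f0 directions.  Speakers
    missing either condition are flagged rather than scored.
    """
    col = f"{score_prefix}{component}"
    if col not in scores.columns:
        raise KeyError(f"score table has no column {col}")
    rows = []
    for spk, g in scores.groupby("speaker_id"):
        small = g.loc[g["vt_condition"] == "small", col]
        large = g.loc[g["vt_condition"] == "large", col]
        if len(small) == 0 or len(large) == 0:
            rows.append({"speaker_id": spk, "vt_skill": np.nan, "flagged": True})
        else:
            rows.append(
                {
                    "speaker_id": spk,
                    "vt_skill": float(small.median() - large.median()),
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def acoustic_skill_score(modulations: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Median modulation in the +4 st (small) minus the -4 st (large)
    conditions, pooled across words, per speaker."""
    if measure not in MEASURES:
        raise KeyError(f"measure must be one of {MEASURES}")
    sub = modulations[modulations["measure"] == measure]
    rows = []
    for spk, g in sub.groupby("speaker_id"):
        small = g.loc[g["vtl_shift_st"] == 4, "modulation_st"]
        large = g.loc[g["vtl_shift_st"] == -4, "modulation_st"]
        if len(small) == 0 or len(large) == 0:
            rows.append(
                {"speaker_id": spk, "measure": measure, "acoustic_skill_st": np.nan, "flagged": True}
            )
        else:
            rows.append(
                {
                    "speaker_id": spk,
                    "measure": measure,
                    "acoustic_skill_st": float(small.median() - large.median()),
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def rank_and_group(
    skills: pd.DataFrame,
    n_per_group: int = 5,
    by: tuple[str, ...] = ("sex",),
    excluded: set[str] | None = None,
) -> pd.DataFrame:
    """Rank speakers by vt_skill within strata and assign good/poor groups.

    Within each stratum (by sex, optionally sex x vocal training) speakers
    are sorted by descending vt_skill, ties broken by speaker_id; the top
    ``n_per_group`` become 'good', the bottom n 'poor', the rest stay
    'unassigned'.  Excluded speakers are removed before ranking.
    """
    excluded = excluded or set()
    df = skills[~skills["speaker_id"].isin(excluded)].copy()
    df = df[~df["vt_skill"].isna()]
    out = []
    for _, g in df.groupby(list(by)):
        if len(g) < 2 * n_per_group:
            raise ValueError(
                f"need at least {2 * n_per_group} speakers per stratum, got {len(g)}"
            )
        g = g.sort_values(
            ["vt_skill", "speaker_id"], ascending=[False, True]
        ).reset_index(drop=True)
        g["rank_within_sex"] = np.arange(1, len(g) + 1)
        group = np.full(len(g), "unassigned", dtype=object)
        group[:n_per_group] = "good"
        group[len(g) - n_per_group :] = "poor"
        g["group"] = group
        out.append(g)
    return pd.concat(out, ignore_index=True)


def skill_acoustic_association(
    vt_skill: pd.Series | np.ndarray,
    acoustic_skill: pd.Series | np.ndarray,
    measure: str = "",
    one_sided: bool = True,
) -> AssociationResult:
    """Pearson correlation between vocal-tract and acoustic skill scores.

    Returns r, t = r sqrt(df / (1 - r^2)) with df = n - 2, and by default
    the one-sided p for a positive association.
    """
    x = np.asarray(vt_skill, dtype=float)
    y = np.asarray(acoustic_skill, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in a variable")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(stats.t.sf(t, df)) if one_sided else float(2 * stats.t.sf(abs(t), df))
    return AssociationResult(
        measure=measure, r=r, n=n, t_statistic=float(t), p_value=p, one_sided=one_sided
    )
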