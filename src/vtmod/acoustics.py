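"""Acoustic measurement tables: stimulus grid, semitone modulation, and aVTL.

The imitation experiments use voice targets built from a speaker's own
baseline recording by shifting fundamental frequency (f0) and formant
spacing (a proxy for vocal-tract length, VTL) in semitone steps.  This
module defines that stimulus grid, the semitone-modulation measure

    modulation_st = 12 * log2(observed / baseline)

and the apparent vocal tract length (aVTL), a composite length estimate
that pools the first four formants through a quarter-wavelength tube
model: a uniform tube of length L closed at the glottis resonates at
F_i = (2i - 1) * c / (4 L).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

SPEED_OF_SOUND_CM_S = 35_000.0
WORDS = ("bead", "bard")
#: f0 of the prepared baseline target sits 2 st above the original recording,
#: leaving headroom for the lowered-pitch targets.
BASELINE_F0_OFFSET_ST = 2.0

MEASURES = ("f0", "F1", "F2", "F3", "F4", "aVTL")


class DomainError(ValueError):
    """A quantity is outside its physically meaningful domain."""


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the f0 x VTL stimulus grid, in semitone shifts.

    Sign convention: a positive ``vtl_shift_st`` raises the formants
    (shorter apparent tract, "small" voice); negative lowers them
    ("large" voice).
    """

    f0_shift_st: int = 0
    vtl_shift_st: int = 0

    def __post_init__(self) -> None:
        if abs(self.f0_shift_st) != abs(self.vtl_shift_st):
            raise ValueError("grid conditions have |f0 shift| == |VTL shift|")
        if abs(self.f0_shift_st) not in (0, 2, 4):
            raise ValueError("shifts are 0, +/-2 or +/-4 semitones")

    @property
    def axis(self) -> str:
        if self.f0_shift_st == 0 and self.vtl_shift_st == 0:
            return "baseline"
        return "congruent" if self.f0_shift_st == self.vtl_shift_st else "incongruent"

    @property
    def vt_condition(self) -> str:
        if self.vtl_shift_st > 0:
            return "small"
        if self.vtl_shift_st < 0:
            return "large"
        return "baseline"

    def short_name(self) -> str:
        return f"f0{self.f0_shift_st:+d}_vtl{self.vtl_shift_st:+d}"


@dataclass
class AcousticTake:
    """Measurements from one recorded vocalization."""

    speaker_id: str
    word: str
    condition: ConditionLabel
    take_index: int
    f0_hz: float
    f1_hz: float
    f2_hz: float
    f3_hz: float
    f4_hz: float

    def __post_init__(self) -> None:
        f = self.formants_hz
        if self.f0_hz <= 0 or np.any(f <= 0):
            raise DomainError("all frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise DomainError("formants must satisfy F1 < F2 < F3 < F4")
        if self.word not in WORDS:
            raise DomainError(f"unknown carrier word {self.word!r}")

    @property
    def formants_hz(self) -> np.ndarray:
        return np.array([self.f1_hz, self.f2_hz, self.f3_hz, self.f4_hz])

    def measure(self, name: str) -> float:
        if name == "f0":
            return self.f0_hz
        if name in ("F1", "F2", "F3", "F4"):
            return float(self.formants_hz[int(name[1]) - 1])
        if name == "aVTL":
            return compute_avtl(self)
        raise KeyError(name)


def build_stimulus_grid(session: str = "full") -> list[ConditionLabel]:
    """Enumerate the per-word stimulus grid.

    ``session="full"`` gives the audio-booth grid: 1 baseline plus shifts of
    +/-2 and +/-4 st along the congruent and incongruent axes (9 conditions,
    8 modified).  ``session="rtmri"`` keeps the baseline and only the four
    +/-4 st axis endpoints used in the scanner.
    """
    steps = (2, 4) if session == "full" else (4,)
    if session not in ("full", "rtmri"):
        raise ValueError("session must be 'full' or 'rtmri'")
    grid = [ConditionLabel(0, 0)]
    for s in steps:
        grid += [
            ConditionLabel(+s, +s),
            ConditionLabel(-s, -s),
            ConditionLabel(+s, -s),
            ConditionLabel(-s, +s),
        ]
    return grid


def enumerate_trials(session: str = "audio") -> pd.DataFrame:
    """Enumerate the trial list of an imitation session.

    The audio-booth session presents each of the 18 word-condition targets
    (9 conditions x 2 words) in 2 non-consecutive blocks of 5 trials.  The
    scanner session presents each of the 10 word-condition targets (rtMRI
    grid x 2 words) in 10 blocks of 4 consecutive trials.
    """
    if session == "audio":
        grid, n_blocks, n_trials = build_stimulus_grid("full"), 2, 5
    elif session == "rtmri":
        grid, n_blocks, n_trials = build_stimulus_grid("rtmri"), 10, 4
    else:
        raise ValueError("session must be 'audio' or 'rtmri'")
    rows = []
    for word in WORDS:
        for cond in grid:
            for block in range(1, n_blocks + 1):
                for trial in range(1, n_trials + 1):
                    rows.append(
                        {
                            "word": word,
                            "f0_shift_st": cond.f0_shift_st,
                            "vtl_shift_st": cond.vtl_shift_st,
                            "axis": cond.axis,
                            "vt_condition": cond.vt_condition,
                            "block": block,
                            "trial": trial,
                        }
                    )
    return pd.DataFrame(rows)


def apply_grid_to_baseline(baseline: AcousticTake, condition: ConditionLabel) -> AcousticTake:
    """Derive a target take from an unmodified recording.

    The prepared baseline target keeps the formants but raises f0 by 2 st;
    grid shifts are applied on top of that as frequency ratios.
    """
    f0 = baseline.f0_hz * 2.0 ** ((BASELINE_F0_OFFSET_ST + condition.f0_shift_st) / 12.0)
    ratio = 2.0 ** (condition.vtl_shift_st / 12.0)
    return replace(
        baseline,
        condition=condition,
        f0_hz=f0,
        f1_hz=baseline.f1_hz * ratio,
        f2_hz=baseline.f2_hz * ratio,
        f3_hz=baseline.f3_hz * ratio,
        f4_hz=baseline.f4_hz * ratio,
    )


def semitone_modulation(observed_hz, baseline_hz):
    """12 * log2(observed / baseline); antisymmetric and additive in chains."""
    observed_hz = np.asarray(observed_hz, dtype=float)
    baseline_hz = np.asarray(baseline_hz, dtype=float)
    if np.any(observed_hz <= 0) or np.any(baseline_hz <= 0):
        raise DomainError("frequencies must be positive")
    out = 12.0 * np.log2(observed_hz / baseline_hz)
    return float(out) if out.ndim == 0 else out


def quarter_wave_formants(length_cm: float, c: float = SPEED_OF_SOUND_CM_S) -> np.ndarray:
    """Resonances F_i = (2i-1) c / (4 L) of a closed-open tube, i = 1..4."""
    if length_cm <= 0:
        raise DomainError("tube length must be positive")
    i = np.arange(1, 5)
    return (2 * i - 1) * c / (4.0 * length_cm)


def avtl_from_formants(formants_hz: Sequence[float], c: float = SPEED_OF_SOUND_CM_S) -> float:
    f = np.asarray(formants_hz, dtype=float)
    if np.any(f <= 0):
        raise DomainError("formants must be positive")
    i = np.arange(1, len(f) + 1)
    return float(np.mean((2 * i - 1) * c / (4.0 * f)))


def compute_avtl(take: AcousticTake, c: float = SPEED_OF_SOUND_CM_S) -> float:
    """Apparent vocal tract length in cm: per-formant quarter-wave lengths, averaged."""
    return avtl_from_formants(take.formants_hz, c=c)


def _median_baseline(takes: Sequence[AcousticTake]) -> dict[str, float]:
    base = [t for t in takes if t.condition.axis == "baseline"]
    if not base:
        raise ValueError("no baseline-condition takes present")
    return {m: float(np.median([t.measure(m) for t in base])) for m in MEASURES}


def modulation_table(takes: Sequence[AcousticTake]) -> pd.DataFrame:
    """Per-take semitone modulation of every measure against the baseline median.

    Takes are grouped by (speaker, word); each group needs baseline takes.
    aVTL modulation is computed on the aVTL values themselves, so an overall
    formant rise (shorter tract) gives a negative aVTL modulation.
    """
    rows = []
    df_keys = sorted({(t.speaker_id, t.word) for t in takes})
    for speaker_id, word in df_keys:
        group = [t for t in takes if t.speaker_id == speaker_id and t.word == word]
        base = _median_baseline(group)
        for t in group:
            for m in MEASURES:
                rows.append(
                    {
                        "speaker_id": speaker_id,
                        "word": word,
                        "f0_shift_st": t.condition.f0_shift_st,
                        "vtl_shift_st": t.condition.vtl_shift_st,
                        "vt_condition": t.condition.vt_condition,
                        "take_index": t.take_index,
                        "measure": m,
                        "modulation_st": semitone_modulation(t.measure(m), base[m]),
                    }
                )
    return pd.DataFrame(rows)


def select_representative_token(takes: Sequence[AcousticTake]) -> AcousticTake:
    """The take closest to the within-cell median f0, F1 and F2.

    Deviation is the summed absolute semitone distance from the three
    medians; ties go to the lowest take_index.
    """
    takes = list(takes)
    if not takes:
        raise ValueError("empty take set")
    med = {m: float(np.median([t.measure(m) for t in takes])) for m in ("f0", "F1", "F2")}
    def deviation(t: AcousticTake) -> float:
        return sum(abs(semitone_modulation(t.measure(m), med[m])) for m in ("f0", "F1", "F2"))
    return min(takes, key=lambda t: (deviation(t), t.take_index))
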