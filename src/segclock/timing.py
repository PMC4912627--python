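"""Somitogenesis timing and segment-boundary scoring.

Covers the three time-lapse/staining read-outs of the study design:

* segmentation period from the timing of somitic furrow emergence
  (ordinary least-squares slope of frame index on somite number, times the
  frame interval, restricted to trunk segments 4-19);
* axis-elongation / PSM-shortening rates from tissue-length time series
  (OLS slope over the 0-600 min window, time 0 at the 5-somite stage);
* per-side somite-boundary defect scoring after a Notch-blockade pulse-chase:
  ALD (anterior limit of defects), FRS (first recovered segment after
  washout at the 9-somite stage) and the re-synchronization rate
  1/(FRS - 9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

TRUNK_FIRST_SOMITE = 4
TRUNK_LAST_SOMITE = 19
#: scoring window: the first two somites and those posterior to the 30th are
#: treated as non-defective (clutch-dependent / too small to score).
SCORE_FIRST = 3
SCORE_LAST = 30
WASHOUT_STAGE = 9
RATE_WINDOW_MIN = (0.0, 600.0)

#: sentinel returned for ALD when no defective boundary exists in [3, 30]
NO_DEFECT = 0


@dataclass(frozen=True)
class FurrowTimes:
    """Furrow-emergence record for one embryo."""

    somite_numbers: np.ndarray
    frame_indices: np.ndarray
    frame_interval: float  # min per frame
    temperature: float | None = None  # deg C, metadata only

    def __post_init__(self) -> None:
        s = np.asarray(self.somite_numbers)
        f = np.asarray(self.frame_indices)
        if s.shape != f.shape:
            raise ValueError("somite_numbers and frame_indices differ in length")
        if np.any(np.diff(s) <= 0):
            raise ValueError("somite_numbers must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "somite_numbers", s)
        object.__setattr__(self, "frame_indices", f)


@dataclass(frozen=True)
class LengthSeries:
    """Tissue length versus time for one embryo; kind is 'axis' or 'psm'."""

    times: np.ndarray
    lengths: np.ndarray
    kind: str = "axis"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.lengths, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and lengths differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("axis", "psm"):
            raise ValueError(f"kind must be 'axis' or 'psm', got {self.kind!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lengths", y)


@dataclass(frozen=True)
class BoundaryRecord:
    """Per-side boundary status vector; statuses[i] is segment i+1."""

    side: str
    statuses: tuple[str, ...]  # 'ok' | 'defective', segment 1..n
    washout_stage: int = WASHOUT_STAGE

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        bad = {s for s in self.statuses} - {"ok", "defective"}
        if bad:
            raise ValueError(f"unknown boundary statuses: {bad}")
        if len(self.statuses) < 10:
            raise ValueError("boundary record must cover at least segment 10")


@dataclass(frozen=True)
class ScoreResult:
    ALD: int  # NO_DEFECT sentinel when no defect in [3, 30]
    FRS: int | None  # None when censored/undefined
    resync_rate: float | None
    defect_fraction: float
    total_segments: int
    trunk_segments: int | None = None


def fit_period(f: FurrowTimes, *, first: int = TRUNK_FIRST_SOMITE,
               last: int = TRUNK_LAST_SOMITE) -> float:
    """Somitogenesis period (min) from furrow-emergence times.

    OLS slope of frame index on somite number over somites ``first..last``,
    multiplied by the frame interval.  Requires >= 5 usable somites.
    """
    mask = (f.somite_numbers >= first) & (f.somite_numbers <= last)
    s = np.asarray(f.somite_numbers, dtype=float)[mask]
    fr = np.asarray(f.frame_indices, dtype=float)[mask]
    if s.size < 5:
        raise ValueError(
            f"need >= 5 somites in [{first}, {last}], got {s.size}"
        )
    slope = stats.linregress(s, fr).slope
    return slope * f.frame_interval


def fit_rate(s: LengthSeries, *, window: tuple[float, float] = RATE_WINDOW_MIN
             ) -> float:
    """Tissue length-change rate (um/min) from the linear fit over ``window``.

    Axis extension is returned as a positive slope; PSM shortening is
    returned as the positive magnitude of a negative slope.
    """
    lo, hi = window
    mask = (s.times >= lo) & (s.times <= hi)
    t = s.times[mask]
    y = s.lengths[mask]
    if t.size < 10:
        raise ValueError(
            f"need >= 10 samples in [{lo}, {hi}] min, got {t.size}"
        )
    slope = stats.linregress(t, y).slope
    if s.kind == "psm":
        return abs(slope)
    return slope


def score_boundaries(rec: BoundaryRecord) -> ScoreResult:
    """Score a per-side boundary record for ALD, FRS and re-sync rate.

    ALD is the first defective boundary in the scoring window [3, 30].
    FRS is the first non-defective boundary after the washout stage that
    follows at least one defective segment (the pulse-chase design guarantees
    a defective region before recovery; without one FRS is undefined).
    If every boundary from washout through segment 30 is defective, FRS is
    censored (None).
    """
    n = len(rec.statuses)
    washout = rec.washout_stage

    def status(seg: int) -> str:
        # outside the scored window segments count as non-defective
        if seg < SCORE_FIRST or seg > SCORE_LAST:
            return "ok"
        return rec.statuses[seg - 1]

    scored = range(SCORE_FIRST, min(SCORE_LAST, n) + 1)
    defects = [seg for seg in scored if status(seg) == "defective"]
    ald = defects[0] if defects else NO_DEFECT

    frs: int | None = None
    if defects:
        # recovery past segment 30 is unobservable (defined non-defective),
        # so an all-defective tail through 30 leaves FRS censored
        for seg in range(washout + 1, min(n, SCORE_LAST) + 1):
            if status(seg) == "ok" and any(d < seg for d in defects):
                frs = seg
                break
    resync = 1.0 / (frs - washout) if frs is not None else None
    n_scored = len(list(scored))
    frac = len(defects) / n_scored if n_scored else 0.0
    return ScoreResult(
        ALD=ald,
        FRS=frs,
        resync_rate=resync,
        defect_fraction=frac,
        total_segments=n,
    )


def count_segments(statuses: Sequence[str], landmark_index: int
                   ) -> tuple[int, int]:
    """(total, trunk) segment counts.

    Total is the highest formed boundary index; trunk is the index of the
    proctodeum-aligned landmark boundary.
    """
    total = len(statuses)
    if total == 0:
        return 0, 0
    if not 0 <= landmark_index <= total:
        raise ValueError(
            f"landmark_index {landmark_index} outside record of {total}"
        )
    return total, landmark_index


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Welch t-test (convenience wrapper): (statistic, p-value)."""
    res = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pooled_summary(values: Sequence[float]) -> dict:
    """Mean +/- s.d. summary in the study's reporting convention."""
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "n": int(v.size),
    }
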