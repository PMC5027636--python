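"""Detection calibration against background and dilution-series diagnostics.

Detection is a one-sided test against a normal background model on the ΔCt
scale: after normalization the background sits at 0, so a value is called
detected when it exceeds ``z(1−α)·bg_sd``.  The limit of detection is the
smallest quantity at which 7 of 8 replicates are detected at α = 0.01.

A probe's usable dynamic range is found by exhaustively scoring every
contiguous window of ≥ 3 dilution levels: replicate-mean ΔCt is regressed on
log2 quantity and the window maximizing ``R² − cost·(levels removed)`` wins
(cost 0.03 per removed level).  A probe is reliable when its selected window
is linear with positive slope, detected above background, and spans the
single-cell scale (1.3 cell equivalents).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DeltaCtTable, SampleType
from .preprocess import BackgroundModel

__all__ = [
    "DetectionThreshold",
    "DilutionSeries",
    "LinearRangeFit",
    "FailureMode",
    "ReliabilityCall",
    "LodResult",
    "detection_threshold",
    "call_detection",
    "series_from_delta_ct",
    "select_linear_range",
    "limit_of_detection",
    "classify_probe_reliability",
]


@dataclass(frozen=True)
class DetectionThreshold:
    """ΔCt level above which a value has probability < alpha of being background."""

    target_id: str
    threshold_dct: float
    alpha: float


@dataclass
class DilutionSeries:
    """Replicate ΔCt measurements across a dilution ladder for one target."""

    target_id: str
    quantities: np.ndarray            # strictly monotone, positive
    replicates: np.ndarray            # levels × n_replicates ΔCt

    def __post_init__(self) -> None:
        self.quantities = np.asarray(self.quantities, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=float)
        d = np.diff(self.quantities)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("quantities must be strictly monotone")
        if self.replicates.shape[0] != len(self.quantities):
            raise ValueError("one replicate row per quantity level required")
        if self.replicates.shape[1] < 2:
            raise ValueError("need >= 2 replicates per level")

    def ascending(self) -> "DilutionSeries":
        order = np.argsort(self.quantities)
        return DilutionSeries(self.target_id, self.quantities[order], self.replicates[order])

    @property
    def level_means(self) -> np.ndarray:
        return self.replicates.mean(axis=1)


@dataclass(frozen=True)
class LinearRangeFit:
    target_id: str
    lo_index: int                 # inclusive, on the ascending-quantity axis
    hi_index: int
    slope: float                  # cycles per doubling
    intercept: float
    r2: float
    n_removed: int
    score: float                  # r2 − range_cost·n_removed


class FailureMode(str, enum.Enum):
    NONE = "NONE"
    NO_SIGNAL = "NO_SIGNAL"
    SATURATED = "SATURATED"
    RANGE_EXCLUDES_SINGLE_CELL = "RANGE_EXCLUDES_SINGLE_CELL"


@dataclass(frozen=True)
class ReliabilityCall:
    target_id: str
    reliable: bool
    failure_mode: FailureMode


@dataclass(frozen=True)
class LodResult:
    target_id: str
    lod_quantity: float | None    # None: no level met the replicate rule


def detection_threshold(bg: BackgroundModel | float, alpha: float = 0.01,
                        target_id: str = "") -> DetectionThreshold:
    """``threshold_dct = z(1−alpha)·bg_sd`` (background mean 0 on the ΔCt scale)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    bg_sd = bg if isinstance(bg, (int, float)) else bg.sd_of(target_id)
    if bg_sd < 0:
        raise ValueError("bg_sd must be nonnegative")
    z = stats.norm.ppf(1 - alpha)
    return DetectionThreshold(target_id=target_id,
                              threshold_dct=max(z * bg_sd, 0.0), alpha=alpha)


def thresholds_for(bg: BackgroundModel, target_ids: list[str], alpha: float = 0.01,
                   default_sd: float = 0.0) -> dict[str, DetectionThreshold]:
    """Per-target thresholds; targets without a background entry (RNA assays,
    which have no zero-cell background) fall back to ``default_sd``, i.e. the
    literal ΔCt > 0 rule at the default."""
    out = {}
    for tid in target_ids:
        sd = bg.sd_of(tid) if tid in bg else default_sd
        out[tid] = detection_threshold(sd, alpha, tid)
    return out


def call_detection(dct_value: float | np.ndarray,
                   threshold: DetectionThreshold) -> bool | np.ndarray:
    """Detected iff ΔCt strictly exceeds the threshold."""
    return np.asarray(dct_value) > threshold.threshold_dct if isinstance(
        dct_value, np.ndarray) else dct_value > threshold.threshold_dct


def series_from_delta_ct(dct: DeltaCtTable, target_id: str) -> DilutionSeries:
    """Assemble the replicate matrix for one target from DILUTION wells."""
    dil = dct.wells_of(SampleType.DILUTION)
    by_q: dict[float, list[float]] = {}
    for w in dil:
        by_q.setdefault(w.dilution_quantity, []).append(float(dct.dct.at[w.well_id, target_id]))
    quantities = np.array(sorted(by_q))
    n_rep = min(len(v) for v in by_q.values())
    reps = np.array([by_q[q][:n_rep] for q in quantities])
    return DilutionSeries(target_id, quantities, reps)


def _window_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² of OLS y~x; R² defined as 0 for a flat window."""
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        slope = 0.0
        return slope, float(np.mean(y)), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def select_linear_range(series: DilutionSeries, range_cost: float = 0.03,
                        min_window: int = 3,
                        override: tuple[int, int] | None = None) -> LinearRangeFit:
    """Best contiguous window of dilution levels by penalized R².

    Every contiguous window of at least ``min_window`` levels is scored as
    ``R² − range_cost · (levels outside the window)``; ties go to the longer
    window, then to the lower start index.  ``override`` pins the window
    (an audited replacement for by-eye range adjustment).
    """
    s = series.ascending()
    n = len(s.quantities)
    if n < min_window:
        raise ValueError(f"need >= {min_window} quantity levels")
    logq = np.log2(s.quantities)
    means = s.level_means

    if override is not None:
        lo, hi = override
        slope, intercept, r2 = _window_ols(logq[lo:hi + 1], means[lo:hi + 1])
        return LinearRangeFit(s.target_id, lo, hi, slope, intercept, r2,
                              n - (hi - lo + 1), r2 - range_cost * (n - (hi - lo + 1)))

    best: LinearRangeFit | None = None
    for lo in range(0, n - min_window + 1):
        for hi in range(lo + min_window - 1, n):
            slope, intercept, r2 = _window_ols(logq[lo:hi + 1], means[lo:hi + 1])
            n_removed = n - (hi - lo + 1)
            fit = LinearRangeFit(s.target_id, lo, hi, slope, intercept, r2,
                                 n_removed, r2 - range_cost * n_removed)
            if best is None:
                best = fit
                continue
            better = (fit.score > best.score
                      or (fit.score == best.score and fit.n_removed < best.n_removed)
                      or (fit.score == best.score and fit.n_removed == best.n_removed
                          and fit.lo_index < best.lo_index))
            if better:
                best = fit
    return best


def limit_of_detection(series: DilutionSeries, threshold: DetectionThreshold,
                       min_detected: int = 7, expected_replicates: int = 8) -> LodResult:
    """Smallest quantity detected in ``min_detected`` of ``expected_replicates``.

    If the series carries a different replicate count, the rule is applied as
    the equivalent proportion ``min_detected / expected_replicates``.
    """
    s = series.ascending()
    n_rep = s.replicates.shape[1]
    need = min_detected if n_rep == expected_replicates else int(
        np.ceil(min_detected / expected_replicates * n_rep))
    detected_counts = (s.replicates > threshold.threshold_dct).sum(axis=1)
    ok = np.flatnonzero(detected_counts >= need)
    if len(ok) == 0:
        return LodResult(series.target_id, None)
    return LodResult(series.target_id, float(s.quantities[ok[0]]))


def classify_probe_reliability(fit: LinearRangeFit, series: DilutionSeries,
                               threshold: DetectionThreshold,
                               single_cell_equivalents: float = 1.3) -> ReliabilityCall:
    """Reliable iff the selected window spans the single-cell scale with a
    positive slope and detectable signal at that scale.

    Failure modes: ``NO_SIGNAL`` when no level's mean exceeds the detection
    threshold; ``SATURATED`` when the response is flat-or-falling while at
    least half the levels show signal; otherwise the window simply excludes
    the single-cell quantity.
    """
    s = series.ascending()
    means = s.level_means
    detected_levels = means > threshold.threshold_dct

    if not detected_levels.any():
        return ReliabilityCall(series.target_id, False, FailureMode.NO_SIGNAL)

    if fit.slope <= 0:
        if detected_levels.mean() >= 0.5:
            return ReliabilityCall(series.target_id, False, FailureMode.SATURATED)
        return ReliabilityCall(series.target_id, False, FailureMode.NO_SIGNAL)

    q_lo, q_hi = s.quantities[fit.lo_index], s.quantities[fit.hi_index]
    spans = q_lo <= single_cell_equivalents <= q_hi
    nearest = int(np.argmin(np.abs(np.log2(s.quantities) - np.log2(single_cell_equivalents))))
    if spans and detected_levels[nearest]:
        return ReliabilityCall(series.target_id, True, FailureMode.NONE)
    return ReliabilityCall(series.target_id, False, FailureMode.RANGE_EXCLUDES_SINGLE_CELL)
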