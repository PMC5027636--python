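"""Expression-distribution models and the in-silico gating screen.

Single-cell ΔCt distributions are bimodal: a point mass at 0 (undetected)
plus a roughly normal expressing component.  Two models are fitted per target
and time point — a plain normal over all values, and a three-parameter model
(fraction expressing π plus a normal over detected values) — each with a χ²
goodness-of-fit check.  Because neither fits universally, differential calls
use two distribution-free tests instead:

* Fisher's exact test on the detected/undetected proportion, run when the
  undetected total across both groups exceeds 10;
* Mann–Whitney U on detected values only, run when the detected total
  exceeds 10.

The in-silico gating screen bifurcates the cells by detection of each target
in turn and applies both tests to every other target, with Benjamini–Hochberg
correction within each gate's family of tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calibration import DetectionThreshold
from .core import DeltaCtTable

__all__ = [
    "ExpressionModelFit",
    "GateTestResult",
    "fit_normal_model",
    "fit_three_param_model",
    "detection_proportion_test",
    "expression_shift_test",
    "in_silico_gate_all",
    "de_between_groups",
    "bh_adjust",
]

#: a test is eligible only when the relevant count across both groups exceeds this
ELIGIBILITY_COUNT = 10


class ModelKind(str, enum.Enum):
    NORMAL2 = "NORMAL2"
    MIXTURE3 = "MIXTURE3"


class Direction(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"


@dataclass(frozen=True)
class ExpressionModelFit:
    target_id: str
    model: ModelKind
    mu: float
    sigma: float
    pi: float | None = None         # MIXTURE3 only
    gof_p: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class GateTestResult:
    gate_target: str
    response_target: str
    test: str                       # FISHER_DETECTION or MWU_LEVEL
    p_value: float
    p_adjusted: float
    direction: Direction | None
    n_gate_pos: int
    n_gate_neg: int
    skipped: bool = False


def _chi2_gof_normal(values: np.ndarray, mu: float, sigma: float) -> float:
    """χ² goodness of fit against Normal(mu, sigma) with equal-probability bins.

    Bin count targets expected counts >= 5; degrees of freedom are reduced by
    the 2 fitted parameters (needs >= 4 bins, i.e. ~20 observations, else NaN).
    """
    n = len(values)
    n_bins = min(10, n // 5)
    if n_bins < 4 or sigma <= 0:
        return float("nan")
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), loc=mu, scale=sigma)
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(values, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = n_bins - 1 - 2
    return float(stats.chi2.sf(chi2, df))


def fit_normal_model(values, target_id: str = "") -> ExpressionModelFit:
    """ML normal fit over all values (zeros included) with χ² GOF."""
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need >= 10 values")
    mu = float(np.mean(values))
    sigma = float(np.std(values))       # ML estimate
    if sigma == 0:
        return ExpressionModelFit(target_id, ModelKind.NORMAL2, mu, 0.0, degenerate=True)
    return ExpressionModelFit(target_id, ModelKind.NORMAL2, mu, sigma,
                              gof_p=_chi2_gof_normal(values, mu, sigma))


def fit_three_param_model(values, threshold: DetectionThreshold,
                          target_id: str = "") -> ExpressionModelFit:
    """Fraction expressing π plus a normal over detected values.

    π is the detected fraction at the given threshold; μ and σ are ML
    estimates on the detected values, with the χ² GOF evaluated on that
    component alone.  With fewer than 4 detected values the components are
    undefined and the fit is flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need >= 10 values")
    detected = values[values > threshold.threshold_dct]
    pi = float(len(detected) / len(values))
    if len(detected) < 4:
        return ExpressionModelFit(target_id, ModelKind.MIXTURE3, float("nan"),
                                  float("nan"), pi=pi, degenerate=True)
    mu = float(np.mean(detected))
    sigma = float(np.std(detected))
    if sigma == 0:
        return ExpressionModelFit(target_id, ModelKind.MIXTURE3, mu, 0.0, pi=pi,
                                  degenerate=True)
    return ExpressionModelFit(target_id, ModelKind.MIXTURE3, mu, sigma, pi=pi,
                              gof_p=_chi2_gof_normal(detected, mu, sigma))


def _detected_split(dct: DeltaCtTable, target_id: str, cells: list[str],
                    threshold: DetectionThreshold) -> np.ndarray:
    return dct.dct.loc[cells, target_id].to_numpy(dtype=float) > threshold.threshold_dct


def detection_proportion_test(dct: DeltaCtTable, target_id: str,
                              group_a: list[str], group_b: list[str],
                              threshold: DetectionThreshold,
                              force: bool = False) -> tuple[float, Direction | None, bool]:
    """Two-sided Fisher's exact test on detection counts.

    Eligible only when the undetected total across both groups exceeds 10
    (``force`` overrides, for sensitivity analyses); returns
    ``(p, direction, skipped)`` where direction UP means a higher detected
    proportion in group_b.
    """
    if set(group_a) & set(group_b) or not group_a or not group_b:
        raise ValueError("groups must be disjoint and non-empty")
    det_a = _detected_split(dct, target_id, group_a, threshold)
    det_b = _detected_split(dct, target_id, group_b, threshold)
    n_undet = int((~det_a).sum() + (~det_b).sum())
    if n_undet <= ELIGIBILITY_COUNT and not force:
        return float("nan"), None, True
    table = [[int(det_a.sum()), int((~det_a).sum())],
             [int(det_b.sum()), int((~det_b).sum())]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    direction = Direction.UP if det_b.mean() > det_a.mean() else Direction.DOWN
    return float(p), direction, False


def expression_shift_test(dct: DeltaCtTable, target_id: str,
                          group_a: list[str], group_b: list[str],
                          threshold: DetectionThreshold,
                          force: bool = False) -> tuple[float, Direction | None, bool]:
    """Two-sided Mann–Whitney U on detected values only.

    Eligible only when the detected total across both groups exceeds 10
    (``force`` overrides, for sensitivity analyses).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    va = dct.dct.loc[group_a, target_id].to_numpy(dtype=float)
    vb = dct.dct.loc[group_b, target_id].to_numpy(dtype=float)
    va = va[va > threshold.threshold_dct]
    vb = vb[vb > threshold.threshold_dct]
    if (len(va) + len(vb) <= ELIGIBILITY_COUNT and not force) or len(va) == 0 or len(vb) == 0:
        return float("nan"), None, True
    res = stats.mannwhitneyu(va, vb, alternative="two-sided")
    direction = Direction.UP if np.median(vb) > np.median(va) else Direction.DOWN
    return float(res.pvalue), direction, False


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_between_groups(dct: DeltaCtTable, target_ids: list[str],
                      group_a: list[str], group_b: list[str],
                      thresholds: dict[str, DetectionThreshold],
                      gate_label: str = "groups") -> list[GateTestResult]:
    """Run both eligible tests for each target between two cell groups, then
    BH-adjust across all executed tests as one family."""
    records: list[GateTestResult] = []
    for tid in target_ids:
        thr = thresholds[tid]
        p_f, dir_f, skip_f = detection_proportion_test(dct, tid, group_a, group_b, thr)
        records.append(GateTestResult(gate_label, tid, "FISHER_DETECTION", p_f,
                                      float("nan"), dir_f, len(group_a), len(group_b),
                                      skipped=skip_f))
        p_m, dir_m, skip_m = expression_shift_test(dct, tid, group_a, group_b, thr)
        records.append(GateTestResult(gate_label, tid, "MWU_LEVEL", p_m,
                                      float("nan"), dir_m, len(group_a), len(group_b),
                                      skipped=skip_m))
    return _apply_bh(records)


def _apply_bh(records: list[GateTestResult]) -> list[GateTestResult]:
    run_idx = [i for i, r in enumerate(records) if not r.skipped]
    if run_idx:
        adj = bh_adjust([records[i].p_value for i in run_idx])
        for i, a in zip(run_idx, adj):
            r = records[i]
            records[i] = GateTestResult(r.gate_target, r.response_target, r.test,
                                        r.p_value, float(a), r.direction,
                                        r.n_gate_pos, r.n_gate_neg)
    return records


def in_silico_gate_all(dct: DeltaCtTable,
                       thresholds: dict[str, DetectionThreshold],
                       gate_targets: list[str] | None = None,
                       response_targets: list[str] | None = None) -> list[GateTestResult]:
    """Bifurcate cells by detection of each gate target and test every other
    target for differential detection (Fisher) and level (Mann–Whitney).

    BH correction is applied within each gate's in-silico experiment (across
    both test kinds and all response targets).
    """
    all_ids = dct.target_ids
    if len(all_ids) < 2:
        raise ValueError("need >= 2 targets")
    gate_targets = all_ids if gate_targets is None else gate_targets
    response_targets = all_ids if response_targets is None else response_targets
    cell_ids = [w.well_id for w in dct.wells]

    out: list[GateTestResult] = []
    for gate in gate_targets:
        det = _detected_split(dct, gate, cell_ids, thresholds[gate])
        pos = [c for c, d in zip(cell_ids, det) if d]
        neg = [c for c, d in zip(cell_ids, det) if not d]
        if not pos or not neg:
            continue    # gate with an empty side carries no information
        records: list[GateTestResult] = []
        for tid in response_targets:
            if tid == gate:
                continue
            thr = thresholds[tid]
            p_f, dir_f, skip_f = detection_proportion_test(dct, tid, neg, pos, thr)
            records.append(GateTestResult(gate, tid, "FISHER_DETECTION", p_f,
                                          float("nan"), dir_f, len(pos), len(neg),
                                          skipped=skip_f))
            p_m, dir_m, skip_m = expression_shift_test(dct, tid, neg, pos, thr)
            records.append(GateTestResult(gate, tid, "MWU_LEVEL", p_m,
                                          float("nan"), dir_m, len(pos), len(neg),
                                          skipped=skip_m))
        out.extend(_apply_bh(records))
    return out


def gate_results_frame(results: list[GateTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gate_target": r.gate_target, "response_target": r.response_target,
        "test": r.test, "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        "direction": r.direction.value if r.direction else None,
        "n_gate_pos": r.n_gate_pos, "n_gate_neg": r.n_gate_neg, "skipped": r.skipped,
    } for r in results])
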