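"""Paired RNA–protein correlation statistics.

Per gene and time point the Spearman rank correlation between the RNA and
protein ΔCt vectors is computed over retained cells, with undetected values
(0) included.  Changes in correlation between time points are tested against
a permutation null: time-point labels are shuffled 10,000 times, the change in
ρ recomputed each time, and a two-sided p-value read from a normal fitted to
the null's mean and SD.  Distribution-level checks (Lilliefors normality,
t-test on means, F-test on variances) compare the per-gene ρ distributions
across time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .core import Analyte, DeltaCtTable

__all__ = [
    "spearman_rho",
    "paired_correlations",
    "delta_correlation_test",
    "correlation_distribution_tests",
    "coefficient_of_variation",
    "qq_curve",
]


def spearman_rho(x, y) -> float:
    """Spearman ρ with average ranks for ties; NaN when a margin is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _pair_columns(dct: DeltaCtTable, gene: str) -> tuple[str, str] | None:
    rna = [t.target_id for t in dct.targets_of(Analyte.RNA) if t.gene == gene]
    prot = [t.target_id for t in dct.targets_of(Analyte.PROTEIN) if t.gene == gene]
    if len(rna) != 1 or len(prot) != 1:
        warnings.warn(f"gene {gene!r} lacks a unique RNA/protein pair; skipped")
        return None
    return rna[0], prot[0]


def paired_correlations(dct: DeltaCtTable, genes: list[str] | None = None) -> pd.DataFrame:
    """One (gene, time point) row of Spearman ρ per RNA/protein pair."""
    genes = dct.paired_genes() if genes is None else genes
    records = []
    for gene in genes:
        cols = _pair_columns(dct, gene)
        if cols is None:
            continue
        rna_id, prot_id = cols
        for tp in dct.time_points():
            sub = dct.cells_at(tp)
            rho = spearman_rho(sub.dct[rna_id], sub.dct[prot_id])
            records.append({"gene": gene, "time_point_hr": tp, "rho": rho,
                            "n_cells": len(sub.wells)})
    return pd.DataFrame(records)


@dataclass(frozen=True)
class DeltaCorrelationTest:
    gene: str
    time_a: float
    time_b: float
    rho_a: float
    rho_b: float
    delta_rho: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def delta_correlation_test(dct: DeltaCtTable, gene: str, time_a: float, time_b: float,
                           n_permutations: int = 10_000, seed: int = 0) -> DeltaCorrelationTest:
    """Permutation-null test for a change in paired correlation across time.

    Cells from the two time points are pooled and their labels shuffled
    (group sizes preserved); the null mean/SD of Δρ feed a two-sided normal
    p-value for the observed change.
    """
    cols = _pair_columns(dct, gene)
    if cols is None:
        raise ValueError(f"gene {gene!r} has no unique RNA/protein pair")
    rna_id, prot_id = cols
    xa = dct.cells_at(time_a).dct[[rna_id, prot_id]].to_numpy()
    xb = dct.cells_at(time_b).dct[[rna_id, prot_id]].to_numpy()
    na, nb = len(xa), len(xb)
    if na < 3 or nb < 3:
        raise ValueError("need >= 3 cells per time point")

    rho_a = spearman_rho(xa[:, 0], xa[:, 1])
    rho_b = spearman_rho(xb[:, 0], xb[:, 1])
    observed = rho_b - rho_a

    pooled = np.vstack([xa, xb])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        idx = rng.permutation(na + nb)
        ga, gb = pooled[idx[:na]], pooled[idx[na:]]
        null[i] = spearman_rho(gb[:, 0], gb[:, 1]) - spearman_rho(ga[:, 0], ga[:, 1])
    null = null[~np.isnan(null)]
    null_mean, null_sd = float(np.mean(null)), float(np.std(null, ddof=1))

    if null_sd == 0:
        p = 1.0 if observed == null_mean else 0.0
        return DeltaCorrelationTest(gene, time_a, time_b, rho_a, rho_b, observed,
                                    null_mean, null_sd, p, n_permutations, degenerate=True)
    z = (observed - null_mean) / null_sd
    p = float(2 * stats.norm.sf(abs(z)))
    return DeltaCorrelationTest(gene, time_a, time_b, rho_a, rho_b, observed,
                                null_mean, null_sd, p, n_permutations)


def correlation_distribution_tests(rho_by_time: dict[float, np.ndarray]) -> pd.DataFrame:
    """Lilliefors normality per time point; pairwise t (means) and F (variances).

    Undefined correlations (NaN, from constant margins) are dropped per group.
    Returns a tidy frame with one row per test.
    """
    rho_by_time = {tp: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
                   for tp, v in rho_by_time.items()}
    tps = sorted(rho_by_time)
    if any(len(rho_by_time[tp]) < 4 for tp in tps):
        raise ValueError("need >= 4 genes per time point")
    records = []
    for tp in tps:
        vals = np.asarray(rho_by_time[tp], dtype=float)
        stat, p = lilliefors(vals, dist="norm")
        records.append({"test": "lilliefors", "group_a": tp, "group_b": None,
                        "statistic": float(stat), "p_value": float(p)})
    for i in range(len(tps)):
        for j in range(i + 1, len(tps)):
            a = np.asarray(rho_by_time[tps[i]], dtype=float)
            b = np.asarray(rho_by_time[tps[j]], dtype=float)
            t_res = stats.ttest_ind(a, b)
            records.append({"test": "t_mean", "group_a": tps[i], "group_b": tps[j],
                            "statistic": float(t_res.statistic), "p_value": float(t_res.pvalue)})
            f = np.var(a, ddof=1) / np.var(b, ddof=1)
            dfa, dfb = len(a) - 1, len(b) - 1
            p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
            records.append({"test": "f_variance", "group_a": tps[i], "group_b": tps[j],
                            "statistic": float(f), "p_value": float(min(p, 1.0))})
    return pd.DataFrame(records)


def coefficient_of_variation(dct: DeltaCtTable, target_id: str, time_point_hr: float,
                             detected_only: bool = False) -> float:
    """σ/μ of a target's ΔCt over cells at a time point; NaN when μ == 0."""
    vals = dct.values_for(target_id, time_point_hr)
    if detected_only:
        vals = vals[vals > 0]
    if len(vals) < 2 or np.mean(vals) == 0:
        return float("nan")
    return float(np.std(vals, ddof=1) / np.mean(vals))


def qq_curve(sample_a, sample_b, n_quantiles: int = 100) -> pd.DataFrame:
    """Matched empirical quantiles of two samples at (i−0.5)/n probabilities."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    return pd.DataFrame({
        "prob": probs,
        "quantile_a": np.quantile(a, probs),
        "quantile_b": np.quantile(b, probs),
    })
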