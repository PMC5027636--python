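"""Ct → ΔCt normalization, protein background estimation, and cell QC.

Normalization rules, applied literally and without PCR-efficiency correction:

* RNA: ``ΔCt = max(24 − Ct, 0)``; a reaction that never crossed threshold is 0.
* Protein: Ct is first clipped to the 24-cycle ceiling (undetected wells
  included), then referenced to the assay's mean background Ct estimated from
  zero-cell capture sites: ``ΔCt = max(bg_mean − Ct, 0)``.
* Dilution wells: referenced to the mean lysis-buffer Ct of the assay, falling
  back to the 24-cycle ceiling for assays undetected in lysis buffer alone.

Cells expressing fewer than 35 reliable RNAs (ΔCt > 0) are culled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Analyte, CtTable, DeltaCtTable, SampleType

__all__ = [
    "BackgroundModel",
    "QcReport",
    "estimate_protein_background",
    "check_background_homogeneity",
    "rna_delta_ct",
    "protein_delta_ct",
    "dilution_delta_ct",
    "combined_delta_ct",
    "cull_cells",
]


@dataclass
class BackgroundModel:
    """Per-target background Ct mean/SD from zero-cell (or buffer) wells."""

    stats: pd.DataFrame           # index target_id; columns bg_mean, bg_sd, n_wells
    pooled_across_time: bool = True

    def mean_of(self, target_id: str) -> float:
        return float(self.stats.at[target_id, "bg_mean"])

    def sd_of(self, target_id: str) -> float:
        return float(self.stats.at[target_id, "bg_sd"])

    def __contains__(self, target_id: str) -> bool:
        return target_id in self.stats.index


@dataclass
class QcReport:
    per_cell: pd.DataFrame        # index well_id; n_rna_detected, culled
    median_before: float
    median_after: float


def _clip_ceiling(ct: pd.DataFrame, ceiling: float) -> pd.DataFrame:
    """NaN (never amplified) and values above the ceiling both become the ceiling."""
    return ct.fillna(ceiling).clip(upper=ceiling)


def estimate_protein_background(ct: CtTable, ct_ceiling: float = 24.0,
                                source: SampleType = SampleType.ZERO_CELL) -> BackgroundModel:
    """Mean/SD of background Ct per protein assay over zero-cell wells.

    Ct values above the ceiling — including the undetected sentinel — are
    clipped to the ceiling before averaging.
    """
    wells = ct.wells_of(source)
    if len(wells) < 2:
        if source is SampleType.ZERO_CELL:
            raise ValueError(
                "need at least 2 zero-cell wells to estimate protein background; "
                "supply lysis-buffer wells (source=SampleType.LYSIS_BUFFER) instead"
            )
        raise ValueError(f"need at least 2 {source.value} wells")
    prot = [t.target_id for t in ct.targets_of(Analyte.PROTEIN)]
    sub = _clip_ceiling(ct.ct.loc[[w.well_id for w in wells], prot], ct_ceiling)
    out = pd.DataFrame({
        "bg_mean": sub.mean(axis=0),
        "bg_sd": sub.std(axis=0, ddof=1),
        "n_wells": len(wells),
    })
    return BackgroundModel(stats=out, pooled_across_time=True)


def check_background_homogeneity(ct: CtTable, alpha: float = 0.05,
                                 ct_ceiling: float = 24.0) -> pd.DataFrame:
    """All-pairwise two-sample t-tests of zero-cell background Ct across time.

    Returns one row per protein target with the minimum pairwise p-value and a
    verdict: ``pool`` when every pair's p exceeds ``alpha``, else ``stratify``
    with the failing pair reported.  Pairs with fewer than 2 wells on either
    side are skipped with a warning.
    """
    zwells = ct.wells_of(SampleType.ZERO_CELL)
    tps = sorted({w.time_point_hr for w in zwells if w.time_point_hr is not None})
    if len(tps) < 2:
        raise ValueError("need zero-cell wells at >= 2 time points")
    prot = [t.target_id for t in ct.targets_of(Analyte.PROTEIN)]
    groups = {tp: [w.well_id for w in zwells if w.time_point_hr == tp] for tp in tps}

    records = []
    for tid in prot:
        min_p, worst_pair, verdict = 1.0, None, "pool"
        for i in range(len(tps)):
            for j in range(i + 1, len(tps)):
                a_ids, b_ids = groups[tps[i]], groups[tps[j]]
                if len(a_ids) < 2 or len(b_ids) < 2:
                    warnings.warn(f"skipping pair ({tps[i]}, {tps[j]}): fewer than 2 wells")
                    continue
                a = _clip_ceiling(ct.ct.loc[a_ids, [tid]], ct_ceiling)[tid].to_numpy()
                b = _clip_ceiling(ct.ct.loc[b_ids, [tid]], ct_ceiling)[tid].to_numpy()
                if np.var(a) == 0 and np.var(b) == 0:
                    p = 1.0 if np.mean(a) == np.mean(b) else 0.0
                else:
                    p = float(stats.ttest_ind(a, b).pvalue)
                if p < min_p:
                    min_p, worst_pair = p, (tps[i], tps[j])
                if p <= alpha:
                    verdict = "stratify"
        records.append({"target_id": tid, "min_p": min_p, "verdict": verdict,
                        "failing_pair": worst_pair if verdict == "stratify" else None})
    return pd.DataFrame(records).set_index("target_id")


def _delta(ct: pd.DataFrame, reference: pd.Series | float) -> pd.DataFrame:
    d = -ct.sub(reference, axis=1) if isinstance(reference, pd.Series) else reference - ct
    return d.clip(lower=0.0).fillna(0.0)


def rna_delta_ct(ct: CtTable, ct_ceiling: float = 24.0) -> DeltaCtTable:
    """``ΔCt = max(24 − Ct, 0)``; sentinel → 0."""
    rna = ct.targets_of(Analyte.RNA)
    mat = ct.ct[[t.target_id for t in rna]]
    return DeltaCtTable(wells=list(ct.wells), targets=rna, dct=_delta(mat, ct_ceiling))


def protein_delta_ct(ct: CtTable, bg: BackgroundModel, ct_ceiling: float = 24.0) -> DeltaCtTable:
    """Clip protein Ct to the ceiling, then ``ΔCt = max(bg_mean − Ct, 0)``."""
    prot = ct.targets_of(Analyte.PROTEIN)
    missing = [t.target_id for t in prot if t.target_id not in bg]
    if missing:
        raise ValueError(f"no background estimate for protein target(s): {missing}")
    mat = _clip_ceiling(ct.ct[[t.target_id for t in prot]], ct_ceiling)
    ref = bg.stats["bg_mean"].reindex([t.target_id for t in prot])
    return DeltaCtTable(wells=list(ct.wells), targets=prot, dct=_delta(mat, ref))


def dilution_delta_ct(ct: CtTable, ct_ceiling: float = 24.0) -> DeltaCtTable:
    """Reference dilution wells to mean lysis-buffer Ct (ceiling if undetected there)."""
    buf = [w.well_id for w in ct.wells_of(SampleType.LYSIS_BUFFER)]
    if not buf:
        raise ValueError("no lysis-buffer wells present")
    dil = ct.wells_of(SampleType.DILUTION)
    mat = ct.ct.loc[[w.well_id for w in dil]]
    ref = ct.ct.loc[buf].mean(axis=0)          # NaN if undetected in every buffer well
    ref = ref.fillna(ct_ceiling)
    return DeltaCtTable(wells=dil, targets=list(ct.targets), dct=_delta(mat, ref))


def combined_delta_ct(ct: CtTable, bg: BackgroundModel, ct_ceiling: float = 24.0) -> DeltaCtTable:
    """RNA + protein ΔCt side by side over the CELL wells."""
    cells = [w for w in ct.wells if w.sample_type is SampleType.CELL]
    cell_ids = [w.well_id for w in cells]
    rna = rna_delta_ct(ct, ct_ceiling)
    prot = protein_delta_ct(ct, bg, ct_ceiling)
    dct = pd.concat([rna.dct.loc[cell_ids], prot.dct.loc[cell_ids]], axis=1)
    targets = rna.targets + prot.targets
    dct = dct[[t.target_id for t in targets]]
    return DeltaCtTable(wells=cells, targets=targets, dct=dct)


def cull_cells(dct: DeltaCtTable, reliable_rna: list[str],
               min_detected: int = 35) -> tuple[DeltaCtTable, QcReport]:
    """Remove cells expressing fewer than ``min_detected`` reliable RNAs.

    Detection for culling is the literal ``ΔCt > 0``.
    """
    if not reliable_rna:
        raise ValueError("reliable_rna must be non-empty")
    cells = [w for w in dct.wells if w.sample_type is SampleType.CELL]
    cell_ids = [w.well_id for w in cells]
    counts = (dct.dct.loc[cell_ids, reliable_rna] > 0).sum(axis=1)
    culled = counts < min_detected
    if culled.all():
        raise ValueError(
            "all cells culled; detected-RNA counts: "
            f"min={counts.min()}, median={counts.median()}, max={counts.max()}"
        )
    report = QcReport(
        per_cell=pd.DataFrame({"n_rna_detected": counts, "culled": culled}),
        median_before=float(counts.median()),
        median_after=float(counts[~culled].median()),
    )
    kept = dct.subset_wells(counts.index[~culled])
    return kept, report
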