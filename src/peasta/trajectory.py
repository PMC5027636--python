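"""Quadrant gating of paired protein/RNA detection and trajectory clustering.

Every cell is binned, per gene measured as both protein and RNA, into one of
four joint-detection quadrants — P−R−, P−R+, P+R+, P+R− — using the
calibrated detection cutoff.  A gene's trajectory is the set of quadrant
proportions across time points; genes are clustered on these trajectories
with a ``1 − Spearman ρ`` distance, average linkage, and a flat cut at 0.75.

RNA assays have no zero-cell background wells, so RNA detection falls back to
the literal ``ΔCt > 0`` rule unless an RNA background (e.g. lysis-buffer
wells) supplies a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calibration import DetectionThreshold
from .core import Analyte, DeltaCtTable
from .correlation import spearman_rho

__all__ = ["QUADRANTS", "QuadrantProfile", "TrajectoryClustering",
           "quadrant_profiles", "cluster_trajectories"]

#: fixed quadrant order: (protein detected, RNA detected)
QUADRANTS = ("P-R-", "P-R+", "P+R+", "P+R-")


@dataclass
class QuadrantProfile:
    gene: str
    proportions: pd.DataFrame      # index time_point_hr; columns QUADRANTS
    counts: pd.DataFrame

    def as_vector(self) -> np.ndarray:
        """Concatenated (time ascending) × (fixed quadrant order) profile."""
        return self.proportions.sort_index().to_numpy().ravel()


@dataclass
class TrajectoryClustering:
    genes: list[str]
    distance: pd.DataFrame
    linkage: np.ndarray | None
    labels: pd.Series
    cut_height: float


def quadrant_profiles(dct: DeltaCtTable, genes: list[str] | None = None,
                      thresholds: dict[str, DetectionThreshold] | None = None,
                      ) -> list[QuadrantProfile]:
    """Per-gene, per-time-point proportions of cells in each detection quadrant.

    ``thresholds`` gives the calibrated cutoff per target; targets without an
    entry (RNA without background wells) use ΔCt > 0.
    """
    genes = dct.paired_genes() if genes is None else genes
    thresholds = thresholds or {}
    out = []
    for gene in genes:
        rna = [t.target_id for t in dct.targets_of(Analyte.RNA) if t.gene == gene]
        prot = [t.target_id for t in dct.targets_of(Analyte.PROTEIN) if t.gene == gene]
        if len(rna) != 1 or len(prot) != 1:
            warnings.warn(f"gene {gene!r} lacks a unique RNA/protein pair; skipped")
            continue
        rna_id, prot_id = rna[0], prot[0]
        thr_r = thresholds[rna_id].threshold_dct if rna_id in thresholds else 0.0
        thr_p = thresholds[prot_id].threshold_dct if prot_id in thresholds else 0.0
        props, counts = {}, {}
        for tp in dct.time_points():
            sub = dct.cells_at(tp)
            r_det = sub.dct[rna_id].to_numpy(dtype=float) > thr_r
            p_det = sub.dct[prot_id].to_numpy(dtype=float) > thr_p
            c = np.array([
                int((~p_det & ~r_det).sum()),
                int((~p_det & r_det).sum()),
                int((p_det & r_det).sum()),
                int((p_det & ~r_det).sum()),
            ])
            counts[tp] = c
            props[tp] = c / c.sum()
        out.append(QuadrantProfile(
            gene=gene,
            proportions=pd.DataFrame(props, index=QUADRANTS).T,
            counts=pd.DataFrame(counts, index=QUADRANTS).T,
        ))
    return out


def cluster_trajectories(profiles: list[QuadrantProfile],
                         cut_height: float = 0.75,
                         method: str = "average") -> TrajectoryClustering:
    """Cluster genes on their quadrant trajectories (distance ``1 − Spearman ρ``).

    A gene whose profile vector is constant has no defined rank correlation;
    it is assigned its own singleton cluster with a warning.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    genes = [p.gene for p in profiles]
    if len(profiles) == 1:
        return TrajectoryClustering(genes, pd.DataFrame([[0.0]], index=genes, columns=genes),
                                    None, pd.Series([1], index=genes, name="cluster"), cut_height)

    vectors = {p.gene: p.as_vector() for p in profiles}
    constant = [g for g, v in vectors.items() if np.ptp(v) == 0]
    for g in constant:
        warnings.warn(f"gene {g!r} has a constant quadrant profile; singleton cluster")
    active = [g for g in genes if g not in constant]

    n = len(active)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho = spearman_rho(vectors[active[i]], vectors[active[j]])
            dist[i, j] = dist[j, i] = 1.0 - rho

    if n >= 2:
        z = hierarchy.linkage(squareform(dist, checks=False), method=method)
        flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    elif n == 1:
        z, flat = None, np.array([1])
    else:
        z, flat = None, np.array([], dtype=int)

    labels = {}
    for g, lab in zip(active, flat):
        labels[g] = int(lab)
    next_label = int(flat.max()) + 1 if len(flat) else 1
    for g in constant:
        labels[g] = next_label
        next_label += 1

    full = pd.DataFrame(np.zeros((len(genes), len(genes))), index=genes, columns=genes)
    for i, gi in enumerate(active):
        for j, gj in enumerate(active):
            full.at[gi, gj] = dist[i, j]
    return TrajectoryClustering(
        genes=genes, distance=full, linkage=z,
        labels=pd.Series([labels[g] for g in genes], index=genes, name="cluster"),
        cut_height=cut_height,
    )
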