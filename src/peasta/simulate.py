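"""Synthetic Ct-table generator with known ground truth.

The generator emulates the measurement structure of a combined single-cell
protein (PEA) + RNA (STA) qPCR study:

* per-target **bimodal** single-cell expression — a fraction ``pi_detect`` of
  cells express the target, and expressing cells have ΔCt drawn from a normal
  truncated to ``(0, ct_ceiling]``;
* **RNA–protein coupling** per gene via a Gaussian copula on a latent scale:
  one latent bivariate standard normal per cell per paired gene, with
  correlation ``pair_rho``, drives both whether each analyte is detected
  (upper-tail event of mass ``pi_detect``) and, when detected, how high its
  ΔCt sits in the truncated-normal margin.  Margins stay exact while detection
  and level co-vary the way bimodal single-cell data do;
* **zero-cell background wells** for proteins (capture sites with no cell,
  which still amplify at the assay's background level);
* **dilution series** that are linear in log2 quantity inside a window, flat
  at background below it, and either saturated or declining ("hook" effect)
  above it, with lysis-buffer control wells.

ΔCt is generated first and Ct back-derived (RNA: ``Ct = ceiling − ΔCt``;
protein: ``Ct = bg_mean − ΔCt``), because the analysis operates on ΔCt and
generating there keeps the ground truth interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Analyte, CtTable, SampleType, Target, WellMeta

__all__ = [
    "TimePointExpression",
    "TargetGenParams",
    "BackgroundGenParams",
    "DilutionGenParams",
    "GroundTruth",
    "generate_single_cell_study",
    "generate_dilution_series",
    "study_like_params",
]

CT_CEILING = 24.0
_MIN_CT = 0.01  # Ct must be positive; back-conversion clips here

#: per-cell capture/lysis efficiency spread (logit units) used for the
#: study-scale conditions; individual C1 capture sites vary in how much of a
#: cell's content reaches the reaction, which spreads per-cell detected-RNA
#: counts enough that the 35-RNA cull removes a low tail of cells
STUDY_CELL_QUALITY_SD = 0.6


@dataclass(frozen=True)
class TimePointExpression:
    """Expression state of one target at one time point."""

    pi_detect: float          # fraction of cells expressing
    mu_dct: float             # mean ΔCt of expressing cells (cycles)
    sigma_dct: float          # SD of expressing cells' ΔCt (cycles)
    pair_rho: float = 0.0     # latent coupling to the paired analyte

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_detect <= 1.0:
            raise ValueError(f"pi_detect must be in [0, 1], got {self.pi_detect}")
        if self.sigma_dct <= 0:
            raise ValueError("sigma_dct must be positive")
        if not -1.0 <= self.pair_rho <= 1.0:
            raise ValueError("pair_rho must be in [-1, 1]")


@dataclass(frozen=True)
class TargetGenParams:
    target_id: str
    analyte: Analyte
    gene: str
    by_time: Mapping[float, TimePointExpression]

    def to_target(self) -> Target:
        return Target(self.target_id, self.analyte, self.gene)


@dataclass(frozen=True)
class BackgroundGenParams:
    """Protein background well model: Ct ~ Normal(bg_mean_ct, bg_sd_ct)."""

    bg_mean_ct: Mapping[str, float]          # per protein target
    bg_sd_ct: Mapping[str, float]
    n_zero_cell_wells: Mapping[float, int]   # per time point

    def __post_init__(self) -> None:
        bad = [t for t, s in self.bg_sd_ct.items() if s <= 0]
        if bad:
            raise ValueError(f"bg_sd_ct must be positive: {bad}")


@dataclass(frozen=True)
class DilutionGenParams:
    """Ground truth for one target's dilution standard curve.

    ``linear_lo``/``linear_hi`` are inclusive indices into ``quantities``
    (after sorting ascending) bounding the truly linear window.  Below the
    window mean ΔCt is 0 (background); above it the signal saturates at the
    window-top value, or declines with quantity when ``hook`` is set.
    """

    quantities: tuple[float, ...]
    slope: float = 1.0                 # cycles per doubling
    intercept: float = 0.0             # cycles at quantity 1
    noise_sd: float = 0.2              # replicate noise, cycles
    linear_lo: int = 0
    linear_hi: int | None = None       # None: window extends to the top level
    hook: bool = False
    hook_decline_factor: float = 1.0   # hook decline rate, in units of |slope|
    n_replicates: int = 8
    target_id: str = "TARGET_P"
    analyte: Analyte = Analyte.PROTEIN
    gene: str = "TARGET"
    bg_mean_ct: float = 23.0
    bg_sd_ct: float = 0.3

    def __post_init__(self) -> None:
        q = np.asarray(self.quantities, dtype=float)
        if len(q) < 3:
            raise ValueError("need at least 3 dilution quantities")
        d = np.diff(q)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("quantities must be strictly monotone")
        if np.any(q <= 0):
            raise ValueError("quantities must be positive")
        hi = len(q) - 1 if self.linear_hi is None else self.linear_hi
        if not 0 <= self.linear_lo <= hi <= len(q) - 1:
            raise ValueError("need 0 <= linear_lo <= linear_hi < n levels")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


@dataclass
class GroundTruth:
    """Everything needed to recompute the generated values."""

    seed: int
    target_params: tuple[TargetGenParams, ...] = ()
    background: BackgroundGenParams | None = None
    dilution: DilutionGenParams | None = None
    detected: pd.DataFrame | None = None   # cells × targets latent detection
    true_dct: pd.DataFrame | None = None   # cells × targets generated ΔCt


def _marginal_dct(u: np.ndarray, tp: TimePointExpression, ct_ceiling: float,
                  quality: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Map copula uniforms to (detected, ΔCt) for one target/time point.

    Detection is the upper ``pi_detect`` tail of ``u``; conditional on
    detection, the rescaled tail quantile feeds the truncated-normal inverse
    CDF, so a cell high in the latent variable is both more likely to be
    detected and, when detected, more highly expressed.  ``quality`` shifts
    each cell's detection probability on the logit scale (per-cell capture
    efficiency); with no quality term the marginal is exactly ``pi_detect``.
    """
    if quality is None or tp.pi_detect in (0.0, 1.0):
        pi = np.full_like(u, tp.pi_detect)
    else:
        logit = np.log(tp.pi_detect / (1.0 - tp.pi_detect))
        pi = 1.0 / (1.0 + np.exp(-(logit + quality)))
    detected = u > 1.0 - pi
    dct = np.zeros_like(u)
    if detected.any():
        v = (u[detected] - (1.0 - pi[detected])) / pi[detected]
        v = np.clip(v, 1e-12, 1.0 - 1e-12)
        a = (0.0 - tp.mu_dct) / tp.sigma_dct
        b = (ct_ceiling - tp.mu_dct) / tp.sigma_dct
        dct[detected] = stats.truncnorm.ppf(v, a, b, loc=tp.mu_dct, scale=tp.sigma_dct)
    return detected, dct


def generate_single_cell_study(
    params: Sequence[TargetGenParams],
    n_cells: Mapping[float, int],
    background: BackgroundGenParams,
    seed: int,
    ct_ceiling: float = CT_CEILING,
    cell_quality_sd: float = 0.0,
) -> tuple[CtTable, GroundTruth]:
    """Generate a full single-cell Ct table plus zero-cell background wells.

    ``cell_quality_sd`` > 0 draws one capture-quality value per cell and
    shifts every target's detection probability by it on the logit scale,
    emulating site-to-site variation in lysis/capture efficiency
    (:data:`STUDY_CELL_QUALITY_SD` for the study-scale conditions).
    """
    if not params:
        raise ValueError("need at least one target")
    if any(n < 1 for n in n_cells.values()):
        raise ValueError("need at least one cell per time point")
    rng = np.random.default_rng(seed)

    targets = [p.to_target() for p in params]
    by_id = {p.target_id: p for p in params}
    # paired genes: exactly one RNA and one protein target sharing the gene
    gene_groups: dict[str, list[TargetGenParams]] = {}
    for p in params:
        gene_groups.setdefault(p.gene, []).append(p)
    pairs = {g: ps for g, ps in gene_groups.items()
             if len(ps) == 2 and {ps[0].analyte, ps[1].analyte} == {Analyte.RNA, Analyte.PROTEIN}}

    wells: list[WellMeta] = []
    rows: list[np.ndarray] = []
    det_rows: list[np.ndarray] = []
    dct_rows: list[np.ndarray] = []
    tids = [t.target_id for t in targets]

    for t_hr in sorted(n_cells):
        n = n_cells[t_hr]
        qual = rng.normal(0.0, cell_quality_sd, n) if cell_quality_sd > 0 else None
        u = pd.DataFrame(index=range(n), columns=tids, dtype=float)
        for gene, ps in gene_groups.items():
            if gene in pairs:
                pa, pb = pairs[gene]
                rho_a = pa.by_time[t_hr].pair_rho
                rho_b = pb.by_time[t_hr].pair_rho
                rho = rho_a if rho_a != 0.0 else rho_b
                z1 = rng.standard_normal(n)
                z2 = rho * z1 + np.sqrt(max(1.0 - rho ** 2, 0.0)) * rng.standard_normal(n)
                u[pa.target_id] = stats.norm.cdf(z1)
                u[pb.target_id] = stats.norm.cdf(z2)
            else:
                for p in ps:
                    u[p.target_id] = stats.norm.cdf(rng.standard_normal(n))

        ct = np.full((n, len(tids)), np.nan)
        det = np.zeros((n, len(tids)), dtype=bool)
        dct = np.zeros((n, len(tids)))
        for j, tid in enumerate(tids):
            p = by_id[tid]
            tp = p.by_time[t_hr]
            detected, d = _marginal_dct(u[tid].to_numpy(), tp, ct_ceiling, qual)
            det[:, j] = detected
            dct[:, j] = d
            if p.analyte is Analyte.RNA:
                ref = ct_ceiling
            else:
                ref = background.bg_mean_ct[tid]
            ct[detected, j] = np.maximum(ref - d[detected], _MIN_CT)
        for i in range(n):
            wells.append(WellMeta(f"c{int(t_hr):02d}_{i:03d}", SampleType.CELL,
                                  time_point_hr=float(t_hr), n_cells_captured=1))
        rows.append(ct)
        det_rows.append(det)
        dct_rows.append(dct)

        # zero-cell wells: proteins amplify at background, RNAs stay undetected
        n_zero = background.n_zero_cell_wells.get(t_hr, 0)
        if n_zero:
            zct = np.full((n_zero, len(tids)), np.nan)
            for j, tid in enumerate(tids):
                if by_id[tid].analyte is Analyte.PROTEIN:
                    zct[:, j] = np.maximum(
                        rng.normal(background.bg_mean_ct[tid], background.bg_sd_ct[tid], n_zero),
                        _MIN_CT)
            for i in range(n_zero):
                wells.append(WellMeta(f"z{int(t_hr):02d}_{i:03d}", SampleType.ZERO_CELL,
                                      time_point_hr=float(t_hr), n_cells_captured=0))
            rows.append(zct)
            det_rows.append(np.zeros((n_zero, len(tids)), dtype=bool))
            dct_rows.append(np.zeros((n_zero, len(tids))))

    well_ids = [w.well_id for w in wells]
    ct_df = pd.DataFrame(np.vstack(rows), index=well_ids, columns=tids)
    truth = GroundTruth(
        seed=seed, target_params=tuple(params), background=background,
        detected=pd.DataFrame(np.vstack(det_rows), index=well_ids, columns=tids),
        true_dct=pd.DataFrame(np.vstack(dct_rows), index=well_ids, columns=tids),
    )
    return CtTable(wells=wells, targets=targets, ct=ct_df), truth


def true_dilution_means(params: DilutionGenParams) -> np.ndarray:
    """Noise-free mean ΔCt at each quantity level, in the given level order."""
    q = np.asarray(params.quantities, dtype=float)
    order = np.argsort(q)
    hi = len(q) - 1 if params.linear_hi is None else params.linear_hi
    lo = params.linear_lo
    q_asc = q[order]
    mean_asc = np.zeros(len(q))
    lin = params.intercept + params.slope * np.log2(q_asc)
    mean_asc[lo:hi + 1] = lin[lo:hi + 1]
    top = lin[hi]
    for k in range(hi + 1, len(q)):
        if params.hook:
            decline = params.hook_decline_factor * abs(params.slope)
            mean_asc[k] = top - decline * (np.log2(q_asc[k]) - np.log2(q_asc[hi]))
        else:
            mean_asc[k] = top
    mean_asc = np.maximum(mean_asc, 0.0)
    out = np.empty(len(q))
    out[order] = mean_asc
    return out


def generate_dilution_series(params: DilutionGenParams,
                             seed: int) -> tuple[CtTable, GroundTruth]:
    """Generate DILUTION replicate wells plus 8 lysis-buffer control wells."""
    rng = np.random.default_rng(seed)
    q = np.asarray(params.quantities, dtype=float)
    means = true_dilution_means(params)

    target = Target(params.target_id, params.analyte, params.gene)
    wells: list[WellMeta] = []
    ct_vals: list[float] = []

    ref = params.bg_mean_ct if params.analyte is Analyte.PROTEIN else CT_CEILING
    for lvl, (quantity, mean_dct) in enumerate(zip(q, means)):
        for r in range(params.n_replicates):
            noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
            dct = mean_dct + noise
            if params.analyte is Analyte.PROTEIN:
                # background always amplifies: signal at/below background still
                # produces a Ct near the background level
                ct = max(ref - dct, _MIN_CT)
            else:
                ct = ref - dct if dct > 0 else np.nan
            wells.append(WellMeta(f"d{lvl:02d}_r{r}", SampleType.DILUTION,
                                  dilution_quantity=float(quantity)))
            ct_vals.append(ct)
    for r in range(8):
        if params.analyte is Analyte.PROTEIN:
            bg = max(rng.normal(params.bg_mean_ct, params.bg_sd_ct), _MIN_CT)
        else:
            bg = np.nan   # RNA never amplifies in lysis buffer alone
        wells.append(WellMeta(f"lb_r{r}", SampleType.LYSIS_BUFFER))
        ct_vals.append(bg)

    ct_df = pd.DataFrame({params.target_id: ct_vals}, index=[w.well_id for w in wells])
    truth = GroundTruth(seed=seed, dilution=params)
    return CtTable(wells=wells, targets=[target], ct=ct_df), truth


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def study_like_params(
    seed: int = 0,
    n_rna: int = 89,
    n_protein: int = 27,
    time_points: Sequence[float] = (0.0, 24.0, 48.0),
    pair_rho: Mapping[float, float] | None = None,
    responder_fraction: float = 0.3,
) -> tuple[list[TargetGenParams], dict[float, int], BackgroundGenParams]:
    """Parameters emulating the study's retained assay panel.

    89 RNA and 27 protein assays, the 27 proteins each paired with one RNA;
    three time points (0/24/48 hr of stimulation) with 91/79/83 captured cells
    and 5/17/13 zero-cell wells.  Per-target detection fractions and
    expressing-cell means span realistic single-cell ranges.  A
    ``responder_fraction`` of RNAs — and a larger share of proteins, with
    larger shifts — respond to stimulation, each following one of three
    temporal profiles (ramp, early saturation, overshoot) so that every time
    point carries some distinguishing signal; the stimulated phenotype is
    easier to read out at the protein level.
    """
    rng = np.random.default_rng(seed)
    tps = list(time_points)
    if pair_rho is None:
        pair_rho = {tp: 0.3 for tp in tps}
    # temporal response profiles: fraction of the full shift realized at each
    # time point (ramp / early-saturating / overshoot-and-decay)
    profiles = [(0.0, 0.5, 1.0), (0.0, 1.0, 1.0), (0.0, 1.0, 0.5)]

    params: list[TargetGenParams] = []
    for i in range(n_rna):
        gene = f"G{i:03d}"
        base_pi = float(rng.uniform(0.25, 0.95))
        base_mu = float(rng.uniform(4.0, 12.0))
        sigma = float(rng.uniform(1.0, 2.0))
        responds = rng.random() < responder_fraction
        d_pi = float(rng.uniform(0.1, 0.2) * rng.choice([-1, 1])) if responds else 0.0
        d_mu = float(rng.uniform(0.5, 1.5) * rng.choice([-1, 1])) if responds else 0.0
        profile = profiles[int(rng.integers(len(profiles)))]
        by_time = {}
        for k, tp in enumerate(tps):
            frac = profile[min(k, len(profile) - 1)]
            by_time[tp] = TimePointExpression(
                pi_detect=float(np.clip(base_pi + d_pi * frac, 0.02, 0.99)),
                mu_dct=float(np.clip(base_mu + d_mu * frac, 1.0, 15.0)),
                sigma_dct=sigma,
                pair_rho=pair_rho[tp] if i < n_protein else 0.0,
            )
        params.append(TargetGenParams(f"G{i:03d}_R", Analyte.RNA, gene, by_time))

    bg_mean: dict[str, float] = {}
    bg_sd: dict[str, float] = {}
    for i in range(n_protein):
        gene = f"G{i:03d}"    # paired with RNA target of the same gene
        tid = f"G{i:03d}_P"
        # proteins are detected more consistently and vary less than RNA
        # (translation buffers transcriptional bursting), so their detection
        # fractions sit higher and their expressing-cell spread lower
        base_pi = float(rng.uniform(0.5, 0.95))
        base_mu = float(rng.uniform(3.0, 7.0))
        sigma = float(rng.uniform(0.5, 1.2))
        responds = rng.random() < min(2.5 * responder_fraction, 1.0)
        d_pi = float(rng.uniform(0.25, 0.45) * rng.choice([-1, 1])) if responds else 0.0
        d_mu = float(rng.uniform(1.5, 3.5) * rng.choice([-1, 1])) if responds else 0.0
        profile = profiles[int(rng.integers(len(profiles)))]
        by_time = {}
        for k, tp in enumerate(tps):
            frac = profile[min(k, len(profile) - 1)]
            by_time[tp] = TimePointExpression(
                pi_detect=float(np.clip(base_pi + d_pi * frac, 0.02, 0.99)),
                mu_dct=float(np.clip(base_mu + d_mu * frac, 0.5, 10.0)),
                sigma_dct=sigma,
                pair_rho=pair_rho[tp],
            )
        params.append(TargetGenParams(tid, Analyte.PROTEIN, gene, by_time))
        bg_mean[tid] = float(rng.uniform(20.0, 23.0))
        bg_sd[tid] = float(rng.uniform(0.2, 0.6))

    n_cells = dict(zip(tps, (91, 79, 83)))
    n_zero = dict(zip(tps, (5, 17, 13)))
    background = BackgroundGenParams(bg_mean_ct=bg_mean, bg_sd_ct=bg_sd,
                                     n_zero_cell_wells=n_zero)
    return params, n_cells, background
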