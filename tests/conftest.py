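import numpy as np
import pandas as pd
import pytest

from peasta.core import (Analyte, CtTable, DeltaCtTable, SampleType, Target,
                         WellMeta)
from peasta.simulate import (BackgroundGenParams, TargetGenParams,
                             TimePointExpression, generate_single_cell_study,
                             study_like_params)


def make_delta_table(values: dict[str, list[float]],
                     analytes: dict[str, str] | None = None,
                     genes: dict[str, str] | None = None,
                     time_points: list[float] | None = None) -> DeltaCtTable:
    """Build a cells × targets ΔCt table from plain lists."""
    n = len(next(iter(values.values())))
    tps = time_points if time_points is not None else [0.0] * n
    wells = [WellMeta(f"c{i:03d}", SampleType.CELL, time_point_hr=tps[i],
                      n_cells_captured=1) for i in range(n)]
    targets = []
    for tid in values:
        analyte = (analytes or {}).get(tid, "RNA" if tid.endswith("_R") else "PROTEIN")
        gene = (genes or {}).get(tid, tid.rsplit("_", 1)[0])
        targets.append(Target(tid, Analyte(analyte), gene))
    dct = pd.DataFrame(values, index=[w.well_id for w in wells], dtype=float)
    return DeltaCtTable(wells=wells, targets=targets, dct=dct)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study: 12 RNA + 5 protein targets (5 paired genes),
    40 cells at each of three time points, plus zero-cell background wells."""
    params, _, bg = study_like_params(seed=0, n_rna=12, n_protein=5)
    ct, truth = generate_single_cell_study(
        params, {0.0: 40, 24.0: 40, 48.0: 40}, bg, seed=11)
    return ct, truth


@pytest.fixture(scope="session")
def small_dct(small_study):
    from peasta import preprocess
    ct, _ = small_study
    bg = preprocess.estimate_protein_background(ct)
    return preprocess.combined_delta_ct(ct, bg), bg


def coupled_pair_params(pair_rho: float, pi: float = 0.6, mu: float = 8.0,
                        sigma: float = 1.5, time_points=(0.0,)):
    """One RNA/protein pair with a given latent coupling, for copula tests."""
    by_time_r = {tp: TimePointExpression(pi, mu, sigma, pair_rho) for tp in time_points}
    by_time_p = {tp: TimePointExpression(pi, mu, sigma, pair_rho) for tp in time_points}
    params = [
        TargetGenParams("X_R", Analyte.RNA, "X", by_time_r),
        TargetGenParams("X_P", Analyte.PROTEIN, "X", by_time_p),
    ]
    bg = BackgroundGenParams(bg_mean_ct={"X_P": 22.0}, bg_sd_ct={"X_P": 0.4},
                             n_zero_cell_wells={tp: 0 for tp in time_points})
    return params, bg
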