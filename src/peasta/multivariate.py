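"""Standardized PCA and one-vs-rest time-point classification.

Each target is z-scored before PCA so protein and RNA assays contribute on an
equal footing.  Time-point labels are predicted from the full set of PC
scores by a random forest trained on a bootstrap draw of four-fifths of the
cells (drawn with replacement); the cells never drawn form the test set, on
which per-class one-vs-rest ROC curves and AUCs are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve

from .core import DeltaCtTable, SampleType

__all__ = [
    "PcaResult",
    "ClassifierEvaluation",
    "pca_standardized",
    "rf_timepoint_classifier",
    "target_pc_correlation",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame             # cells × components
    loadings: pd.DataFrame           # targets × components
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ClassifierEvaluation:
    auc_by_class: dict[float, float]            # NaN when class absent from test set
    roc_by_class: dict[float, pd.DataFrame]
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    undefined_classes: list[float] = field(default_factory=list)


def pca_standardized(dct: DeltaCtTable, target_subset: list[str] | None = None) -> PcaResult:
    """Per-target z-scoring followed by PCA via SVD.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are deterministic across SVD implementations.
    """
    cells = dct.cells_at(None)
    ids = target_subset if target_subset is not None else cells.target_ids
    mat = cells.dct[ids].to_numpy(dtype=float)
    if mat.shape[0] < 3 or mat.shape[1] < 2:
        raise ValueError("need >= 3 cells and >= 2 targets")

    sd = mat.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all targets constant; nothing to decompose")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance target(s)")
    ids = [t for t, k in zip(ids, keep) if k]
    z = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic signs
    flips = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flips[:, None]
    u = u * flips[None, :]
    scores = u * s
    var_frac = s ** 2 / (s ** 2).sum()
    comp = [f"PC{i+1}" for i in range(len(s))]
    cell_ids = [w.well_id for w in cells.wells]
    return PcaResult(
        scores=pd.DataFrame(scores, index=cell_ids, columns=comp),
        loadings=pd.DataFrame(vt.T, index=ids, columns=comp),
        variance_fraction=var_frac,
    )


def rf_timepoint_classifier(pca: PcaResult, labels: pd.Series,
                            train_fraction: float = 0.8, seed: int = 0,
                            n_trees: int = 500,
                            deterministic_split: bool = False) -> ClassifierEvaluation:
    """Random forest over all PC scores with a bootstrap train / out-of-bag test.

    The training indices are ``ceil(train_fraction · n)`` draws *with
    replacement*; cells never drawn form the test set (its size is therefore
    random).  ``deterministic_split`` switches to a plain shuffled
    train/test split of the same fraction.
    """
    labels = labels.reindex(pca.scores.index)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    if (counts < 10).any():
        raise ValueError("need >= 10 cells per class")

    rng = np.random.default_rng(seed)
    n = len(labels)
    idx = np.arange(n)
    if deterministic_split:
        perm = rng.permutation(n)
        n_train = int(np.ceil(train_fraction * n))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        n_train = int(np.ceil(train_fraction * n))
        train_idx = rng.choice(idx, size=n_train, replace=True)
        test_idx = np.setdiff1d(idx, np.unique(train_idx))
    if len(test_idx) == 0:
        raise ValueError("bootstrap draw covered every cell; no test set")

    x = pca.scores.to_numpy()
    y = labels.to_numpy()
    clf = RandomForestClassifier(n_estimators=n_trees, max_depth=None,
                                 random_state=int(rng.integers(2 ** 31)))
    clf.fit(x[train_idx], y[train_idx])
    prob = clf.predict_proba(x[test_idx])

    auc_by, roc_by, undefined = {}, {}, []
    y_test = y[test_idx]
    for cls in classes:
        if cls not in clf.classes_ or (y_test == cls).sum() == 0 or (y_test != cls).sum() == 0:
            auc_by[cls] = float("nan")
            undefined.append(cls)
            continue
        col = list(clf.classes_).index(cls)
        fpr, tpr, thr = roc_curve(y_test == cls, prob[:, col])
        auc_by[cls] = float(auc(fpr, tpr))
        roc_by[cls] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    cell_ids = list(pca.scores.index)
    return ClassifierEvaluation(
        auc_by_class=auc_by, roc_by_class=roc_by,
        train_ids=[cell_ids[i] for i in np.unique(train_idx)],
        test_ids=[cell_ids[i] for i in test_idx],
        seed=seed, undefined_classes=undefined,
    )


def target_pc_correlation(dct: DeltaCtTable, target_id: str, pca: PcaResult,
                          n_components: int = 2) -> pd.Series:
    """Spearman ρ of a target's ΔCt vector against each leading PC score."""
    cells = dct.cells_at(None)
    vals = cells.dct.loc[pca.scores.index, target_id].to_numpy(dtype=float)
    out = {}
    for comp in pca.scores.columns[:n_components]:
        sc = pca.scores[comp].to_numpy()
        if np.ptp(vals) == 0:
            out[comp] = float("nan")
        else:
            out[comp] = float(stats.spearmanr(vals, sc).statistic)
    return pd.Series(out, name=target_id)
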