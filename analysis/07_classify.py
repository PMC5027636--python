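#!/usr/bin/env python
"""Time-point classification from standardized PCA scores.

Runs PCA on the protein, RNA and combined ΔCt matrices, trains a random
forest on a bootstrap four-fifths of the cells, and evaluates one-vs-rest
ROC/AUC per time point on the out-of-bag cells.  Writes pca_variance.csv and
auc.csv under results/classification/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from peasta import multivariate
from peasta.core import Analyte, read_delta_ct_table, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=ROOT / "results" / "preprocessed")
    ap.add_argument("--out-dir", type=Path,
                    default=ROOT / "results" / "classification")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-splits", type=int, default=5,
                    help="bootstrap splits to average AUC over")
    args = ap.parse_args()

    dct = read_delta_ct_table(args.in_dir / "dct.csv", args.in_dir / "wells.csv",
                              args.in_dir / "targets.csv")
    labels = pd.Series({w.well_id: w.time_point_hr for w in dct.wells})
    rng = np.random.default_rng(args.seed)

    subsets = {
        "protein": [t.target_id for t in dct.targets_of(Analyte.PROTEIN)],
        "rna": [t.target_id for t in dct.targets_of(Analyte.RNA)],
        "both": dct.target_ids,
    }
    var_rows, auc_rows = [], []
    for name, ids in subsets.items():
        pca = multivariate.pca_standardized(dct, ids)
        var_rows.append({"subset": name,
                         "pc1": pca.variance_fraction[0],
                         "pc2": pca.variance_fraction[1]})
        collected: dict[float, list[float]] = {tp: [] for tp in dct.time_points()}
        for _ in range(args.n_splits):
            ev = multivariate.rf_timepoint_classifier(
                pca, labels, 0.8, seed=int(rng.integers(2 ** 31)))
            for tp, a in ev.auc_by_class.items():
                if not np.isnan(a):
                    collected[tp].append(a)
        means = {tp: float(np.mean(v)) for tp, v in collected.items()}
        for tp, a in means.items():
            auc_rows.append({"subset": name, "time_point_hr": tp, "auc": a})
        pretty = ", ".join(f"{a:.2f} at {int(tp)} hr" for tp, a in sorted(means.items()))
        print(f"{name:>7}: one-vs-rest AUC {pretty} "
              f"(PC1 carries {pca.variance_fraction[0]:.0%} of variance)")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame(var_rows).set_index("subset"),
                args.out_dir / "pca_variance.csv")
    write_table(pd.DataFrame(auc_rows).set_index("subset"), args.out_dir / "auc.csv")


if __name__ == "__main__":
    main()
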