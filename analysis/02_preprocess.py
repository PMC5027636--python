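#!/usr/bin/env python
"""Normalize Ct to ΔCt and cull low-quality cells.

Estimates each protein assay's background from zero-cell wells (pooling
across time points after the pairwise t-test homogeneity check), applies the
RNA (24 − Ct) and protein (background − Ct) ΔCt rules, and removes cells
expressing fewer than 35 RNAs.  Writes dct.csv, background.csv and
qc_report.csv under results/preprocessed/.
"""

import argparse
from pathlib import Path

from peasta import preprocess
from peasta.core import Analyte, read_ct_table, write_delta_ct_table, write_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=ROOT / "results" / "simulated")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "preprocessed")
    ap.add_argument("--min-detected", type=int, default=35)
    args = ap.parse_args()

    ct = read_ct_table(args.in_dir / "ct.csv", args.in_dir / "wells.csv",
                       args.in_dir / "targets.csv")
    verdicts = preprocess.check_background_homogeneity(ct)
    n_stratify = (verdicts.verdict == "stratify").sum()
    print(f"background homogeneity: {len(verdicts) - n_stratify}/{len(verdicts)} "
          f"protein assays pool across time points")

    bg = preprocess.estimate_protein_background(ct)
    dct = preprocess.combined_delta_ct(ct, bg)
    rna_ids = [t.target_id for t in dct.targets_of(Analyte.RNA)]
    kept, qc = preprocess.cull_cells(dct, rna_ids, args.min_detected)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_table(bg.stats, args.out_dir / "background.csv")
    write_table(verdicts.drop(columns="failing_pair"), args.out_dir / "homogeneity.csv")
    write_table(qc.per_cell, args.out_dir / "qc_report.csv")
    write_delta_ct_table(kept, args.out_dir / "dct.csv",
                         args.out_dir / "wells.csv", args.out_dir / "targets.csv")

    n_culled = int(qc.per_cell.culled.sum())
    print(f"median RNAs detected per cell: {qc.median_before:.0f} before cull, "
          f"{qc.median_after:.0f} after")
    print(f"culled {n_culled}/{len(qc.per_cell)} cells (<{args.min_detected} RNAs); "
          f"retained per time point: "
          f"{ {tp: len(kept.cells_at(tp).wells) for tp in kept.time_points()} }")


if __name__ == "__main__":
    main()
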