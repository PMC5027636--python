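#!/usr/bin/env python
"""Convert a supplementary spreadsheet export to the canonical CSV layout.

Published single-cell qPCR tables usually ship as spreadsheet sheets with
wells as rows and assays as columns but without machine-readable well or
assay metadata.  This converter extracts the Ct matrix into ``ct.csv`` and
emits *template* ``wells.csv`` / ``targets.csv`` files with the metadata
columns the pipeline needs (sample_type, time_point_hr, n_cells_captured,
dilution_quantity; analyte, gene), inferring what it can from naming
conventions (``*_P`` protein / ``*_R`` RNA suffixes).  The templates must be
reviewed and completed by hand before running the pipeline — sample types
and time points are typically encoded only in well names or figure legends.

Usage:
    python scripts/convert_supplementary.py TABLE.xlsx --sheet "Ct values" \
        --out-dir data/study
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd


def infer_targets(columns: list[str]) -> pd.DataFrame:
    rows = []
    for c in columns:
        if c.endswith("_P"):
            analyte, gene = "PROTEIN", c[:-2].split(".")[0]
        elif c.endswith("_R"):
            analyte, gene = "RNA", c[:-2].split(".")[0]
        else:
            analyte, gene = "FIXME", c
        rows.append({"target_id": c, "analyte": analyte, "gene": gene})
    return pd.DataFrame(rows).set_index("target_id")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table", type=Path, help="xlsx or csv export, wells x assays")
    ap.add_argument("--sheet", default=0, help="sheet name or index for xlsx")
    ap.add_argument("--out-dir", type=Path, default=Path("data/converted"))
    args = ap.parse_args()

    if args.table.suffix.lower() in (".xlsx", ".xls"):
        mat = pd.read_excel(args.table, sheet_name=args.sheet, index_col=0)
    else:
        mat = pd.read_csv(args.table, index_col=0)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    mat.to_csv(args.out_dir / "ct.csv")

    wells = pd.DataFrame({
        "well_id": mat.index.astype(str),
        "sample_type": "FIXME(CELL|ZERO_CELL|LYSIS_BUFFER|DILUTION)",
        "time_point_hr": "",
        "n_cells_captured": "",
        "dilution_quantity": "",
    }).set_index("well_id")
    wells.to_csv(args.out_dir / "wells.csv")
    infer_targets(list(mat.columns)).to_csv(args.out_dir / "targets.csv")
    print(f"wrote ct.csv and metadata templates to {args.out_dir}; "
          "edit the FIXME fields before running the pipeline")


if __name__ == "__main__":
    main()
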