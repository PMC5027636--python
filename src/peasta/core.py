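"""Domain types, table I/O and study configuration.

The working units of the pipeline are two wells-by-assays matrices:

* :class:`CtTable` — raw cycle-threshold (Ct) values exported from a
  Biomark-style qPCR run, with undetected reactions stored as NaN (never the
  instrument's ``999`` sentinel, which must not participate in arithmetic);
* :class:`DeltaCtTable` — nonnegative background/ceiling-referenced ΔCt values
  on a log2 abundance scale, where 0 encodes undetected.

Everything downstream consumes these two containers; no later stage re-reads
raw files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Analyte",
    "SampleType",
    "Target",
    "WellMeta",
    "CtTable",
    "DeltaCtTable",
    "StudyConfig",
    "TableFormatError",
    "read_ct_table",
    "read_delta_ct_table",
    "write_table",
    "write_ct_table",
    "write_delta_ct_table",
]

#: strings in raw exports that mean "reaction never crossed threshold"
UNDETECTED_STRINGS = {"999", "999.0", "undetermined", "undetected", "na", "nan", ""}


class TableFormatError(ValueError):
    """Raised when an input table is malformed or inconsistent."""


class Analyte(str, enum.Enum):
    RNA = "RNA"
    PROTEIN = "PROTEIN"


class SampleType(str, enum.Enum):
    CELL = "CELL"
    ZERO_CELL = "ZERO_CELL"
    LYSIS_BUFFER = "LYSIS_BUFFER"
    DILUTION = "DILUTION"


@dataclass(frozen=True)
class Target:
    """One qPCR assay (e.g. ``MET_P`` for protein, ``MET.5_R`` for RNA).

    Paired RNA/protein assays share the ``gene`` label; ``reliable`` is set by
    the calibration stage once dilution-series behaviour has been assessed.
    """

    target_id: str
    analyte: Analyte
    gene: str
    reliable: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))


@dataclass(frozen=True)
class WellMeta:
    """Metadata for one reaction chamber / capture site."""

    well_id: str
    sample_type: SampleType
    time_point_hr: float | None = None
    n_cells_captured: int = 0
    dilution_quantity: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_type", SampleType(self.sample_type))
        st = self.sample_type
        if st is SampleType.CELL and self.n_cells_captured != 1:
            raise TableFormatError(
                f"well {self.well_id!r}: CELL wells must have n_cells_captured == 1"
            )
        if st is SampleType.ZERO_CELL and self.n_cells_captured != 0:
            raise TableFormatError(
                f"well {self.well_id!r}: ZERO_CELL wells must have n_cells_captured == 0"
            )
        if st is SampleType.DILUTION:
            if self.dilution_quantity is None or not self.dilution_quantity > 0:
                raise TableFormatError(
                    f"well {self.well_id!r}: DILUTION wells need a positive dilution_quantity"
                )


def _check_axes(matrix: pd.DataFrame, wells: Sequence[WellMeta], targets: Sequence[Target]) -> None:
    well_ids = [w.well_id for w in wells]
    target_ids = [t.target_id for t in targets]
    if len(set(well_ids)) != len(well_ids):
        raise TableFormatError("duplicate well_id in well metadata")
    if len(set(target_ids)) != len(target_ids):
        raise TableFormatError("duplicate target_id in target metadata")
    if list(matrix.index) != well_ids:
        missing = sorted(set(well_ids) ^ set(matrix.index))
        raise TableFormatError(f"well axis mismatch between matrix and metadata: {missing[:5]}")
    if list(matrix.columns) != target_ids:
        missing = sorted(set(target_ids) ^ set(matrix.columns))
        raise TableFormatError(f"target axis mismatch between matrix and metadata: {missing[:5]}")


@dataclass
class _AssayTable:
    wells: list[WellMeta]
    targets: list[Target]

    # -- axis helpers shared by Ct and ΔCt tables ------------------------------
    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]

    @property
    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    def targets_of(self, analyte: Analyte | str) -> list[Target]:
        analyte = Analyte(analyte)
        return [t for t in self.targets if t.analyte is analyte]

    def wells_of(self, sample_type: SampleType | str, time_point_hr: float | None = None) -> list[WellMeta]:
        sample_type = SampleType(sample_type)
        out = [w for w in self.wells if w.sample_type is sample_type]
        if time_point_hr is not None:
            out = [w for w in out if w.time_point_hr == time_point_hr]
        return out

    def time_points(self) -> list[float]:
        tps = sorted({w.time_point_hr for w in self.wells
                      if w.sample_type is SampleType.CELL and w.time_point_hr is not None})
        return tps

    def target(self, target_id: str) -> Target:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(target_id)

    def paired_genes(self) -> list[str]:
        """Genes measured by both an RNA and a protein assay."""
        rna = {t.gene for t in self.targets_of(Analyte.RNA)}
        prot = {t.gene for t in self.targets_of(Analyte.PROTEIN)}
        return sorted(rna & prot)


@dataclass
class CtTable(_AssayTable):
    """Raw wells × assays Ct matrix; NaN marks a reaction that never amplified."""

    ct: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_axes(self.ct, self.wells, self.targets)
        vals = self.ct.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise TableFormatError("Ct values must be positive or undetected")

    def subset_wells(self, keep: Iterable[str]) -> "CtTable":
        keep = list(keep)
        wells = [w for w in self.wells if w.well_id in set(keep)]
        return CtTable(wells=wells, targets=list(self.targets), ct=self.ct.loc[[w.well_id for w in wells]])


@dataclass
class DeltaCtTable(_AssayTable):
    """Cells × targets ΔCt matrix on the log2 scale; 0 encodes undetected."""

    dct: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_axes(self.dct, self.wells, self.targets)
        if (self.dct.to_numpy(dtype=float) < 0).any():
            raise TableFormatError("ΔCt values must be nonnegative")

    def subset_wells(self, keep: Iterable[str]) -> "DeltaCtTable":
        keep_set = set(keep)
        wells = [w for w in self.wells if w.well_id in keep_set]
        return DeltaCtTable(wells=wells, targets=list(self.targets),
                            dct=self.dct.loc[[w.well_id for w in wells]])

    def subset_targets(self, keep: Iterable[str]) -> "DeltaCtTable":
        keep_set = set(keep)
        targets = [t for t in self.targets if t.target_id in keep_set]
        return DeltaCtTable(wells=list(self.wells), targets=targets,
                            dct=self.dct[[t.target_id for t in targets]])

    def cells_at(self, time_point_hr: float | None = None) -> "DeltaCtTable":
        wells = self.wells_of(SampleType.CELL, time_point_hr)
        return self.subset_wells(w.well_id for w in wells)

    def values_for(self, target_id: str, time_point_hr: float | None = None) -> np.ndarray:
        sub = self.cells_at(time_point_hr)
        return sub.dct[target_id].to_numpy(dtype=float)


@dataclass
class StudyConfig:
    """All tunable constants of the analysis, with the study's defaults.

    ``ct_ceiling`` (24 cycles) caps every Ct; ``cull_min_detected_rna`` (35)
    is the minimum number of reliable RNAs a cell must express to survive QC;
    ``detection_alpha`` (0.01) is the probability a signal is background;
    ``range_cost`` (0.03 per removed point) penalizes shrinking the dilution
    window; the LOD calls a quantity detected when ``lod_min_detected`` of
    ``lod_replicates`` replicates pass; ``single_cell_equivalents`` (1.3) is
    the physiological quantity a reliable probe's window must include.
    """

    ct_ceiling: float = 24.0
    cull_min_detected_rna: int = 35
    detection_alpha: float = 0.01
    range_cost: float = 0.03
    lod_min_detected: int = 7
    lod_replicates: int = 8
    single_cell_equivalents: float = 1.3
    n_permutations: int = 10_000
    edge_rho_threshold: float = 0.3
    trajectory_cut: float = 0.75
    train_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.detection_alpha < 1:
            raise ValueError("detection_alpha must be in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lod_min_detected > self.lod_replicates:
            raise ValueError("lod_min_detected cannot exceed lod_replicates")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# I/O — canonical CSV layout: one matrix CSV (wells as rows, targets as
# columns) plus two metadata CSVs.
# ---------------------------------------------------------------------------

def _parse_ct_cell(raw: object, row: str, col: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s.lower() in UNDETECTED_STRINGS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise TableFormatError(f"non-numeric Ct at well {row!r}, target {col!r}: {raw!r}") from None


def _read_well_meta(path: str | Path) -> list[WellMeta]:
    df = pd.read_csv(path, dtype={"well_id": str})
    required = {"well_id", "sample_type"}
    if not required <= set(df.columns):
        raise TableFormatError(f"well metadata must have columns {sorted(required)}")
    wells = []
    for rec in df.to_dict("records"):
        tp = rec.get("time_point_hr")
        dq = rec.get("dilution_quantity")
        wells.append(WellMeta(
            well_id=str(rec["well_id"]),
            sample_type=SampleType(rec["sample_type"]),
            time_point_hr=None if tp is None or pd.isna(tp) else float(tp),
            n_cells_captured=int(rec.get("n_cells_captured", 0) or 0),
            dilution_quantity=None if dq is None or pd.isna(dq) else float(dq),
        ))
    return wells


def _read_target_meta(path: str | Path) -> list[Target]:
    df = pd.read_csv(path, dtype=str)
    required = {"target_id", "analyte", "gene"}
    if not required <= set(df.columns):
        raise TableFormatError(f"target metadata must have columns {sorted(required)}")
    out = []
    for rec in df.to_dict("records"):
        rel = rec.get("reliable")
        out.append(Target(
            target_id=rec["target_id"], analyte=Analyte(rec["analyte"]),
            gene=rec["gene"],
            reliable=None if rel is None or pd.isna(rel) else str(rel).lower() == "true",
        ))
    return out


def read_ct_table(path: str | Path, well_meta_path: str | Path,
                  target_meta_path: str | Path) -> CtTable:
    """Load and validate a raw Ct matrix with its well and target metadata.

    Sentinel entries (``999``, ``Undetermined``, empty cells) become NaN,
    counted as undetected downstream.
    """
    wells = _read_well_meta(well_meta_path)
    targets = _read_target_meta(target_meta_path)
    raw = pd.read_csv(path, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)

    well_ids = {w.well_id for w in wells}
    matrix_ids = set(raw.index)
    if well_ids != matrix_ids:
        missing = sorted(well_ids ^ matrix_ids)
        raise TableFormatError(f"wells present in only one of matrix/metadata: {missing[:5]}")
    target_ids = {t.target_id for t in targets}
    if target_ids != set(raw.columns):
        missing = sorted(target_ids ^ set(raw.columns))
        raise TableFormatError(f"targets present in only one of matrix/metadata: {missing[:5]}")

    parsed = pd.DataFrame(
        [[_parse_ct_cell(raw.at[w, t], w, t) for t in raw.columns] for w in raw.index],
        index=raw.index, columns=raw.columns, dtype=float,
    )
    # order matrix to match metadata order
    parsed = parsed.loc[[w.well_id for w in wells], [t.target_id for t in targets]]
    return CtTable(wells=wells, targets=targets, ct=parsed)


def read_delta_ct_table(path: str | Path, well_meta_path: str | Path,
                        target_meta_path: str | Path) -> DeltaCtTable:
    wells = _read_well_meta(well_meta_path)
    targets = _read_target_meta(target_meta_path)
    mat = pd.read_csv(path, index_col=0)
    mat.index = mat.index.astype(str)
    mat = mat.loc[[w.well_id for w in wells], [t.target_id for t in targets]].astype(float)
    return DeltaCtTable(wells=wells, targets=targets, dct=mat)


def write_table(table: pd.DataFrame, path: str | Path, float_format: str = "%.6f") -> None:
    """Write a tabular result as CSV with a header and deterministic columns."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    if table.empty:
        raise ValueError(f"refusing to write empty table to {path}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, float_format=float_format)


def _write_meta(table: _AssayTable, well_meta_path: str | Path, target_meta_path: str | Path) -> None:
    wdf = pd.DataFrame([{
        "well_id": w.well_id, "sample_type": w.sample_type.value,
        "time_point_hr": w.time_point_hr, "n_cells_captured": w.n_cells_captured,
        "dilution_quantity": w.dilution_quantity,
    } for w in table.wells]).set_index("well_id")
    tdf = pd.DataFrame([{
        "target_id": t.target_id, "analyte": t.analyte.value, "gene": t.gene,
        "reliable": t.reliable,
    } for t in table.targets]).set_index("target_id")
    write_table(wdf, well_meta_path)
    write_table(tdf, target_meta_path)


def write_ct_table(table: CtTable, path: str | Path, well_meta_path: str | Path,
                   target_meta_path: str | Path) -> None:
    write_table(table.ct, path)
    _write_meta(table, well_meta_path, target_meta_path)


def write_delta_ct_table(table: DeltaCtTable, path: str | Path, well_meta_path: str | Path,
                         target_meta_path: str | Path) -> None:
    write_table(table.dct, path)
    _write_meta(table, well_meta_path, target_meta_path)
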