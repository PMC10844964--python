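"""Reading and writing per-cell segmentation tables and clinical tables.

Cell tables follow a configurable CSV dialect modelled on common
single-cell segmentation exports (one row per segmented cell, per-marker
mean-intensity columns).  Clinical tables carry patient follow-up.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TissueClass",
    "CellRecord",
    "SurvivalRecord",
    "TableDialect",
    "CellTableFormatError",
    "read_cell_table",
    "write_cell_table",
    "filter_by_confidence",
    "read_clinical_table",
    "write_clinical_table",
]


class TissueClass(str, enum.Enum):
    """Tissue compartment of a segmented cell."""

    EPI_TUMOR = "EPI_TUMOR"
    STROMA = "STROMA"
    OTHER = "OTHER"


class CellTableFormatError(ValueError):
    """Raised when a cell or clinical table violates its dialect contract."""


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell.

    Coordinates are Cartesian micrometres.  ``intensities`` holds the
    per-cell mean intensity for every configured marker.  ``confidence``
    is the classifier confidence in [0, 1].
    """

    sample_id: str
    cell_id: str
    x_um: float
    y_um: float
    tissue_class: TissueClass
    intensities: Mapping[str, float]
    confidence: float
    phenotype: str | None = None
    cell_area_um2: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise ValueError(f"cell {self.cell_id}: non-finite coordinates")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"cell {self.cell_id}: confidence {self.confidence} outside [0, 1]"
            )
        if self.cell_area_um2 is not None and self.cell_area_um2 <= 0:
            raise ValueError(f"cell {self.cell_id}: non-positive cell area")


@dataclass(frozen=True)
class SurvivalRecord:
    """Patient follow-up: time in months and death indicator."""

    patient_id: str
    time: float
    event: bool
    sample_ids: tuple[str, ...] = ()
    strata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"patient {self.patient_id}: non-positive time {self.time}")


# Default tissue-label vocabulary; unknown labels map to OTHER.
_DEFAULT_TISSUE_MAP = {
    "tumor": TissueClass.EPI_TUMOR,
    "tumour": TissueClass.EPI_TUMOR,
    "epithelium": TissueClass.EPI_TUMOR,
    "epi": TissueClass.EPI_TUMOR,
    "epi_tumor": TissueClass.EPI_TUMOR,
    "stroma": TissueClass.STROMA,
    "other": TissueClass.OTHER,
}


@dataclass(frozen=True)
class TableDialect:
    """Column map and unit scale for a cell-table CSV dialect.

    ``um_per_unit`` converts stored coordinates to micrometres (1.0 when
    coordinates are already in µm; e.g. 0.5 for 0.5 µm/px pixel tables).
    ``confidence_percent`` marks dialects that store confidence as 0-100.
    """

    sample_col: str = "Sample Name"
    cell_id_col: str = "Cell ID"
    x_col: str = "Cell X Position"
    y_col: str = "Cell Y Position"
    tissue_col: str = "Tissue Category"
    confidence_col: str = "Confidence"
    phenotype_col: str | None = "Phenotype"
    cell_area_col: str | None = None
    marker_cols: Mapping[str, str] = field(default_factory=dict)
    um_per_unit: float = 1.0
    confidence_percent: bool = False
    tissue_label_map: Mapping[str, TissueClass] = field(
        default_factory=lambda: dict(_DEFAULT_TISSUE_MAP)
    )

    def mandatory_columns(self) -> list[str]:
        cols = [
            self.sample_col,
            self.cell_id_col,
            self.x_col,
            self.y_col,
            self.tissue_col,
            self.confidence_col,
        ]
        cols.extend(self.marker_cols.values())
        return cols

    def tissue_class(self, label: str) -> TissueClass:
        return self.tissue_label_map.get(str(label).strip().lower(), TissueClass.OTHER)


def read_cell_table(path: str | Path, dialect: TableDialect) -> list[CellRecord]:
    """Read a cell table CSV/TSV into :class:`CellRecord` objects.

    Raises :class:`CellTableFormatError` naming the first missing mandatory
    column, or a row-level error (with row index) for non-numeric
    coordinates.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in dialect.mandatory_columns():
        if col not in df.columns:
            raise CellTableFormatError(f"missing mandatory column: {col!r}")

    records: list[CellRecord] = []
    conf_scale = 0.01 if dialect.confidence_percent else 1.0
    for idx, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        try:
            x = float(row_map[dialect.x_col]) * dialect.um_per_unit
            y = float(row_map[dialect.y_col]) * dialect.um_per_unit
        except ValueError as exc:
            raise CellTableFormatError(
                f"row {idx}: non-numeric coordinate ({exc})"
            ) from exc
        try:
            conf = float(row_map[dialect.confidence_col]) * conf_scale
        except ValueError as exc:
            raise CellTableFormatError(f"row {idx}: non-numeric confidence") from exc
        intensities = {}
        for marker, col in dialect.marker_cols.items():
            try:
                intensities[marker] = float(row_map[col])
            except ValueError as exc:
                raise CellTableFormatError(
                    f"row {idx}: non-numeric intensity in column {col!r}"
                ) from exc
        phenotype = None
        if dialect.phenotype_col and dialect.phenotype_col in row_map:
            raw = str(row_map[dialect.phenotype_col]).strip()
            phenotype = raw or None
        area = None
        if dialect.cell_area_col and dialect.cell_area_col in row_map:
            raw = str(row_map[dialect.cell_area_col]).strip()
            if raw:
                area = float(raw)
        records.append(
            CellRecord(
                sample_id=str(row_map[dialect.sample_col]),
                cell_id=str(row_map[dialect.cell_id_col]),
                x_um=x,
                y_um=y,
                tissue_class=dialect.tissue_class(row_map[dialect.tissue_col]),
                intensities=intensities,
                confidence=conf,
                phenotype=phenotype,
                cell_area_um2=area,
            )
        )
    return records


def write_cell_table(
    cells: Iterable[CellRecord], path: str | Path, dialect: TableDialect
) -> None:
    """Write cells as RFC-4180 CSV in the given dialect (µm coordinates)."""
    cells = list(cells)
    markers = list(dialect.marker_cols)
    header = [
        dialect.sample_col,
        dialect.cell_id_col,
        dialect.x_col,
        dialect.y_col,
        dialect.tissue_col,
        dialect.confidence_col,
    ] + [dialect.marker_cols[m] for m in markers]
    if dialect.phenotype_col:
        header.append(dialect.phenotype_col)
    if dialect.cell_area_col:
        header.append(dialect.cell_area_col)
    conf_scale = 100.0 if dialect.confidence_percent else 1.0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for c in cells:
            row = [
                c.sample_id,
                c.cell_id,
                repr(c.x_um / dialect.um_per_unit),
                repr(c.y_um / dialect.um_per_unit),
                c.tissue_class.value,
                repr(c.confidence * conf_scale),
            ]
            row.extend(repr(float(c.intensities[m])) for m in markers)
            if dialect.phenotype_col:
                row.append(c.phenotype or "")
            if dialect.cell_area_col:
                row.append("" if c.cell_area_um2 is None else repr(c.cell_area_um2))
            writer.writerow(row)


def filter_by_confidence(
    cells: Sequence[CellRecord], min_conf: float = 0.5
) -> list[CellRecord]:
    """Keep cells whose confidence is strictly greater than ``min_conf``.

    The default reproduces the quality rule of dropping every cell at or
    below 50% classifier confidence.  Order is preserved; idempotent.
    """
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError(f"min_conf {min_conf} outside [0, 1]")
    return [c for c in cells if c.confidence > min_conf]


_TRUE_TOKENS = {"1", "true", "t", "yes"}
_FALSE_TOKENS = {"0", "false", "f", "no"}


def read_clinical_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical CSV with columns patient_id, time_months, event.

    An optional ``sample_ids`` column holds semicolon-separated sample ids;
    any further columns become stratification variables.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise CellTableFormatError(
            f"missing mandatory column: {sorted(missing)[0]!r}"
        )
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise CellTableFormatError(f"duplicate patient_id: {dup!r}")
    extra = [c for c in df.columns if c not in required and c != "sample_ids"]
    records = []
    for idx, row in df.iterrows():
        try:
            time = float(row["time_months"])
        except ValueError as exc:
            raise CellTableFormatError(f"row {idx}: non-numeric time") from exc
        if time <= 0:
            raise CellTableFormatError(f"row {idx}: non-positive time {time}")
        token = str(row["event"]).strip().lower()
        if token in _TRUE_TOKENS:
            event = True
        elif token in _FALSE_TOKENS:
            event = False
        else:
            raise CellTableFormatError(f"row {idx}: unparsable event {token!r}")
        sample_ids: tuple[str, ...] = ()
        if "sample_ids" in df.columns and str(row["sample_ids"]).strip():
            sample_ids = tuple(
                s.strip() for s in str(row["sample_ids"]).split(";") if s.strip()
            )
        records.append(
            SurvivalRecord(
                patient_id=str(row["patient_id"]),
                time=time,
                event=event,
                sample_ids=sample_ids,
                strata={c: str(row[c]) for c in extra},
            )
        )
    # each sample id may belong to at most one patient
    seen: dict[str, str] = {}
    for rec in records:
        for sid in rec.sample_ids:
            if sid in seen and seen[sid] != rec.patient_id:
                raise CellTableFormatError(
                    f"sample {sid!r} assigned to patients {seen[sid]!r} and {rec.patient_id!r}"
                )
            seen[sid] = rec.patient_id
    return records


def write_clinical_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    records = list(records)
    strata_keys = sorted({k for r in records for k in r.strata})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "time_months", "event", "sample_ids", *strata_keys])
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    repr(r.time),
                    int(r.event),
                    ";".join(r.sample_ids),
                    *[r.strata.get(k, "") for k in strata_keys],
                ]
            )
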