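"""Reading and writing per-nucleus signal-count tables.

The on-disk format is a UTF-8 tab-separated table with a header row
``sample_id  cell_id  <probe1> ... <probeN>  [qc]``: one row per nucleus, one
integer signal count per probe.  An ``.xlsx`` workbook with the same column
layout is accepted as a convenience (signal counts are routinely recorded in
spreadsheets at the microscope).

Nucleus-level quality control is absolute: a nucleus flagged as overlapping,
damaged/incomplete, or with a non-evaluable probe signal is excluded from all
downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .panel import PanelError, ProbePanel

logger = logging.getLogger(__name__)

QC_OVERLAPPING = "overlapping"
QC_DAMAGED = "damaged_or_incomplete"
QC_MISSING = "missing_signal"
VALID_QC_FLAGS = frozenset({QC_OVERLAPPING, QC_DAMAGED, QC_MISSING})

#: counts above this are accepted but logged; near-octoploid-doubling signal
#: numbers are biologically plausible yet very rare.
HIGH_COUNT_WARN = 16

ID_COLUMNS = ("sample_id", "cell_id")
QC_COLUMN = "qc"


class CountTableError(ValueError):
    """Raised when a per-cell count table violates the schema."""


@dataclass(frozen=True)
class CellRecord:
    """One nucleus: per-probe integer signal counts plus QC flags."""

    sample_id: str
    cell_id: str
    counts: tuple[int, ...]
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def passes_qc(self) -> bool:
        return not self.qc_flags


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical annotation consumed as categorical metadata."""

    sample_id: str
    cohort: str  # HCC | NAFLD | normal
    age: float | None = None
    sex: str | None = None
    tumor_size_cm: float | None = None
    stage: str | None = None
    grade: str | None = None
    fibrosis: str | None = None
    nas: int | None = None
    steatosis_pct: float | None = None
    mutation_status: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cohort not in ("HCC", "NAFLD", "normal"):
            raise CountTableError(
                f"sample {self.sample_id}: cohort must be HCC/NAFLD/normal, "
                f"got {self.cohort!r}"
            )
        if self.nas is not None and not 0 <= self.nas <= 8:
            raise CountTableError(
                f"sample {self.sample_id}: NAS must be within 0-8, got {self.nas}"
            )
        if self.cohort != "HCC" and (self.grade or self.stage):
            raise CountTableError(
                f"sample {self.sample_id}: grade/stage are only valid for cohort HCC"
            )


def _parse_qc_cell(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    text = str(value).strip()
    if not text or text.lower() in ("nan", "none", "pass", "ok"):
        return frozenset()
    flags = {tok.strip() for tok in text.replace(",", ";").split(";") if tok.strip()}
    unknown = flags - VALID_QC_FLAGS
    if unknown:
        raise CountTableError(
            f"unknown qc flag(s) {sorted(unknown)}; valid: {sorted(VALID_QC_FLAGS)}"
        )
    return frozenset(flags)


def read_cell_counts(path: str | Path, panel: ProbePanel) -> pd.DataFrame:
    """Read a per-nucleus count table into the canonical cell frame.

    Returns a DataFrame with columns ``sample_id, cell_id, <panel probes...>,
    qc``.  Probe columns are re-ordered to panel order; a missing (empty)
    count cell flags the nucleus ``missing_signal``; negative or non-integer
    counts raise :class:`CountTableError` with the offending row number.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, dtype=object)
    else:
        raw = pd.read_csv(path, sep="\t", dtype=object)
    for col in ID_COLUMNS:
        if col not in raw.columns:
            raise CountTableError(f"{path}: missing required column {col!r}")
    probe_cols = [c for c in raw.columns if c not in ID_COLUMNS and c != QC_COLUMN]
    unmatched = sorted(set(probe_cols) - set(panel.names))
    if unmatched:
        raise CountTableError(
            f"{path}: column(s) {unmatched} do not match any panel probe "
            f"(panel: {list(panel.names)})"
        )
    missing = sorted(set(panel.names) - set(probe_cols))
    if missing:
        raise CountTableError(f"{path}: missing probe column(s) {missing}")

    out = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].astype(str),
            "cell_id": raw["cell_id"].astype(str),
        }
    )
    flags_extra: list[set[str]] = [set() for _ in range(len(raw))]
    for name in panel.names:  # re-order to panel order
        parsed = np.zeros(len(raw), dtype=np.int64)
        for i, value in enumerate(raw[name].tolist()):
            if value is None or (isinstance(value, float) and np.isnan(value)) or (
                isinstance(value, str) and not value.strip()
            ):
                flags_extra[i].add(QC_MISSING)
                continue
            try:
                as_float = float(value)
            except (TypeError, ValueError):
                raise CountTableError(
                    f"{path}: row {i + 2}: count {value!r} for probe {name} "
                    "is not a number"
                ) from None
            if as_float != int(as_float):
                raise CountTableError(
                    f"{path}: row {i + 2}: count {value!r} for probe {name} "
                    "is not an integer"
                )
            count = int(as_float)
            if count < 0:
                raise CountTableError(
                    f"{path}: row {i + 2}: negative count {count} for probe {name}"
                )
            if count > HIGH_COUNT_WARN:
                logger.warning(
                    "%s: row %d: probe %s count %d exceeds %d (accepted)",
                    path, i + 2, name, count, HIGH_COUNT_WARN,
                )
            parsed[i] = count
        out[name] = parsed

    qc_in = raw[QC_COLUMN] if QC_COLUMN in raw.columns else [None] * len(raw)
    qc_parsed = []
    for i, value in enumerate(qc_in):
        flags = _parse_qc_cell(value) | flags_extra[i]
        qc_parsed.append(";".join(sorted(flags)))
    out[QC_COLUMN] = qc_parsed
    return out


def apply_qc(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cell frame into QC-passed rows and an exclusion log.

    Returns ``(kept, exclusion_log)`` where the log has columns ``cell_id``
    and ``reason``.  The partition is exact: every input row lands in exactly
    one of the two outputs.
    """
    if len(cells) == 0:
        return cells.copy(), pd.DataFrame(columns=["cell_id", "reason"])
    qc = cells[QC_COLUMN].fillna("") if QC_COLUMN in cells.columns else pd.Series(
        [""] * len(cells), index=cells.index
    )
    flagged = qc.astype(str).str.len() > 0
    kept = cells.loc[~flagged].copy()
    log = pd.DataFrame(
        {
            "cell_id": cells.loc[flagged, "cell_id"].astype(str).to_numpy(),
            "reason": qc.loc[flagged].astype(str).to_numpy(),
        }
    )
    return kept, log


def write_fishtrees_export(
    cells: pd.DataFrame, path: str | Path, panel: ProbePanel
) -> None:
    """Write QC-passed nuclei as a tab-separated count table.

    One row per nucleus, integer counts in panel order; round-trips
    losslessly through :func:`read_cell_counts`.
    """
    cols = list(ID_COLUMNS) + list(panel.names)
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise CountTableError(f"cell frame lacks column(s) {missing}")
    frame = cells[cols].copy()
    for name in panel.names:
        frame[name] = frame[name].astype(np.int64)
    frame.to_csv(path, sep="\t", index=False)


def counts_matrix(cells: pd.DataFrame, panel: ProbePanel) -> np.ndarray:
    """The (n_cells, n_probes) integer count matrix in panel order."""
    return cells[list(panel.names)].to_numpy(dtype=np.int64)


def iter_records(cells: pd.DataFrame, panel: ProbePanel) -> Iterator[CellRecord]:
    """Iterate rows of a cell frame as typed :class:`CellRecord` objects."""
    qc_col = cells[QC_COLUMN] if QC_COLUMN in cells.columns else None
    mat = counts_matrix(cells, panel)
    for i, (_, row) in enumerate(cells.iterrows()):
        flags = _parse_qc_cell(qc_col.iloc[i]) if qc_col is not None else frozenset()
        yield CellRecord(
            sample_id=str(row["sample_id"]),
            cell_id=str(row["cell_id"]),
            counts=tuple(int(x) for x in mat[i]),
            qc_flags=flags,
        )


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample clinical metadata from a TSV file.

    Required columns: ``sample_id, cohort``; recognised optional columns:
    ``age, sex, tumor_size_cm, stage, grade, fibrosis, nas, steatosis_pct,
    mutation_status`` (semicolon-separated tags).
    """
    raw = pd.read_csv(path, sep="\t", dtype=object)
    for col in ("sample_id", "cohort"):
        if col not in raw.columns:
            raise CountTableError(f"{path}: missing required column {col!r}")

    def _opt(row, col, cast):
        if col not in raw.columns:
            return None
        value = row[col]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        text = str(value).strip()
        if not text or text.lower() == "nan":
            return None
        return cast(text)

    out = []
    for _, row in raw.iterrows():
        tags = _opt(row, "mutation_status", str) or ""
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                cohort=str(row["cohort"]),
                age=_opt(row, "age", float),
                sex=_opt(row, "sex", str),
                tumor_size_cm=_opt(row, "tumor_size_cm", float),
                stage=_opt(row, "stage", str),
                grade=_opt(row, "grade", str),
                fibrosis=_opt(row, "fibrosis", str),
                nas=_opt(row, "nas", lambda s: int(float(s))),
                steatosis_pct=_opt(row, "steatosis_pct", float),
                mutation_status=tuple(t for t in tags.split(";") if t),
            )
        )
    return out
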