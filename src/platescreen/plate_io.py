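"""Readers and writers for every file format the screen pipeline touches.

Two colony-size input dialects are supported:

* a *log file* as produced by plate-imaging pipelines — colony sizes listed
  in plate order (A1, A2, … row-major), either as a bare position-ordered
  list of numbers or as a header-bearing long table with ``plate``,
  ``index``/``position``, ``size`` (and optionally ``circularity``) columns;
* a *generic table* with ``Label, Plate, Row, Column, colonysize`` columns,
  one row per colony, usable to import measurements from any imaging tool.

A *key file* (``Plate, Row, Column, ID``) assigns a strain identifier to
every plate position; the reserved identifier ``Control`` marks positions
carrying within-plate normalization controls.

The three result-table schemas (replicates, mean, merge) are written and
re-read as comma-separated text; numeric fields are written at 12
significant digits so a write/read round trip is lossless to ~1e-12
relative precision.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: reserved strain identifier marking within-plate control positions
CONTROL_ID = "Control"

#: the standard pinning densities: total -> (rows, columns)
STANDARD_FORMATS: Mapping[int, tuple[int, int]] = {
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}


class FormatError(ValueError):
    """Array-format violation (unknown density, index out of range, count mismatch)."""


class ParseError(ValueError):
    """Malformed input text."""


class SchemaError(ParseError):
    """A required column is missing from a delimited table."""


class DuplicatePositionError(ParseError):
    """The same (label, plate, row, column) appears more than once."""


class KeyConflictError(ParseError):
    """Two key-file rows assign different IDs to one position."""


@dataclass(frozen=True)
class ArrayFormat:
    """One of the standard colony array densities (96, 384 or 1536 per plate)."""

    rows: int
    columns: int

    def __post_init__(self) -> None:
        if STANDARD_FORMATS.get(self.rows * self.columns) != (self.rows, self.columns):
            raise FormatError(
                f"({self.rows} x {self.columns}) is not a standard array format; "
                f"expected one of {sorted(STANDARD_FORMATS.values())}"
            )

    @property
    def total(self) -> int:
        return self.rows * self.columns

    @classmethod
    def from_total(cls, total: int) -> "ArrayFormat":
        try:
            rows, columns = STANDARD_FORMATS[int(total)]
        except KeyError:
            raise FormatError(
                f"{total} colonies per plate is not a standard density; "
                f"expected one of {sorted(STANDARD_FORMATS)}"
            ) from None
        return cls(rows, columns)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.total}-colony ({self.rows}x{self.columns})"


@dataclass(frozen=True, order=True)
class Position:
    """A 1-based (plate, row, column) address on a pinned array."""

    plate: int
    row: int
    column: int

    @property
    def row_label(self) -> str:
        return row_label(self.row)


def row_label(row: int) -> str:
    """Spreadsheet-style row letters: 1 -> 'A', 26 -> 'Z', 27 -> 'AA', 32 -> 'AF'."""
    if row < 1:
        raise ValueError("row index must be >= 1")
    label = ""
    n = row
    while n > 0:
        n, r = divmod(n - 1, 26)
        label = chr(ord("A") + r) + label
    return label


def index_to_position(i: int, array_format: ArrayFormat, plate: int = 1) -> Position:
    """Map a 0-based running index to its (row, column) in row-major plate order.

    Index 0 is A1; for the 96 density index 95 is H12.
    """
    if not 0 <= i < array_format.total:
        raise FormatError(
            f"index {i} out of range for the {array_format.total}-colony format"
        )
    return Position(plate, i // array_format.columns + 1, i % array_format.columns + 1)


@dataclass
class ColonyGrid:
    """One plate's colony sizes, addressed by (row, column). NaN marks missing."""

    format: ArrayFormat
    plate: int
    condition_label: str
    sizes: np.ndarray
    circularity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.shape != (self.format.rows, self.format.columns):
            raise FormatError(
                f"size grid shape {self.sizes.shape} does not match "
                f"{self.format.rows}x{self.format.columns}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.sizes < 0):
                raise ValueError("colony sizes must be nonnegative")

    def size_at(self, row: int, column: int) -> float:
        return float(self.sizes[row - 1, column - 1])


@dataclass
class KeyMap:
    """Assignment of strain identifiers to plate positions.

    ``entries`` maps (plate, row, column) to an identifier string; positions
    absent from the map are unassigned and excluded from strain aggregation.
    The reserved identifier ``Control`` marks control positions.
    """

    entries: dict[tuple[int, int, int], str]
    control_id: str = CONTROL_ID

    def id_at(self, plate: int, row: int, column: int) -> str | None:
        return self.entries.get((plate, row, column))

    def plates(self) -> list[int]:
        return sorted({p for p, _, _ in self.entries})

    def strain_ids(self) -> set[str]:
        return set(self.entries.values())

    def positions_on_plate(self, plate: int) -> list[tuple[int, int]]:
        return sorted((r, c) for p, r, c in self.entries if p == plate)

    def control_positions(self, plate: int) -> list[tuple[int, int]]:
        return sorted(
            (r, c)
            for (p, r, c), sid in self.entries.items()
            if p == plate and sid == self.control_id
        )


# ---------------------------------------------------------------------------
# input parsing

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_number(token: str) -> bool:
    return bool(_NUMBER_RE.match(token.strip()))


def sniff_delimiter(text: str) -> str | None:
    """Detect the field delimiter: tab first, then comma; None for whitespace."""
    lines = [ln for ln in text.splitlines() if ln.strip()][:100]
    for delim in ("\t", ","):
        counts = {ln.count(delim) for ln in lines}
        if len(counts) == 1 and counts.pop() > 0:
            return delim
    return None


def _read_table(text: str) -> pd.DataFrame:
    delim = sniff_delimiter(text)
    if delim is None:
        raise ParseError(
            "could not detect a consistent tab or comma delimiter in the table"
        )
    df = pd.read_csv(io.StringIO(text), sep=delim, skipinitialspace=True,
                     float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _colmap(df: pd.DataFrame) -> dict[str, str]:
    return {str(c).strip().lower(): c for c in df.columns}


def parse_cm_log(
    text: str, array_format: ArrayFormat, condition_label: str = ""
) -> list[ColonyGrid]:
    """Parse a position-ordered colony-size log file into per-plate grids.

    Accepts either a headerless list of sizes (row-major plate order, plates
    concatenated) or a header-bearing long table with columns ``plate``,
    ``size`` (or ``colonysize``) and optionally ``index`` (0-based) /
    ``position`` (1-based) and ``circularity``.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty log file")
    delim = sniff_delimiter(text)
    first_tokens = [t for t in re.split(r"[,\t\s]+", lines[0].strip()) if t]
    if all(_is_number(t) for t in first_tokens):
        return _parse_flat_log(lines, array_format, condition_label)
    return _parse_long_log(text, array_format, condition_label, delim)


def _parse_flat_log(
    lines: Sequence[str], array_format: ArrayFormat, condition_label: str
) -> list[ColonyGrid]:
    values: list[float] = []
    for lineno, ln in enumerate(lines, start=1):
        for tok in re.split(r"[,\t\s]+", ln.strip()):
            if not tok:
                continue
            if not _is_number(tok):
                raise ParseError(f"non-numeric colony size {tok!r} on line {lineno}")
            values.append(float(tok))
    if len(values) % array_format.total != 0:
        raise FormatError(
            f"{len(values)} colony sizes is not a multiple of the declared "
            f"{array_format.total}-colony format"
        )
    n_plates = len(values) // array_format.total
    grids = []
    arr = np.asarray(values, dtype=float)
    for p in range(n_plates):
        block = arr[p * array_format.total : (p + 1) * array_format.total]
        grids.append(
            ColonyGrid(
                format=array_format,
                plate=p + 1,
                condition_label=condition_label,
                sizes=block.reshape(array_format.rows, array_format.columns),
            )
        )
    return grids


def _parse_long_log(
    text: str, array_format: ArrayFormat, condition_label: str, delim: str | None
) -> list[ColonyGrid]:
    df = pd.read_csv(io.StringIO(text), sep=delim if delim else r"\s+",
                     float_precision="round_trip")
    cols = _colmap(df)
    if "plate" not in cols:
        raise SchemaError("log file header must contain a 'plate' column")
    size_col = next(
        (cols[k] for k in ("size", "colonysize", "colony_size") if k in cols), None
    )
    if size_col is None:
        raise SchemaError("log file header must contain a 'size' column")
    sizes = pd.to_numeric(df[size_col], errors="coerce")
    bad = sizes.isna() & df[size_col].notna()
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise ParseError(
            f"non-numeric colony size {df[size_col][bad.idxmax()]!r} on line {lineno}"
        )
    circ_col = cols.get("circularity")
    grids = []
    for plate, sub in df.groupby(cols["plate"], sort=True):
        if len(sub) != array_format.total:
            raise FormatError(
                f"plate {plate} has {len(sub)} colony records; the declared "
                f"format expects {array_format.total}"
            )
        if "index" in cols:
            order = pd.to_numeric(sub[cols["index"]]).to_numpy(dtype=int)
        elif "position" in cols:
            order = pd.to_numeric(sub[cols["position"]]).to_numpy(dtype=int) - 1
        else:
            order = np.arange(array_format.total)
        grid = np.full(array_format.total, np.nan)
        grid[order] = sizes.loc[sub.index].to_numpy()
        circ = None
        if circ_col is not None:
            circ = np.full(array_format.total, np.nan)
            circ[order] = pd.to_numeric(sub[circ_col], errors="coerce").to_numpy()
            circ = circ.reshape(array_format.rows, array_format.columns)
        grids.append(
            ColonyGrid(
                format=array_format,
                plate=int(plate),
                condition_label=condition_label,
                sizes=grid.reshape(array_format.rows, array_format.columns),
                circularity=circ,
            )
        )
    return grids


def infer_format(max_row: int, max_col: int) -> ArrayFormat:
    """Infer the array density from the largest observed row/column index.

    The observed maxima must exactly match a standard (rows, columns) pair;
    partially filled tables are ambiguous and require an explicit format.
    """
    for rows, columns in STANDARD_FORMATS.values():
        if (max_row, max_col) == (rows, columns):
            return ArrayFormat(rows, columns)
    raise FormatError(
        f"cannot infer array format from max row {max_row}, max column {max_col}; "
        "pass array_format explicitly for partially filled tables"
    )


def parse_generic_table(
    text: str, array_format: ArrayFormat | None = None
) -> dict[str, list[ColonyGrid]]:
    """Parse a Label/Plate/Row/Column/colonysize table, grouped by condition label."""
    df = _read_table(text)
    cols = _colmap(df)
    required = ["label", "plate", "row", "column", "colonysize"]
    missing = [k for k in required if k not in cols]
    if missing:
        raise SchemaError(
            "generic colony table must contain columns "
            "Label, Plate, Row, Column, colonysize "
            f"(missing: {', '.join(missing)})"
        )
    key_cols = [cols[k] for k in ("label", "plate", "row", "column")]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df.loc[dup.idxmax(), key_cols].tolist()
        raise DuplicatePositionError(
            f"duplicate colony record for (Label, Plate, Row, Column) = {tuple(first)}"
        )
    if array_format is None:
        array_format = infer_format(
            int(df[cols["row"]].max()), int(df[cols["column"]].max())
        )
    out: dict[str, list[ColonyGrid]] = {}
    for label, sub in df.groupby(cols["label"], sort=False):
        grids = []
        for plate, psub in sub.groupby(cols["plate"], sort=True):
            grid = np.full((array_format.rows, array_format.columns), np.nan)
            r = psub[cols["row"]].to_numpy(dtype=int) - 1
            c = psub[cols["column"]].to_numpy(dtype=int) - 1
            if (r < 0).any() or (r >= array_format.rows).any() or (c < 0).any() or (
                c >= array_format.columns
            ).any():
                raise FormatError(
                    f"row/column index outside the {array_format} grid "
                    f"for label {label!r}, plate {plate}"
                )
            grid[r, c] = pd.to_numeric(psub[cols["colonysize"]]).to_numpy(dtype=float)
            grids.append(
                ColonyGrid(
                    format=array_format,
                    plate=int(plate),
                    condition_label=str(label),
                    sizes=grid,
                )
            )
        out[str(label)] = grids
    return out


def parse_key_file(text: str) -> KeyMap:
    """Parse a Plate/Row/Column/ID key file into a :class:`KeyMap`."""
    df = _read_table(text)
    cols = _colmap(df)
    missing = [k for k in ("plate", "row", "column", "id") if k not in cols]
    if missing:
        raise SchemaError(
            "key file must contain columns Plate, Row, Column, ID "
            f"(missing: {', '.join(missing)})"
        )
    entries: dict[tuple[int, int, int], str] = {}
    for _, rec in df.iterrows():
        pos = (int(rec[cols["plate"]]), int(rec[cols["row"]]), int(rec[cols["column"]]))
        sid = str(rec[cols["id"]]).strip()
        if pos in entries and entries[pos] != sid:
            raise KeyConflictError(
                f"position (plate {pos[0]}, row {pos[1]}, column {pos[2]}) assigned "
                f"to both {entries[pos]!r} and {sid!r}"
            )
        entries[pos] = sid
    return KeyMap(entries=entries)


# ---------------------------------------------------------------------------
# result tables

REPLICATE_COLUMNS = [
    "Plate", "Row", "Column", "ID",
    "control_norm", "experiment_norm", "LGR", "excluded",
]
MEAN_COLUMNS = [
    "Plate", "Row", "Column", "ID", "n_reps",
    "control_mean_norm", "experiment_mean_norm", "mean_LGR",
    "p_value", "q_value", "neg_lnP", "neg_lnQ", "zscore", "excluded",
]
MERGE_COLUMNS = [
    "ID", "Plate", "mean_LGR_c1", "mean_LGR_c2", "avg_LGR",
    "zscore_c1", "zscore_c2", "zscore_merged",
    "max_p", "max_q", "neg_ln_maxP", "neg_ln_maxQ",
]

_SCHEMAS = {"replicates": REPLICATE_COLUMNS, "mean": MEAN_COLUMNS, "merge": MERGE_COLUMNS}
_SORT_KEYS = {
    "replicates": ["Plate", "Row", "Column"],
    "mean": ["Plate", "ID"],
    "merge": ["Plate", "ID"],
}


def write_results_table(records: pd.DataFrame, kind: str, destination) -> None:
    """Write a replicates/mean/merge table as CSV with the fixed column schema.

    Floats are rendered at 12 significant digits; missing values are empty
    fields; rows are sorted by (Plate, Row, Column) for replicates and by
    (Plate, ID) otherwise.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_SCHEMAS)}")
    schema = _SCHEMAS[kind]
    missing = [c for c in schema if c not in records.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing columns: {', '.join(missing)}")
    df = records.loc[:, schema].sort_values(_SORT_KEYS[kind], kind="mergesort")
    df.to_csv(destination, index=False, float_format="%.12g", lineterminator="\n")


def read_results_table(source, kind: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing columns: {', '.join(missing)}")
    if "excluded" in df.columns and df["excluded"].dtype == object:
        df["excluded"] = df["excluded"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return df
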