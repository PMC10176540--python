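"""Relational tables as ordered, string-valued columns.

The anonymizer treats every cell as opaque text: no type coercion, no NA
semantics, no reformatting.  Output files must be byte-compatible with the
input layout (same header, same column order, RFC-4180 quoting), so I/O goes
through the stdlib ``csv`` module while the in-memory container is a pandas
DataFrame with ``object`` dtype holding plain ``str`` values ("" for empty).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["RelationalTable", "TableError", "read_table", "write_table"]


class TableError(ValueError):
    """Structural problem with a relational table (bad header, ragged row)."""


@dataclass
class RelationalTable:
    """A named table of text values with a stable column order.

    Parameters
    ----------
    name
        Table identifier; for file-backed tables this is the filename stem.
    data
        DataFrame with ``object`` dtype; every cell is a ``str`` (possibly
        empty).  Column order is significant and preserved by every
        operation in this package.
    """

    name: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise TableError("table name must be non-empty")
        cols = list(self.data.columns)
        if len(cols) == 0:
            raise TableError(f"table {self.name!r} has an empty header")
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise TableError(f"table {self.name!r} has duplicate field names: {dupes}")
        if any(not isinstance(c, str) or not c for c in cols):
            raise TableError(f"table {self.name!r} has blank or non-text field names")

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def copy(self) -> "RelationalTable":
        return RelationalTable(self.name, self.data.copy())

    def column_values(self, field_name: str) -> list[str]:
        if field_name not in self.data.columns:
            raise TableError(f"table {self.name!r} has no field {field_name!r}")
        return [str(v) for v in self.data[field_name]]

    @classmethod
    def from_rows(
        cls, name: str, columns: list[str], rows: list[list[str]]
    ) -> "RelationalTable":
        if len(set(columns)) != len(columns):
            dupes = sorted({c for c in columns if columns.count(c) > 1})
            raise TableError(f"table {name!r} has duplicate field names: {dupes}")
        for i, row in enumerate(rows):
            if len(row) != len(columns):
                raise TableError(
                    f"table {name!r} row {i} has {len(row)} values, "
                    f"expected {len(columns)}"
                )
        df = pd.DataFrame(rows or None, columns=columns, dtype=object)
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
        return cls(name, df.astype(object))


def read_table(path: str | Path, name: str | None = None) -> RelationalTable:
    """Read one delimited text file into a table (filename stem = table name)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableError(f"{path} is empty (no header row)") from None
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise TableError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)
    return RelationalTable.from_rows(name or path.stem, header, rows)


def write_table(table: RelationalTable, path: str | Path) -> Path:
    """Write a table as UTF-8 CSV with RFC-4180 minimal quoting."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(table.columns)
        for row in table.data.itertuples(index=False):
            writer.writerow(["" if v is None else str(v) for v in row])
    return path
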