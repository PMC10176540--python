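"""The data record description (data dictionary) that drives anonymization.

Every (table, field) pair in the source data gets one entry assigning a
privacy measure: leave alone, erase, pseudonymize, or randomize dates.
Whole tables (system tables, exports that must not leave the house) can be
excluded outright.  Split calendar dates stored as three adjacent columns
are bound together through a ``date_group`` so day/month/year are shifted
as one value.

The dictionary is a hand-editable CSV with header
``table_name,field_name,description,measure,date_group,date_role``;
a row with an empty field name and measure ``Excluded`` marks a whole
table as excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

from .tables import RelationalTable

__all__ = [
    "Measure",
    "FieldEntry",
    "DataDictionary",
    "DictionaryError",
    "extract_schema",
    "load_dictionary",
    "save_dictionary",
    "validate_dictionary",
]

DICT_HEADER = ["table_name", "field_name", "description", "measure", "date_group", "date_role"]
EXCLUDED_MARKER = "excluded"
DATE_ROLES = ("day", "month", "year")


class DictionaryError(ValueError):
    """Invalid dictionary content or a dictionary/data mismatch."""


class Measure(Enum):
    """The four privacy measures a field can be assigned."""

    NO_ACTION = "No Action"
    DELETION = "Deletion"
    PSEUDONYMIZATION = "Pseudonymization"
    DATE_RANDOMIZATION = "Date Randomization"

    @classmethod
    def parse(cls, text: str) -> "Measure":
        """Map a measure string onto the enum, case- and separator-insensitively."""
        key = text.strip().lower().replace("-", " ").replace("_", " ")
        key = " ".join(key.split())
        for m in cls:
            if m.value.lower() == key:
                return m
        raise DictionaryError(f"unknown measure {text!r}")


@dataclass(frozen=True)
class FieldEntry:
    """One row of the data record description."""

    table_name: str
    field_name: str
    description: str = ""
    measure: Measure = Measure.NO_ACTION
    date_group: str | None = None   # binds the 3 columns of a split date
    date_role: str | None = None    # 'day' | 'month' | 'year'

    def __post_init__(self) -> None:
        if not self.table_name or not self.field_name:
            raise DictionaryError("table_name and field_name must be non-empty")
        if (self.date_group is None) != (self.date_role is None):
            raise DictionaryError(
                f"{self.table_name}.{self.field_name}: date_group and date_role "
                "must be set together"
            )
        if self.date_group is not None:
            if self.measure is not Measure.DATE_RANDOMIZATION:
                raise DictionaryError(
                    f"{self.table_name}.{self.field_name}: date_group requires "
                    "measure Date Randomization"
                )
            if self.date_role not in DATE_ROLES:
                raise DictionaryError(
                    f"{self.table_name}.{self.field_name}: date_role must be one of "
                    f"{DATE_ROLES}, got {self.date_role!r}"
                )


@dataclass
class DataDictionary:
    """Ordered field entries plus the set of excluded tables."""

    entries: list[FieldEntry] = field(default_factory=list)
    excluded_tables: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.table_name, e.field_name)
            if key in seen:
                raise DictionaryError(f"duplicate dictionary entry for {key}")
            seen.add(key)
        overlap = self.excluded_tables & {e.table_name for e in self.entries}
        if overlap:
            raise DictionaryError(
                f"tables both excluded and described: {sorted(overlap)}"
            )
        self._check_date_groups()

    def _check_date_groups(self) -> None:
        groups: dict[tuple[str, str], dict[str, str]] = {}
        for e in self.entries:
            if e.date_group is None:
                continue
            roles = groups.setdefault((e.table_name, e.date_group), {})
            if e.date_role in roles:
                raise DictionaryError(
                    f"date group {e.date_group!r} in table {e.table_name!r} has "
                    f"two {e.date_role!r} columns"
                )
            roles[e.date_role] = e.field_name
        # a group name may not span tables
        names_by_group: dict[str, set[str]] = {}
        for (tbl, grp) in groups:
            names_by_group.setdefault(grp, set()).add(tbl)
        for grp, tbls in names_by_group.items():
            if len(tbls) > 1:
                raise DictionaryError(
                    f"date group {grp!r} spans tables {sorted(tbls)}"
                )
        for (tbl, grp), roles in groups.items():
            if set(roles) != set(DATE_ROLES):
                raise DictionaryError(
                    f"date group {grp!r} in table {tbl!r} has roles "
                    f"{sorted(roles)}; needs exactly one day, month and year column"
                )

    def entries_for(self, table_name: str) -> list[FieldEntry]:
        return [e for e in self.entries if e.table_name == table_name]

    def table_names(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.table_name not in out:
                out.append(e.table_name)
        return out

    def measure_counts(self) -> dict[str, int]:
        counts = {m.name: 0 for m in Measure}
        for e in self.entries:
            counts[e.measure.name] += 1
        return counts


def extract_schema(tables: Iterable[RelationalTable]) -> DataDictionary:
    """Build a dictionary skeleton from table headers.

    One entry per (table, field), in table order then column order, all set
    to ``No Action`` with an empty description.  This is the automated first
    step; descriptions and measures are then curated by hand.
    """
    tables = list(tables)
    names = [t.name for t in tables]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DictionaryError(f"duplicate table names: {dupes}")
    entries = [
        FieldEntry(table_name=t.name, field_name=col)
        for t in tables
        for col in t.columns
    ]
    return DataDictionary(entries=entries)


def load_dictionary(path: str | Path) -> DataDictionary:
    """Parse a dictionary CSV; see module docstring for the format."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DictionaryError(f"{path} is empty") from None
        header = [h.strip() for h in header]
        if header not in (DICT_HEADER, DICT_HEADER[:5], DICT_HEADER[:4]):
            raise DictionaryError(
                f"{path}: header must be {','.join(DICT_HEADER)} "
                "(the last two columns may be omitted)"
            )
        entries: list[FieldEntry] = []
        excluded: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            row = list(row) + [""] * (len(DICT_HEADER) - len(row))
            tbl, fld, desc, meas, grp, role = (v.strip() for v in row[:6])
            if not tbl:
                raise DictionaryError(f"{path}:{lineno}: empty table_name")
            if not fld:
                if meas.lower() == EXCLUDED_MARKER:
                    excluded.add(tbl)
                    continue
                raise DictionaryError(
                    f"{path}:{lineno}: empty field_name is only valid with "
                    "measure 'Excluded'"
                )
            try:
                measure = Measure.parse(meas) if meas else Measure.NO_ACTION
            except DictionaryError as exc:
                raise DictionaryError(f"{path}:{lineno}: {exc}") from None
            try:
                entries.append(
                    FieldEntry(
                        table_name=tbl,
                        field_name=fld,
                        description=desc,
                        measure=measure,
                        date_group=grp or None,
                        date_role=role or None,
                    )
                )
            except DictionaryError as exc:
                raise DictionaryError(f"{path}:{lineno}: {exc}") from None
    return DataDictionary(entries=entries, excluded_tables=excluded)


def save_dictionary(dictionary: DataDictionary, path: str | Path) -> Path:
    """Write a dictionary CSV such that load(save(d)) == d, byte-stably."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(DICT_HEADER)
        for e in dictionary.entries:
            writer.writerow(
                [
                    e.table_name,
                    e.field_name,
                    e.description,
                    e.measure.value,
                    e.date_group or "",
                    e.date_role or "",
                ]
            )
        for tbl in sorted(dictionary.excluded_tables):
            writer.writerow([tbl, "", "", "Excluded", "", ""])
    return path


def validate_dictionary(
    dictionary: DataDictionary,
    tables: Iterable[RelationalTable],
    unknown_policy: str = "error",
) -> DataDictionary:
    """Reconcile a dictionary against the actual data.

    Every field present in the data must be covered by an entry or belong to
    an excluded table.  Uncovered fields are either an error
    (``unknown_policy='error'``) or get synthesized ``Deletion`` entries
    (``'delete'``): a field nobody could describe is erased rather than
    leaked.  Entries pointing at tables or fields that no longer exist are
    always an error — a stale dictionary must not silently drive a run.
    """
    if unknown_policy not in ("error", "delete"):
        raise DictionaryError(f"unknown_policy must be 'error' or 'delete', got {unknown_policy!r}")
    tables = list(tables)
    by_name = {t.name: t for t in tables}

    stale: list[str] = []
    for e in dictionary.entries:
        t = by_name.get(e.table_name)
        if t is None:
            stale.append(f"{e.table_name} (table missing)")
        elif e.field_name not in t.columns:
            stale.append(f"{e.table_name}.{e.field_name}")
    if stale:
        raise DictionaryError(f"dictionary references nonexistent data: {stale}")

    covered = {(e.table_name, e.field_name) for e in dictionary.entries}
    uncovered: list[tuple[str, str]] = []
    for t in tables:
        if t.name in dictionary.excluded_tables:
            continue
        for col in t.columns:
            if (t.name, col) not in covered:
                uncovered.append((t.name, col))
    if not uncovered:
        return DataDictionary(
            entries=list(dictionary.entries),
            excluded_tables=set(dictionary.excluded_tables),
        )
    if unknown_policy == "error":
        offenders = ", ".join(f"{t}.{f}" for t, f in uncovered)
        raise DictionaryError(f"fields not covered by the dictionary: {offenders}")
    extra = [
        FieldEntry(table_name=t, field_name=f, description="", measure=Measure.DELETION)
        for t, f in uncovered
    ]
    return DataDictionary(
        entries=list(dictionary.entries) + extra,
        excluded_tables=set(dictionary.excluded_tables),
    )
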