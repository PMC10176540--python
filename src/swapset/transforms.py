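"""Field-level privacy measures: deletion, pseudonymization, date shifting.

Deletion blanks a column in place (the column itself stays, so the output
keeps the input's exact shape).  Pseudonymization replaces each non-empty
value with the SHA3-256 hex digest of the value concatenated with a secret
16-byte salt; the salt lives only for the duration of one run, so the
mapping is one-way, yet identical values — cross-table identifiers in
particular — map to identical tokens within the run.

Date randomization comes in two flavours matching the two layouts found in
registry exports: combined ``DD.MM.YYYY`` strings, shifted by a uniform
random offset of 3–6 days in either direction, and split day/month/year
column triples, recombined, shifted by 2–10 days either way, and written
back into the three columns with each column's zero-padding width kept.
Offsets are drawn fresh per value.

Empty cells pass through every measure untouched: missingness patterns are
part of the utility the swapping data set is meant to preserve, and hashing
the empty string would plant one conspicuous fake token.
"""

from __future__ import annotations

import hashlib
import re
import secrets as _secrets
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from random import Random, SystemRandom

from .dictionary import DataDictionary, Measure
from .tables import RelationalTable, TableError

__all__ = [
    "RunSecrets",
    "ShiftAudit",
    "DateParseError",
    "COMBINED_OFFSETS",
    "SPLIT_OFFSETS",
    "delete_column",
    "pseudonymize_column",
    "shift_date_combined",
    "shift_date_split",
    "apply_measures",
]

SALT_BYTES = 16

# admissible signed day offsets, taken literally from the method definition:
# combined dates move by +-3..6 days, split dates by +-2..10 days; zero and
# the offsets adjacent to zero are never produced.
COMBINED_OFFSETS: tuple[int, ...] = tuple(
    s * m for m in range(3, 7) for s in (-1, 1)
)
SPLIT_OFFSETS: tuple[int, ...] = tuple(
    s * m for m in range(2, 11) for s in (-1, 1)
)

_COMBINED_RE = re.compile(r"^\d{2}\.\d{2}\.\d{4}$")


class DateParseError(ValueError):
    """A value that should be a calendar date is not one."""


@dataclass
class RunSecrets:
    """Per-run secret salt and randomness source.

    In production mode the salt comes from the OS CSPRNG and the randomness
    source is non-seedable (``random.SystemRandom``); neither is ever
    persisted, which is what makes the pseudonyms irreversible.  Test mode
    accepts an injected salt and seed so runs are bit-reproducible.
    """

    salt: bytes
    rng: Random
    mode: str = "production"

    def __post_init__(self) -> None:
        if len(self.salt) != SALT_BYTES:
            raise ValueError(f"salt must be exactly {SALT_BYTES} bytes, got {len(self.salt)}")
        if self.mode not in ("production", "test"):
            raise ValueError(f"mode must be 'production' or 'test', got {self.mode!r}")

    @classmethod
    def production(cls) -> "RunSecrets":
        return cls(salt=_secrets.token_bytes(SALT_BYTES), rng=SystemRandom(), mode="production")

    @classmethod
    def for_testing(cls, seed: int, salt: bytes | None = None) -> "RunSecrets":
        return cls(salt=salt if salt is not None else bytes(SALT_BYTES), rng=Random(seed), mode="test")


@dataclass
class ShiftAudit:
    """Aggregate accounting of applied date shifts.

    Keyed by (table, field-or-date-group); stores only offset frequencies
    and counts of unparsable values blanked.  Deliberately contains no row
    indices and no original or shifted values, so the audit itself cannot be
    used to undo the shifts.
    """

    shifts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    unparsable: dict[tuple[str, str], int] = field(default_factory=dict)

    def record_shift(self, table: str, key: str, offset: int) -> None:
        self.shifts.setdefault((table, key), Counter())[offset] += 1

    def record_unparsable(self, table: str, key: str) -> None:
        self.unparsable[(table, key)] = self.unparsable.get((table, key), 0) + 1

    def total_shifts(self) -> int:
        return sum(sum(c.values()) for c in self.shifts.values())

    def total_unparsable(self) -> int:
        return sum(self.unparsable.values())

    def to_dict(self) -> dict:
        return {
            "shifts": {
                f"{t}.{k}": {str(off): n for off, n in sorted(c.items())}
                for (t, k), c in sorted(self.shifts.items())
            },
            "unparsable": {
                f"{t}.{k}": n for (t, k), n in sorted(self.unparsable.items())
            },
        }


def delete_column(table: RelationalTable, field_name: str) -> RelationalTable:
    """Erase every value in one column; the column header remains."""
    if field_name not in table.columns:
        raise TableError(f"table {table.name!r} has no field {field_name!r}")
    out = table.copy()
    out.data[field_name] = ""
    return out


def pseudonymize_column(
    table: RelationalTable, field_name: str, run_secrets: RunSecrets
) -> RelationalTable:
    """Replace each non-empty value with SHA3-256(value || salt) in hex."""
    if field_name not in table.columns:
        raise TableError(f"table {table.name!r} has no field {field_name!r}")
    salt = run_secrets.salt
    out = table.copy()
    out.data[field_name] = [
        hashlib.sha3_256(str(v).encode("utf-8") + salt).hexdigest() if str(v) else ""
        for v in out.data[field_name]
    ]
    return out


def _parse_combined(value: str) -> date:
    if not _COMBINED_RE.match(value):
        raise DateParseError(f"not a DD.MM.YYYY date")
    d, m, y = int(value[:2]), int(value[3:5]), int(value[6:])
    try:
        return date(y, m, d)
    except ValueError:
        raise DateParseError("invalid calendar date") from None


def shift_date_combined(value: str, rng: Random) -> str:
    """Shift a ``DD.MM.YYYY`` date by a random offset of 3..6 days, either sign.

    The offset is drawn uniformly over the 8 admissible values, fresh per
    call; month and year roll over via ordinary calendar arithmetic.
    """
    parsed = _parse_combined(value)
    shifted = parsed + timedelta(days=rng.choice(COMBINED_OFFSETS))
    return f"{shifted.day:02d}.{shifted.month:02d}.{shifted.year:04d}"


def _parse_split(day: str, month: str, year: str) -> date:
    parts = (day.strip(), month.strip(), year.strip())
    if not all(p.isdigit() for p in parts):
        raise DateParseError("split date columns must be digits")
    try:
        return date(int(parts[2]), int(parts[1]), int(parts[0]))
    except ValueError:
        raise DateParseError("invalid calendar date") from None


def shift_date_split(
    day: str, month: str, year: str, rng: Random
) -> tuple[str, str, str]:
    """Shift a (day, month, year) column triple by 2..10 days, either sign.

    The triple is recombined into one date, shifted by an offset drawn
    uniformly over the 18 admissible values, and redistributed to the three
    columns with each input column's zero-padding width preserved.
    """
    parsed = _parse_split(day, month, year)
    shifted = parsed + timedelta(days=rng.choice(SPLIT_OFFSETS))
    return (
        str(shifted.day).zfill(len(day.strip()) or 2),
        str(shifted.month).zfill(len(month.strip()) or 2),
        str(shifted.year).zfill(len(year.strip()) or 4),
    )


def _day_delta(before: date, after: date) -> int:
    return (after - before).days


def apply_measures(
    table: RelationalTable,
    dictionary: DataDictionary,
    run_secrets: RunSecrets,
    bad_date_policy: str = "blank",
) -> tuple[RelationalTable, ShiftAudit]:
    """Apply each field's measure; returns the transformed table and audit.

    Split-date triples (bound by a dictionary ``date_group``) are handled
    atomically: if any of the three cells does not form a valid date, all
    three are blanked (policy ``'blank'``) or the run aborts (``'error'``).
    Row order and count never change at this stage.  Error messages name
    the table and field but never a cell value, so no data leaks into logs.
    """
    if bad_date_policy not in ("blank", "error"):
        raise ValueError(f"bad_date_policy must be 'blank' or 'error', got {bad_date_policy!r}")
    audit = ShiftAudit()
    out = table.copy()
    entries = dictionary.entries_for(table.name)
    group_fields: dict[str, dict[str, str]] = {}
    for e in entries:
        if e.field_name not in out.columns:
            raise TableError(f"table {table.name!r} has no field {e.field_name!r}")
        if e.date_group is not None:
            group_fields.setdefault(e.date_group, {})[e.date_role] = e.field_name

    for e in entries:
        if e.measure is Measure.DELETION:
            out = delete_column(out, e.field_name)
        elif e.measure is Measure.PSEUDONYMIZATION:
            out = pseudonymize_column(out, e.field_name, run_secrets)

    # combined-format date columns
    for e in entries:
        if e.measure is not Measure.DATE_RANDOMIZATION or e.date_group is not None:
            continue
        values = list(out.data[e.field_name])
        new_values = []
        for v in values:
            v = str(v)
            if not v:
                new_values.append("")
                continue
            try:
                before = _parse_combined(v)
            except DateParseError:
                if bad_date_policy == "error":
                    raise DateParseError(
                        f"unparsable date in {table.name}.{e.field_name}"
                    ) from None
                audit.record_unparsable(table.name, e.field_name)
                new_values.append("")
                continue
            shifted = shift_date_combined(v, run_secrets.rng)
            audit.record_shift(
                table.name, e.field_name, _day_delta(before, _parse_combined(shifted))
            )
            new_values.append(shifted)
        out.data[e.field_name] = new_values

    # split-format date groups, processed atomically per triple
    for group_name in sorted(group_fields):
        roles = group_fields[group_name]
        fd, fm, fy = roles["day"], roles["month"], roles["year"]
        days = [str(v) for v in out.data[fd]]
        months = [str(v) for v in out.data[fm]]
        years = [str(v) for v in out.data[fy]]
        for i in range(len(days)):
            triple = (days[i], months[i], years[i])
            if all(not p.strip() for p in triple):
                continue
            try:
                before = _parse_split(*triple)
            except DateParseError:
                if bad_date_policy == "error":
                    raise DateParseError(
                        f"unparsable split date in {table.name} group {group_name}"
                    ) from None
                audit.record_unparsable(table.name, group_name)
                days[i] = months[i] = years[i] = ""
                continue
            nd, nm, ny = shift_date_split(*triple, run_secrets.rng)
            audit.record_shift(
                table.name, group_name, _day_delta(before, _parse_split(nd, nm, ny))
            )
            days[i], months[i], years[i] = nd, nm, ny
        out.data[fd] = days
        out.data[fm] = months
        out.data[fy] = years

    return out, audit
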