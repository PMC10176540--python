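"""Value swapping within ICD-10 entity groups, plus row sampling.

Swapping is the destructive core of the anonymizer: within each entity
group, every column is independently replaced by a uniform random
permutation of its own values.  Per-column marginals inside a group are
exactly preserved (the value multiset is untouched) while the linkage
between columns — and hence to any natural person — is destroyed.

Entity groups are keyed on the 3-character ICD-10 category prefix so that
disease-level structure survives.  Groups smaller than ``k_min`` (default
25) observations are merged into pools so no swap group is small enough to
leak; the packing rule below is deterministic given the group counts.

Sampling then deletes an exact fraction (default 30%) of rows uniformly at
random, so true record counts and frequencies cannot be recovered from the
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random

from .tables import RelationalTable, TableError

__all__ = [
    "SwapConfig",
    "EntityGrouping",
    "UNKNOWN_GROUP",
    "WHOLE_TABLE_GROUP",
    "build_entity_groups",
    "swap_within_groups",
    "sample_rows",
]

UNKNOWN_GROUP = "UNKNOWN"
WHOLE_TABLE_GROUP = "ALL"


@dataclass(frozen=True)
class SwapConfig:
    """Per-table swapping and sampling parameters.

    ``icd_field`` names the grouping column; a table without one is swapped
    as a single whole-table group.  ``k_min`` is the minimum entity-group
    size after merging; ``sample_fraction`` the fraction of rows deleted
    after swapping; ``icd_prefix_len`` the length of the ICD-10 category
    prefix used as the group key.
    """

    icd_field: str | None = None
    k_min: int = 25
    sample_fraction: float = 0.30
    icd_prefix_len: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.sample_fraction < 1):
            raise ValueError(f"sample_fraction must be in [0, 1), got {self.sample_fraction}")
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.icd_prefix_len < 1:
            raise ValueError(f"icd_prefix_len must be >= 1, got {self.icd_prefix_len}")


@dataclass
class EntityGrouping:
    """Assignment of every table row to one swap group.

    ``assignment[i]`` is the group key of row ``i``; ``registry`` maps each
    key to its size and the set of ICD prefixes of its members;
    ``merged_flags`` marks keys that are merged pools of small groups.
    """

    assignment: list[str]
    registry: dict[str, dict] = field(default_factory=dict)
    merged_flags: dict[str, bool] = field(default_factory=dict)

    def rows_by_group(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, key in enumerate(self.assignment):
            out.setdefault(key, []).append(i)
        return out

    def min_group_size(self) -> int:
        sizes = [info["size"] for info in self.registry.values()]
        return min(sizes) if sizes else 0

    def n_merged_pools(self) -> int:
        return sum(1 for v in self.merged_flags.values() if v)


def _icd_key(value: str, prefix_len: int) -> str:
    v = value.strip().upper()
    if len(v) < prefix_len:
        return UNKNOWN_GROUP
    return v[:prefix_len]


def build_entity_groups(table: RelationalTable, config: SwapConfig) -> EntityGrouping:
    """Partition rows by ICD prefix, then merge groups smaller than k_min.

    Merge rule (deterministic): sort undersized groups by size descending
    (ties by key), accumulate them greedily into pools, closing a pool once
    it reaches ``k_min``; a final still-undersized pool is absorbed into the
    smallest closed pool, or — if none was formed — into the smallest
    full-size group.  A table with fewer than ``k_min`` rows overall
    becomes one pool.
    """
    n = table.n_rows
    if config.icd_field is None:
        reg = {WHOLE_TABLE_GROUP: {"size": n, "prefixes": set()}} if n else {}
        return EntityGrouping(
            assignment=[WHOLE_TABLE_GROUP] * n,
            registry=reg,
            merged_flags={k: False for k in reg},
        )
    if config.icd_field not in table.columns:
        raise TableError(
            f"table {table.name!r} has no ICD field {config.icd_field!r}"
        )
    keys = [_icd_key(str(v), config.icd_prefix_len) for v in table.data[config.icd_field]]
    sizes: dict[str, int] = {}
    for k in keys:
        sizes[k] = sizes.get(k, 0) + 1

    large = {k for k, s in sizes.items() if s >= config.k_min}
    small = sorted(
        (k for k in sizes if k not in large),
        key=lambda k: (-sizes[k], k),
    )

    remap: dict[str, str] = {k: k for k in sizes}
    pools: list[tuple[str, list[str], int]] = []  # (pool key, members, size)
    current: list[str] = []
    current_size = 0
    for k in small:
        current.append(k)
        current_size += sizes[k]
        if current_size >= config.k_min:
            pools.append((f"POOL_{len(pools) + 1}", list(current), current_size))
            current, current_size = [], 0
    if current:
        if pools:
            # absorb the leftover into the smallest closed pool
            idx = min(range(len(pools)), key=lambda i: (pools[i][2], pools[i][0]))
            key, members, size = pools[idx]
            pools[idx] = (key, members + current, size + current_size)
        elif large:
            host = min(large, key=lambda k: (sizes[k], k))
            pools.append((host, list(current) + [host], sizes[host] + current_size))
            large.discard(host)
        else:
            # entire table is below k_min: one pool is the best we can do
            pools.append(("POOL_1", list(current), current_size))
    for key, members, _size in pools:
        for m in members:
            remap[m] = key

    assignment = [remap[k] for k in keys]
    registry: dict[str, dict] = {}
    merged_flags: dict[str, bool] = {}
    for k in large:
        registry[k] = {"size": sizes[k], "prefixes": {k}}
        merged_flags[k] = False
    for key, members, size in pools:
        registry[key] = {"size": size, "prefixes": set(members)}
        merged_flags[key] = True
    return EntityGrouping(assignment=assignment, registry=registry, merged_flags=merged_flags)


def swap_within_groups(
    table: RelationalTable, grouping: EntityGrouping, rng: Random
) -> RelationalTable:
    """Independently permute each column's values within each entity group.

    Every column participates, including pseudonymized identifiers and the
    ICD column itself, and empty cells are permuted like any other value so
    per-group missingness marginals are preserved.  A fresh Fisher–Yates
    shuffle is drawn per (group, column).
    """
    if len(grouping.assignment) != table.n_rows:
        raise ValueError(
            f"grouping covers {len(grouping.assignment)} rows, table has {table.n_rows}"
        )
    out = table.copy()
    rows_by_group = grouping.rows_by_group()
    col_arrays = {c: [str(v) for v in out.data[c]] for c in out.columns}
    for key in sorted(rows_by_group):
        idx = rows_by_group[key]
        if len(idx) < 2:
            continue
        for col in out.columns:
            values = [col_arrays[col][i] for i in idx]
            rng.shuffle(values)
            for i, v in zip(idx, values):
                col_arrays[col][i] = v
    for c in out.columns:
        out.data[c] = col_arrays[c]
    return out


def sample_rows(
    table: RelationalTable, config: SwapConfig, rng: Random
) -> RelationalTable:
    """Delete exactly floor(sample_fraction * n) rows, chosen uniformly.

    Surviving rows keep their relative order.
    """
    n = table.n_rows
    n_delete = math.floor(config.sample_fraction * n)
    if n_delete == 0:
        return table.copy()
    doomed = set(rng.sample(range(n), n_delete))
    keep = [i for i in range(n) if i not in doomed]
    out = table.copy()
    out.data = out.data.iloc[keep].reset_index(drop=True)
    return out
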