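"""Pipeline orchestration: validate -> measures -> swap -> sample -> write.

One secret salt and one randomness source serve the whole run, so
cross-table identifiers stay consistent through the measures stage and the
swapping stage destroys them together.  The run is fail-closed: every
table is validated and transformed in memory before a single output file
is written, because a partially anonymized export is the worst possible
failure mode for this tool.

The audit report counts what happened (tables, fields per measure, shift
offsets, group sizes, rows before/after sampling) without ever recording a
row-level mapping between input and output.  ``verify_output`` re-checks
the finished run from the outside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dictionary import (
    DataDictionary,
    Measure,
    load_dictionary,
    validate_dictionary,
)
from .swapper import (
    SwapConfig,
    build_entity_groups,
    sample_rows,
    swap_within_groups,
)
from .tables import RelationalTable, read_table, write_table
from .transforms import (
    COMBINED_OFFSETS,
    SPLIT_OFFSETS,
    RunSecrets,
    ShiftAudit,
    _parse_combined,
    _parse_split,
    apply_measures,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "AuditReport",
    "VerificationReport",
    "run_pipeline",
    "verify_output",
]

log = logging.getLogger("swapset")

REPORT_JSON = "swapset_report.json"
REPORT_TEXT = "swapset_report.txt"
INTERMEDIATE_DIR = "intermediates"


class PipelineError(RuntimeError):
    """Configuration or orchestration failure; nothing was exported."""


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Test mode accepts an injected seed and salt and may keep the pre-swap
    intermediates; production mode forbids all three, since intermediates
    retain row linkage and a persisted seed or salt would make the
    pseudonyms reversible.
    """

    input_dir: Path
    dictionary_path: Path
    output_dir: Path
    swap: SwapConfig = field(default_factory=SwapConfig)
    icd_fields: dict[str, str] = field(default_factory=dict)
    mode: str = "production"
    test_seed: int | None = None
    test_salt: bytes | None = None
    keep_intermediates: bool = False
    bad_date_policy: str = "blank"
    unknown_policy: str = "error"

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.dictionary_path = Path(self.dictionary_path)
        self.output_dir = Path(self.output_dir)
        if self.mode not in ("production", "test"):
            raise PipelineError(f"mode must be 'production' or 'test', got {self.mode!r}")
        if self.mode == "production":
            offending = [
                name
                for name, v in (
                    ("test_seed", self.test_seed),
                    ("test_salt", self.test_salt),
                    ("keep_intermediates", self.keep_intermediates or None),
                )
                if v is not None
            ]
            if offending:
                raise PipelineError(
                    f"{', '.join(offending)} only permitted in test mode"
                )
        if self.test_salt is not None and len(self.test_salt) != 16:
            raise PipelineError("test_salt must be exactly 16 bytes")
        if self.bad_date_policy not in ("blank", "error"):
            raise PipelineError(f"invalid bad_date_policy {self.bad_date_policy!r}")
        if self.unknown_policy not in ("error", "delete"):
            raise PipelineError(f"invalid unknown_policy {self.unknown_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise PipelineError(f"{path}: config must be a mapping")
        swap_raw = raw.pop("swap", {}) or {}
        icd_fields = swap_raw.pop("icd_fields", raw.pop("icd_fields", {})) or {}
        salt = raw.pop("test_salt", None)
        if isinstance(salt, str):
            salt = bytes.fromhex(salt)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs: dict = dict(raw)
        kwargs["swap"] = SwapConfig(**swap_raw)
        kwargs["icd_fields"] = dict(icd_fields)
        if salt is not None:
            kwargs["test_salt"] = salt
        kwargs.update(overrides)
        return cls(**kwargs)

    def swap_for(self, table_name: str) -> SwapConfig:
        icd = self.icd_fields.get(table_name)
        return dataclasses.replace(self.swap, icd_field=icd)


@dataclass
class AuditReport:
    """Per-run accounting; all numbers, no values, no row mappings."""

    tables: dict[str, dict] = field(default_factory=dict)
    measure_counts: dict[str, int] = field(
        default_factory=lambda: {m.name: 0 for m in Measure}
    )
    shift_audit: dict = field(default_factory=dict)
    sample_fraction: float = 0.30
    k_min: int = 25
    totals: dict[str, int] = field(default_factory=dict)

    def finalize(self) -> None:
        described = len(self.tables)
        excluded = sum(1 for t in self.tables.values() if t["excluded"])
        fields_total = sum(self.measure_counts.values())
        modified = (
            self.measure_counts["DELETION"]
            + self.measure_counts["PSEUDONYMIZATION"]
            + self.measure_counts["DATE_RANDOMIZATION"]
        )
        self.totals = {
            "tables_described": described,
            "tables_excluded": excluded,
            "tables_output": described - excluded,
            "fields_total": fields_total,
            "fields_modified": modified,
        }

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "measure_counts": self.measure_counts,
            "sample_fraction": self.sample_fraction,
            "k_min": self.k_min,
            "tables": self.tables,
            "shift_audit": self.shift_audit,
        }

    def to_text(self) -> str:
        lines = ["swapset run report", "=" * 40]
        for k, v in self.totals.items():
            lines.append(f"{k.replace('_', ' ')}: {v}")
        lines.append("-" * 40)
        lines.append("fields per measure:")
        for m, n in self.measure_counts.items():
            lines.append(f"  {m}: {n}")
        lines.append("-" * 40)
        for name, info in self.tables.items():
            if info["excluded"]:
                lines.append(f"{name}: EXCLUDED")
                continue
            g = info["groups"]
            lines.append(
                f"{name}: rows {info['rows_in']} -> {info['rows_out']}; "
                f"groups n={g['count']} min={g['min_size']} max={g['max_size']} "
                f"merged_pools={g['merged_pools']}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_dict(cls, raw: dict) -> "AuditReport":
        rep = cls(
            tables=raw.get("tables", {}),
            measure_counts=raw.get("measure_counts", {m.name: 0 for m in Measure}),
            shift_audit=raw.get("shift_audit", {}),
            sample_fraction=raw.get("sample_fraction", 0.30),
            k_min=raw.get("k_min", 25),
        )
        rep.totals = raw.get("totals", {})
        return rep


def _load_input_tables(
    input_dir: Path, dictionary_path: Path | None = None
) -> list[RelationalTable]:
    skip = dictionary_path.resolve() if dictionary_path is not None else None
    paths = sorted(
        p
        for p in input_dir.glob("*.csv")
        if p.is_file() and p.resolve() != skip
    )
    if not paths:
        raise PipelineError(f"no .csv tables found in {input_dir}")
    return [read_table(p) for p in paths]


def _make_secrets(config: PipelineConfig) -> RunSecrets:
    if config.mode == "test":
        seed = config.test_seed if config.test_seed is not None else 0
        return RunSecrets.for_testing(seed, config.test_salt)
    return RunSecrets.production()


def run_pipeline(config: PipelineConfig) -> AuditReport:
    """Execute a full anonymization run; returns the audit report.

    All transformation happens in memory; output files (and the report)
    are written only after every table succeeded.
    """
    tables = _load_input_tables(config.input_dir, config.dictionary_path)
    dictionary = load_dictionary(config.dictionary_path)
    dictionary = validate_dictionary(dictionary, tables, config.unknown_policy)

    run_secrets = _make_secrets(config)
    report = AuditReport(
        sample_fraction=config.swap.sample_fraction, k_min=config.swap.k_min
    )
    for m, n in dictionary.measure_counts().items():
        report.measure_counts[m] = n

    combined_audit = ShiftAudit()
    outputs: list[RelationalTable] = []
    measured_stage: list[RelationalTable] = []
    swapped_stage: list[RelationalTable] = []

    for table in tables:
        if table.name in dictionary.excluded_tables:
            log.info("table %s: excluded, no output", table.name)
            report.tables[table.name] = {
                "rows_in": table.n_rows,
                "rows_out": 0,
                "excluded": True,
            }
            continue
        measured, audit = apply_measures(
            table, dictionary, run_secrets, config.bad_date_policy
        )
        combined_audit.shifts.update(audit.shifts)
        combined_audit.unparsable.update(audit.unparsable)
        swap_cfg = config.swap_for(table.name)
        grouping = build_entity_groups(measured, swap_cfg)
        swapped = swap_within_groups(measured, grouping, run_secrets.rng)
        sampled = sample_rows(swapped, swap_cfg, run_secrets.rng)
        sizes = [info["size"] for info in grouping.registry.values()]
        report.tables[table.name] = {
            "rows_in": table.n_rows,
            "rows_out": sampled.n_rows,
            "excluded": False,
            "groups": {
                "count": len(sizes),
                "min_size": min(sizes) if sizes else 0,
                "max_size": max(sizes) if sizes else 0,
                "merged_pools": grouping.n_merged_pools(),
            },
        }
        log.info(
            "table %s: %d fields, rows %d -> %d, %d swap groups",
            table.name, len(table.columns), table.n_rows, sampled.n_rows, len(sizes),
        )
        outputs.append(sampled)
        measured_stage.append(measured)
        swapped_stage.append(swapped)

    report.shift_audit = combined_audit.to_dict()
    report.finalize()

    config.output_dir.mkdir(parents=True, exist_ok=True)
    for t in outputs:
        write_table(t, config.output_dir / f"{t.name}.csv")
    (config.output_dir / REPORT_JSON).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (config.output_dir / REPORT_TEXT).write_text(report.to_text(), encoding="utf-8")
    if config.keep_intermediates and config.mode == "test":
        inter = config.output_dir / INTERMEDIATE_DIR
        (inter / "measured").mkdir(parents=True, exist_ok=True)
        (inter / "swapped").mkdir(parents=True, exist_ok=True)
        for t in measured_stage:
            write_table(t, inter / "measured" / f"{t.name}.csv")
        for t in swapped_stage:
            write_table(t, inter / "swapped" / f"{t.name}.csv")
    return report


@dataclass
class VerificationReport:
    """Outcome of the post-run checks: name -> passed/failed/skipped."""

    checks: dict[str, dict] = field(default_factory=dict)

    def record(self, name: str, passed: bool | None, detail: str = "") -> None:
        status = "skipped" if passed is None else ("pass" if passed else "FAIL")
        self.checks[name] = {"status": status, "detail": detail}

    @property
    def ok(self) -> bool:
        return all(c["status"] != "FAIL" for c in self.checks.values())

    def to_dict(self) -> dict:
        return {"ok": self.ok, "checks": self.checks}

    def to_text(self) -> str:
        lines = [f"verification: {'OK' if self.ok else 'FAILED'}"]
        for name, c in self.checks.items():
            lines.append(f"  [{c['status']:>7}] {name}" + (f" — {c['detail']}" if c["detail"] else ""))
        return "\n".join(lines) + "\n"


def _admissible(offset: int, combined: bool) -> bool:
    return offset in (COMBINED_OFFSETS if combined else SPLIT_OFFSETS)


def verify_output(
    input_dir: str | Path,
    output_dir: str | Path,
    dictionary_path: str | Path,
    report: AuditReport,
    intermediates: str | Path | None = None,
    icd_fields: dict[str, str] | None = None,
) -> VerificationReport:
    """Independently re-check a finished run against its inputs.

    Checks: deletion columns empty; no raw identifier from a deleted or
    pseudonymized input column survives anywhere in the output; exact
    sampled row counts; excluded tables absent; headers and column order
    identical; minimum group size; and — when test-mode intermediates are
    available — per-group per-column multiset conservation and shift
    admissibility.  Checks needing missing intermediates are reported as
    skipped, never as failed.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    icd_fields = icd_fields or {}
    vr = VerificationReport()
    in_tables = {
        t.name: t for t in _load_input_tables(input_dir, Path(dictionary_path))
    }
    dictionary = load_dictionary(dictionary_path)

    out_tables: dict[str, RelationalTable] = {}
    for name in in_tables:
        p = output_dir / f"{name}.csv"
        if p.exists():
            out_tables[name] = read_table(p)

    # (d) excluded tables absent
    leaked = [t for t in dictionary.excluded_tables if (output_dir / f"{t}.csv").exists()]
    vr.record("excluded_tables_absent", not leaked, f"present: {leaked}" if leaked else "")

    # (g) headers and column order identical
    bad_headers = [
        name
        for name, t in out_tables.items()
        if t.columns != in_tables[name].columns
    ]
    vr.record("headers_identical", not bad_headers, ", ".join(bad_headers))

    # (a) deletion columns entirely empty
    offenders = []
    for e in dictionary.entries:
        if e.measure is not Measure.DELETION:
            continue
        t = out_tables.get(e.table_name)
        if t is None or e.field_name not in t.columns:
            continue
        if any(str(v) for v in t.data[e.field_name]):
            offenders.append(f"{e.table_name}.{e.field_name}")
    vr.record("deletion_columns_empty", not offenders, ", ".join(offenders))

    # (b) raw-identifier leak scan
    raw_values: set[str] = set()
    for e in dictionary.entries:
        if e.measure not in (Measure.DELETION, Measure.PSEUDONYMIZATION):
            continue
        t = in_tables.get(e.table_name)
        if t is None or e.field_name not in t.columns:
            continue
        raw_values.update(v for v in (str(x) for x in t.data[e.field_name]) if v)
    leak = None
    for name, t in out_tables.items():
        for col in t.columns:
            hits = {str(v) for v in t.data[col]} & raw_values
            if hits:
                leak = f"{name}.{col}"
                break
        if leak:
            break
    vr.record("no_raw_identifier_leak", leak is None, leak or "")

    # (c) exact sampled row counts
    bad_counts = []
    f = report.sample_fraction
    for name, t in out_tables.items():
        n_in = in_tables[name].n_rows
        expected = n_in - math.floor(f * n_in)
        if t.n_rows != expected:
            bad_counts.append(f"{name}: {t.n_rows} != {expected}")
    vr.record("sampled_row_counts", not bad_counts, "; ".join(bad_counts))

    # (f) minimum entity-group size
    small = []
    for name, info in report.tables.items():
        if info.get("excluded"):
            continue
        g = info.get("groups", {})
        if in_tables.get(name) is not None and in_tables[name].n_rows >= report.k_min:
            if g.get("min_size", 0) < report.k_min:
                small.append(f"{name}: min {g.get('min_size')}")
    vr.record("min_group_size", not small, "; ".join(small))

    # (e) intermediate-stage checks (test mode only)
    if intermediates is None:
        vr.record("swap_multisets_conserved", None, "no intermediates")
        vr.record("date_shifts_admissible", None, "no intermediates")
        return vr

    inter = Path(intermediates)
    measured_dir, swapped_dir = inter / "measured", inter / "swapped"
    if not measured_dir.is_dir() or not swapped_dir.is_dir():
        vr.record("swap_multisets_conserved", None, "intermediates incomplete")
        vr.record("date_shifts_admissible", None, "intermediates incomplete")
        return vr

    multiset_bad = []
    for p in sorted(measured_dir.glob("*.csv")):
        name = p.stem
        measured = read_table(p)
        swapped_p = swapped_dir / p.name
        if not swapped_p.exists():
            multiset_bad.append(f"{name}: swapped stage missing")
            continue
        swapped = read_table(swapped_p)
        cfg = SwapConfig(
            icd_field=icd_fields.get(name),
            k_min=report.k_min,
            sample_fraction=report.sample_fraction,
        )
        grouping = build_entity_groups(measured, cfg)
        for key, idx in grouping.rows_by_group().items():
            for col in measured.columns:
                before = sorted(str(measured.data[col].iloc[i]) for i in idx)
                after = sorted(str(swapped.data[col].iloc[i]) for i in idx)
                if before != after:
                    multiset_bad.append(f"{name}.{col} group {key}")
    vr.record("swap_multisets_conserved", not multiset_bad, "; ".join(multiset_bad[:5]))

    shift_bad = []
    for e in dictionary.entries:
        if e.measure is not Measure.DATE_RANDOMIZATION or e.date_group is not None:
            continue
        p = measured_dir / f"{e.table_name}.csv"
        if not p.exists() or e.table_name not in in_tables:
            continue
        measured = read_table(p)
        original = in_tables[e.table_name]
        for i in range(original.n_rows):
            ov, mv = str(original.data[e.field_name].iloc[i]), str(measured.data[e.field_name].iloc[i])
            if not ov or not mv:
                continue
            try:
                delta = (_parse_combined(mv) - _parse_combined(ov)).days
            except ValueError:
                continue
            if not _admissible(delta, combined=True):
                shift_bad.append(f"{e.table_name}.{e.field_name} row {i}: {delta}")
    groups_seen: set[tuple[str, str]] = set()
    for e in dictionary.entries:
        if e.date_group is None or (e.table_name, e.date_group) in groups_seen:
            continue
        groups_seen.add((e.table_name, e.date_group))
        roles = {
            x.date_role: x.field_name
            for x in dictionary.entries
            if x.table_name == e.table_name and x.date_group == e.date_group
        }
        p = measured_dir / f"{e.table_name}.csv"
        if not p.exists() or e.table_name not in in_tables:
            continue
        measured = read_table(p)
        original = in_tables[e.table_name]
        for i in range(original.n_rows):
            try:
                before = _parse_split(
                    str(original.data[roles["day"]].iloc[i]),
                    str(original.data[roles["month"]].iloc[i]),
                    str(original.data[roles["year"]].iloc[i]),
                )
                after = _parse_split(
                    str(measured.data[roles["day"]].iloc[i]),
                    str(measured.data[roles["month"]].iloc[i]),
                    str(measured.data[roles["year"]].iloc[i]),
                )
            except ValueError:
                continue
            if not _admissible((after - before).days, combined=False):
                shift_bad.append(f"{e.table_name}.{e.date_group} row {i}")
    vr.record("date_shifts_admissible", not shift_bad, "; ".join(shift_bad[:5]))
    return vr
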