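"""Synthetic tumor-registry generator.

Emits a linked four-table data set shaped like a hospital tumor
documentation export — a patient identity table with split birth-date
columns, a tumor table with ICD-10 codes and combined-format diagnosis
dates, a therapy table, and a molecular-pathology table — together with the
matching data dictionary, so the whole anonymization pipeline can be
exercised without any real patient data.

The ICD-10 code distribution mixes a few frequent cancer entities (breast,
lung, colon, prostate, pancreas) with a long tail of rare codes whose
3-character groups fall well below the k=25 merge threshold, because that
tail is exactly what the group-merging rule exists for.  All identity text
comes from small word lists; no real-person data appears anywhere.

``inject_pathologies`` then plants the messiness of routine data the
pipeline must survive: malformed dates, truncated ICD codes, and repeated
identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from random import Random

from .dictionary import DataDictionary, FieldEntry, Measure
from .tables import RelationalTable

__all__ = ["RegistryConfig", "generate_registry", "inject_pathologies"]

# frequent entities carry almost all the mass; the tail codes each get a
# weight small enough that their 3-char groups stay under 25 members at the
# default scale of ~3000 tumors (expected count ~= weight/total * 3000).
DEFAULT_ICD_DISTRIBUTION: tuple[tuple[str, float], ...] = (
    ("C50.9", 18.0), ("C50.4", 8.0), ("C50.8", 6.0),
    ("C34.9", 12.0), ("C34.1", 5.0), ("C34.2", 3.0),
    ("C18.9", 9.0), ("C18.2", 4.0),
    ("C61", 11.0),
    ("C25.9", 6.0),
    ("C16.9", 4.0), ("C20", 4.0), ("C67.9", 3.0),
    # long tail of rare codes (each expected < 25 of ~3000 tumors)
    ("C37", 0.2), ("C38.1", 0.25), ("C40.2", 0.3), ("C45.1", 0.2),
    ("C46.7", 0.15), ("C48.2", 0.3), ("C58", 0.1), ("C7A.0", 0.2),
    ("C17.1", 0.35), ("C23", 0.3), ("C31.0", 0.2), ("C33", 0.15),
    ("C69.3", 0.25), ("C74.9", 0.2), ("C75.1", 0.1),
)

DEFAULT_MISSINGNESS: dict[str, float] = {
    "address": 0.10,
    "diagnosis_date": 0.05,
    "therapy_type": 0.10,
    "therapy_start_date": 0.08,
    "gene": 0.15,
    "variant": 0.25,
}

_FIRST_NAMES = (
    "Anna", "Ben", "Clara", "David", "Emma", "Felix", "Greta", "Hans",
    "Ida", "Jonas", "Katrin", "Lukas", "Marie", "Nils", "Olga", "Paul",
    "Rosa", "Stefan", "Tanja", "Uwe",
)
_LAST_NAMES = (
    "Albrecht", "Bauer", "Christiansen", "Dietrich", "Ebert", "Fischer",
    "Gruber", "Hoffmann", "Ilgner", "Jung", "Keller", "Lang", "Meier",
    "Neumann", "Otto", "Peters", "Richter", "Schmidt", "Thaler", "Vogel",
)
_STREETS = (
    "Ahornweg", "Birkenstr.", "Carlplatz", "Dornallee", "Eichenweg",
    "Feldstr.", "Gartenweg", "Hauptstr.", "Lindenallee", "Marktplatz",
)
_GENES = (
    "TP53", "KRAS", "EGFR", "BRCA1", "BRCA2", "PIK3CA", "BRAF", "ALK",
    "HER2", "APC", "PTEN", "MET",
)
_THERAPY_TYPES = ("Chemotherapy", "Radiation", "Surgery", "Immunotherapy", "Hormone therapy")


@dataclass
class RegistryConfig:
    """Parameters of the synthetic registry.

    Defaults produce 2,000 patients and roughly 3,000 tumors — large enough
    for the rare-code tail and the group-merge rule to matter, small enough
    that a full pipeline run takes seconds.
    """

    n_patients: int = 2000
    icd_distribution: tuple[tuple[str, float], ...] = DEFAULT_ICD_DISTRIBUTION
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    date_window: tuple[date, date] = (date(2005, 1, 1), date(2022, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(w <= 0 for _, w in self.icd_distribution):
            raise ValueError("ICD weights must be positive")
        if self.date_window[0] >= self.date_window[1]:
            raise ValueError("date_window must satisfy earliest < latest")
        if any(not (0 <= p <= 1) for p in self.missingness.values()):
            raise ValueError("missingness probabilities must be in [0, 1]")


def _fmt(d: date) -> str:
    return f"{d.day:02d}.{d.month:02d}.{d.year:04d}"


def _rand_date(rng: Random, lo: date, hi: date) -> date:
    return lo + timedelta(days=rng.randrange((hi - lo).days + 1))


def _maybe_blank(rng: Random, value: str, p: float) -> str:
    return "" if p > 0 and rng.random() < p else value


def generate_registry(
    config: RegistryConfig,
) -> tuple[list[RelationalTable], DataDictionary]:
    """Generate the four linked tables plus their data dictionary.

    Deterministic given ``config.seed``.  Referential integrity holds:
    every tumor's patient, every therapy's tumor, and every molecular
    sample's tumor exist.
    """
    rng = Random(config.seed)
    miss = config.missingness
    codes = [c for c, _ in config.icd_distribution]
    weights = [w for _, w in config.icd_distribution]
    lo, hi = config.date_window

    patients: list[list[str]] = []
    tumors: list[list[str]] = []
    therapies: list[list[str]] = []
    molpath: list[list[str]] = []

    tumor_no = 0
    therapy_no = 0
    sample_no = 0
    for p in range(config.n_patients):
        pid = f"{10_000_000 + p:010d}"
        birth = _rand_date(rng, date(1925, 1, 1), date(1995, 12, 31))
        patients.append(
            [
                pid,
                rng.choice(_FIRST_NAMES),
                rng.choice(_LAST_NAMES),
                f"{birth.day:02d}",
                f"{birth.month:02d}",
                f"{birth.year:04d}",
                _maybe_blank(
                    rng,
                    f"{rng.choice(_STREETS)} {rng.randrange(1, 200)}, "
                    f"{rng.randrange(10000, 99999)} Musterstadt",
                    miss.get("address", 0.0),
                ),
            ]
        )
        n_tumors = rng.choices((1, 2, 3), weights=(70, 20, 10))[0]
        for _ in range(n_tumors):
            tumor_no += 1
            tid = f"{tumor_no:07d}"
            code = rng.choices(codes, weights=weights)[0]
            diag = _rand_date(rng, lo, hi)
            tumors.append(
                [
                    tid,
                    pid,
                    code,
                    _maybe_blank(rng, _fmt(diag), miss.get("diagnosis_date", 0.0)),
                ]
            )
            for _ in range(rng.choices((0, 1, 2), weights=(30, 50, 20))[0]):
                therapy_no += 1
                start = _rand_date(rng, diag, min(hi, diag + timedelta(days=365)))
                therapies.append(
                    [
                        f"T{therapy_no:07d}",
                        tid,
                        _maybe_blank(rng, _fmt(start), miss.get("therapy_start_date", 0.0)),
                        _maybe_blank(rng, rng.choice(_THERAPY_TYPES), miss.get("therapy_type", 0.0)),
                    ]
                )
            if rng.random() < 0.4:
                sample_no += 1
                gene = rng.choice(_GENES)
                molpath.append(
                    [
                        f"S{sample_no:07d}",
                        tid,
                        _maybe_blank(rng, gene, miss.get("gene", 0.0)),
                        _maybe_blank(
                            rng,
                            f"p.{rng.choice('ACDEFGHIKLMNPQRSTVWY')}"
                            f"{rng.randrange(10, 900)}"
                            f"{rng.choice('ACDEFGHIKLMNPQRSTVWY')}",
                            miss.get("variant", 0.0),
                        ),
                    ]
                )

    tables = [
        RelationalTable.from_rows(
            "PATIENTS",
            ["patient_id", "first_name", "last_name", "birth_day", "birth_month", "birth_year", "address"],
            patients,
        ),
        RelationalTable.from_rows(
            "TUMORS", ["tumor_id", "patient_id", "icd10_code", "diagnosis_date"], tumors
        ),
        RelationalTable.from_rows(
            "THERAPIES",
            ["therapy_id", "tumor_id", "therapy_start_date", "therapy_type"],
            therapies,
        ),
        RelationalTable.from_rows(
            "MOLPATH", ["sample_id", "tumor_id", "gene", "variant"], molpath
        ),
    ]
    return tables, _registry_dictionary()


def _registry_dictionary() -> DataDictionary:
    e = FieldEntry
    M = Measure
    entries = [
        e("PATIENTS", "patient_id", "Patient ID", M.PSEUDONYMIZATION),
        e("PATIENTS", "first_name", "First name", M.DELETION),
        e("PATIENTS", "last_name", "Last name", M.DELETION),
        e("PATIENTS", "birth_day", "Birth date (day)", M.DATE_RANDOMIZATION, "birth_date", "day"),
        e("PATIENTS", "birth_month", "Birth date (month)", M.DATE_RANDOMIZATION, "birth_date", "month"),
        e("PATIENTS", "birth_year", "Birth date (year)", M.DATE_RANDOMIZATION, "birth_date", "year"),
        e("PATIENTS", "address", "Home address", M.DELETION),
        e("TUMORS", "tumor_id", "Tumor ID", M.PSEUDONYMIZATION),
        e("TUMORS", "patient_id", "Patient ID (link)", M.PSEUDONYMIZATION),
        e("TUMORS", "icd10_code", "ICD-10 diagnosis code", M.NO_ACTION),
        e("TUMORS", "diagnosis_date", "Date of diagnosis", M.DATE_RANDOMIZATION),
        e("THERAPIES", "therapy_id", "Therapy ID", M.PSEUDONYMIZATION),
        e("THERAPIES", "tumor_id", "Tumor ID (link)", M.PSEUDONYMIZATION),
        e("THERAPIES", "therapy_start_date", "Start of therapy", M.DATE_RANDOMIZATION),
        e("THERAPIES", "therapy_type", "Therapy modality", M.NO_ACTION),
        e("MOLPATH", "sample_id", "Sample ID", M.PSEUDONYMIZATION),
        e("MOLPATH", "tumor_id", "Tumor ID (link)", M.PSEUDONYMIZATION),
        e("MOLPATH", "gene", "Gene symbol", M.NO_ACTION),
        e("MOLPATH", "variant", "Variant (protein notation)", M.NO_ACTION),
    ]
    return DataDictionary(entries=entries)


def inject_pathologies(
    tables: list[RelationalTable], config: RegistryConfig
) -> list[RelationalTable]:
    """Deterministically plant routine-data edge cases into the registry.

    Adds malformed date strings, ICD codes shorter than 3 characters,
    duplicated patient visits (rows repeating existing IDs), and extra rows
    for at least five rare ICD codes so group merging is always exercised.
    Derives its own stream from ``config.seed``; never removes rows.
    """
    rng = Random(config.seed + 0x5EED)
    out = {t.name: t.copy() for t in tables}

    tumors = out["TUMORS"]
    rows = [list(map(str, r)) for r in tumors.data.itertuples(index=False)]
    n = len(rows)
    bad_dates = ("00.13.2020", "31.02.2019", "7.4.2021", "not-a-date")
    for j, bad in enumerate(bad_dates):
        rows[rng.randrange(n)][3] = bad
    short_codes = ("C5", "D", "")
    for code in short_codes:
        rows[rng.randrange(n)][2] = code
    # duplicate visits: repeat a few existing rows verbatim (repeated IDs)
    for _ in range(5):
        rows.append(list(rows[rng.randrange(n)]))
    # guarantee >= 5 rare 3-char groups under any k threshold in use
    for i, code in enumerate(("C96.9", "C97", "C88.4", "C84.0", "C81.1")):
        donor = rows[rng.randrange(n)]
        rows.append([f"X{i:06d}", donor[1], code, donor[3]])
    out["TUMORS"] = RelationalTable.from_rows(tumors.name, tumors.columns, rows)

    therapies = out["THERAPIES"]
    trows = [list(map(str, r)) for r in therapies.data.itertuples(index=False)]
    if trows:
        trows[rng.randrange(len(trows))][2] = "99.99.9999"
        out["THERAPIES"] = RelationalTable.from_rows(
            therapies.name, therapies.columns, trows
        )
    return [out[t.name] for t in tables]
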