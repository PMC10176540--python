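# Methods

## The procedure and its assumptions

swapset implements statistical disclosure control by *value swapping*
(data shuffling) rather than by generalization or suppression. The threat
model is re-identification through linkage: even after direct identifiers
(IDAT: names, addresses) are removed, the combination of quasi-identifiers
inside the medical content (MDAT) — dates, rare diagnosis combinations,
unusual treatment patterns — can single out a person. Swapping attacks the
linkage itself: after every column has been independently permuted within
its entity group, a row is a *fake tuple* assembled from several real
patients, so no combination of its fields refers to one person. What
survives, by construction, is the per-column marginal distribution and
missingness pattern inside each group — exactly the information an
external partner needs to judge whether a planned analysis is feasible on
the real data.

The pipeline assumes flat-file exports of the relational source (one
delimited text file per table, header row of field names), treats every
cell as opaque text, and is driven entirely by the data record description
(the dictionary). It does not connect to live databases and does not
attempt automatic classification of fields as identifiers; curating the
dictionary is deliberately a human task.

Stage order is fixed: **measures → swap → sample**. Measures run first so
that identifiers are already pseudonymized when swapping permutes them;
sampling runs last so that the deleted rows thin the already-unlinked
data, making the original frequencies unrecoverable.

## Parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| combined date offset | ±3…±6 | days | admissible signed offsets, uniform over the 8 values, drawn fresh per value |
| split date offset | ±2…±10 | days | uniform over the 18 values; triple recombined, shifted, redistributed |
| salt length | 16 | bytes | drawn from the OS CSPRNG per run; never persisted |
| digest | SHA3-256 | — | full lowercase hex; truncation would add collision risk for no benefit |
| `k_min` | 25 | rows | minimum entity-group size after merging |
| `icd_prefix_len` | 3 | chars | ICD-10 category level (letter + two digits) |
| `sample_fraction` | 0.30 | — | exact-count deletion, ⌊f·n⌋ rows per table |

The offset ranges are taken literally as the admissible sets {±3,…,±6}
and {±2,…,±10}: zero and the offsets adjacent to zero never occur, sign
and magnitude are independent and uniform. Uniformity is the
least-assumption choice where no distribution is prescribed.

Pseudonymization concatenates `value ‖ salt` (salt appended, byte level);
the order is fixed so an independent SHA-3 implementation can serve as a
test oracle. Empty cells pass through every measure unchanged — hashing
the empty string would fabricate one high-frequency fake token and distort
the missingness structure the output is supposed to preserve.

## Group merging

The merge rule for undersized entity groups is deterministic given the
group counts: sort groups of size < `k_min` by size descending (ties by
key), accumulate greedily into pools, closing a pool as soon as it reaches
`k_min`; a final still-undersized pool is absorbed into the smallest
closed pool, or, if none exists, into the smallest full-size group. A
table with fewer than `k_min` rows in total becomes a single pool — the
guarantee "every group ≥ k_min" holds whenever the table itself has at
least `k_min` rows. Codes shorter than the prefix length (including empty
cells) go to a reserved `UNKNOWN` group that is merged like any other.
Tables with no configured ICD column are swapped as one whole-table group.

Which tables get grouped swapping is configuration (`icd_fields`); the
package does not guess. A pre-swap join from ID-linked tables to their
tumor's ICD code would be possible via the run-consistent pseudonyms but
is not enabled by default, since grouped swapping of the tumor table alone
already carries the disease-level utility.

## Modes, determinism, irreversibility

Production mode uses `random.SystemRandom` and a fresh salt, refuses
injected seeds/salts and never writes intermediates — the pre-swap stages
retain row linkage and must not exist on disk. Test mode accepts a seed
and a salt and may keep intermediates; with both fixed, the entire output
tree is bit-reproducible, which is what the deep verification checks
(multiset conservation per group and column, shift admissibility per cell)
are run against. The audit report contains only counts and offset
histograms, never values, row indices or mappings, so neither the report
nor the logs can act as a de-anonymization key.

## The synthetic registry

The generator emulates the *structural* features of a tumor-documentation
export that the anonymizer must handle: four linked tables (patients with
split birth-date columns and identity text, tumors with ICD-10 codes and
combined-format diagnosis dates, therapies, molecular pathology), a code
distribution dominated by a few frequent entities with a long tail of rare
codes whose 3-character groups fall below `k_min`, per-field missingness,
and — via `inject_pathologies` — malformed dates, truncated codes and
duplicated visit rows. Defaults are 2,000 patients / roughly 3,000 tumors:
the pipeline is linear in rows, so scale adds nothing to correctness and
the full suite stays in seconds. Identity text comes from fixed word
lists; no real-person data exists anywhere in the package.

What the generator does **not** emulate: clinical plausibility of
code/therapy/variant combinations, survival structure, inter-field
correlations, realistic name frequency distributions, or encoding quirks
of specific registry software. Passing tests therefore demonstrate the
transformation contracts (exact counts, bounds, conservation laws,
irreversibility mechanics) — not that any particular real export is free
of further pathologies.

## Numerical and degenerate-input choices

* Combined dates must match `\d{2}\.\d{2}\.\d{4}` and be valid Gregorian
  dates; split triples must be all-digit and form a valid date. Anything
  else is, by policy, either blanked and counted in the audit (default —
  routine data is messy) or aborts the run before any output is written.
* Split-date output preserves each input column's zero-padding width
  (`zfill` to the input width, never truncating).
* Swapping uses one `Fisher–Yates` shuffle per (group, column), iterating
  groups in sorted key order and columns in table order, so a seeded run
  is reproducible. A group of size 1 is a no-op.
* Sampling deletes exactly ⌊f·n⌋ rows chosen without replacement;
  survivors keep their relative order.
* The run is fail-closed: every table is transformed in memory and any
  validation error aborts before the first output file is written. A
  partially anonymized export is the worst failure mode for this tool.
* Dictionary fields unknown to the curators can be synthesized as
  Deletion entries (`unknown_policy=delete`): an undescribed field is
  erased rather than leaked.

## Known limitations

* No formal disclosure-risk metric (k-anonymity, l-diversity, t-closeness)
  is computed; the verification command checks the mechanics of this
  procedure, not a general privacy bound.
* Rank swapping and correlation-preserving variants are out of scope; all
  cross-column correlation inside a group is destroyed by design.
* The leak scan in `verify_output` is an exact-substring set check on
  values from deleted/pseudonymized columns; it cannot detect partial or
  transformed leaks.
* Frequencies of very rare categorical values inside a large group are
  preserved by swapping; sampling perturbs but does not eliminate them.

## Problem sizes used in the checks

Unit and acceptance tests run on synthetic registries of 400–1,500
patients; the shift-bound measurements use 10,000 shifted dates per
scheme; the injectivity check hashes 10^6 distinct values; the linkage
destruction property is simulated on a 5-row × 3-column group over 4,000
trials against the analytic intact-tuple expectation n^(2−c).
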