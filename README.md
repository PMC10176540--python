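# swapset

Anonymize relational health-registry exports into a **swapping data set**:
a data set with exactly the structure, per-column value distributions and
missingness of the original, but with no recoverable linkage between a row
and a natural person. External partners can develop analysis code against
the swapped data; the code is then executed in-house on the real data.
Aimed at registry teams (tumor documentation, molecular pathology) that
need to share *structure* without sharing *data*.

## The method

A curated **data record description** assigns every (table, field) pair one
of four privacy measures, which drive the pipeline field by field:

| Measure | Effect |
|---|---|
| No Action | value kept verbatim |
| Deletion | every value in the column erased (column retained) |
| Pseudonymization | value `v` → `SHA3-256(v ‖ salt)` hex, with a secret 16-byte salt drawn fresh per run and never stored |
| Date Randomization | `DD.MM.YYYY` dates shifted by a uniform random offset `s`, `|s| ∈ {3,…,6}` days; split day/month/year column triples recombined, shifted by `|s| ∈ {2,…,10}` days, and redistributed |

Then the two destructive stages:

1. **Value swapping.** Rows are partitioned into *entity groups* keyed on
   the 3-character ICD-10 category prefix; groups with fewer than *k* = 25
   observations are merged into pools so no swap group is small enough to
   leak. Within each group, every column is independently replaced by a
   uniform random permutation of its own values — per-column marginals are
   exactly preserved, cross-column linkage is destroyed.
2. **Sampling.** Exactly ⌊0.30 · *n*⌋ rows of each table are deleted
   uniformly at random, so the original record counts and frequencies
   cannot be recovered.

Output tables are written in the identical delimited-text format as the
input, alongside an audit report (counts only — never a value or a
row-level mapping) and a verification command that re-checks the finished
run from the outside.

## Worked example

Generate a synthetic 500-patient tumor registry (no real data is used
anywhere in this package), anonymize it in seeded test mode, and verify:

```sh
swapset simulate --out demo/in --patients 500 --seed 42
swapset run --input demo/in --dictionary demo/in/dictionary.csv \
            --output demo/out --mode test --test-seed 42 \
            --keep-intermediates --icd-field TUMORS=icd10_code
swapset verify --input demo/in --output demo/out \
               --dictionary demo/in/dictionary.csv \
               --icd-field TUMORS=icd10_code
```

prints

```
wrote 4 tables + dictionary to demo/in
run complete: 4/4 tables out, 15/19 fields modified
verification: OK
  [   pass] excluded_tables_absent
  [   pass] headers_identical
  [   pass] deletion_columns_empty
  [   pass] no_raw_identifier_leak
  [   pass] sampled_row_counts
  [   pass] min_group_size
  [   pass] swap_multisets_conserved
  [   pass] date_shifts_admissible
```

"15/19 fields modified" counts the dictionary entries carrying a measure
other than No Action (3 deletions, 7 pseudonymizations, 5 date
randomizations across the four tables). The tumor table goes in as

```
tumor_id,patient_id,icd10_code,diagnosis_date
0000001,0010000000,C61,26.03.2017
0000002,0010000001,C34.9,30.01.2007
```

and comes out as

```
tumor_id,patient_id,icd10_code,diagnosis_date
b789b707ecd793bc603f85db1907be919eccee2f...,ae8d5b9e76b3b079f6d3b9922374bb2bf2379e1e...,C61,20.07.2010
e77a753b95d671fcab6617a23074eada66583b25...,9fe1098a12b9185a421ddc54a155b7e90385e5a3...,C34.9,24.02.2012
```

— identifiers are salted hashes, dates and codes belong to *other* rows of
the same entity group (note the prefix is preserved: a C61 row stays C61),
and the run report records `TUMORS: rows 695 -> 487; groups n=9 min=26
max=216 merged_pools=2`: 695 tumors fell into 9 swap groups, every group
has at least 26 ≥ 25 members after two merge pools absorbed the rare
codes, and sampling kept exactly 695 − ⌊0.3 · 695⌋ = 487 rows.

In production mode (`--mode production`, the default) seeds, injected
salts and intermediates are refused, and two runs over the same input
yield disjoint pseudonym sets.

The same functionality is available as a library:

```python
from swapset import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(
    input_dir="demo/in", dictionary_path="demo/in/dictionary.csv",
    output_dir="demo/out", icd_fields={"TUMORS": "icd10_code"},
))
```

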