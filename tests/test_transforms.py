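import re
from datetime import date, timedelta
from random import Random

import pytest
from hypothesis import given, strategies as st

from swapset import (
    COMBINED_OFFSETS,
    DataDictionary,
    DateParseError,
    FieldEntry,
    Measure,
    RelationalTable,
    RunSecrets,
    SPLIT_OFFSETS,
    apply_measures,
    delete_column,
    pseudonymize_column,
    shift_date_combined,
    shift_date_split,
)

# digests computed beforehand with OpenSSL's SHA-3 implementation:
#   printf '<value>' followed by 16 zero bytes | openssl dgst -sha3-256
OPENSSL_DIGESTS = {
    "0022113344": "d8d3cec459008576d146c5211b2cc90a95bc4187bd22e46d325572bd997bfd80",
    "Mustermann": "af05111c9b939d94ef1439266ba5d96a36780eb6f1e4831bcb3bb986f47e4869",
}

ZERO_SALT = bytes(16)


def one_column(values, name="T", col="v"):
    return RelationalTable.from_rows(name, [col], [[v] for v in values])


class TestDeletion:
    def test_values_erased_column_retained(self):
        t = one_column(["Max", "Daniel", "Julia"], col="first_name")
        out = delete_column(t, "first_name")
        assert out.column_values("first_name") == ["", "", ""]
        assert out.columns == t.columns

    def test_idempotent_and_other_columns_untouched(self):
        t = RelationalTable.from_rows("T", ["a", "b"], [["x", "keep"], ["", "also"]])
        out = delete_column(delete_column(t, "a"), "a")
        assert out.column_values("a") == ["", ""]
        assert out.column_values("b") == ["keep", "also"]

    def test_large_column_fully_blanked(self):
        t = one_column([f"name{i}" for i in range(1000)])
        out = delete_column(t, "v")
        assert out.n_rows == 1000
        assert sum(1 for v in out.column_values("v") if v) == 0


class TestPseudonymization:
    def test_matches_independent_sha3_oracle(self):
        secrets = RunSecrets.for_testing(0, salt=ZERO_SALT)
        t = one_column(list(OPENSSL_DIGESTS))
        out = pseudonymize_column(t, "v", secrets)
        assert out.column_values("v") == list(OPENSSL_DIGESTS.values())

    def test_equal_inputs_equal_tokens_within_run(self, test_secrets):
        t = one_column(["0022113344", "other", "0022113344"])
        out = pseudonymize_column(t, "v", test_secrets)
        v = out.column_values("v")
        assert v[0] == v[2] and v[0] != v[1]

    def test_empty_values_stay_empty(self, test_secrets):
        out = pseudonymize_column(one_column(["", "x", ""]), "v", test_secrets)
        v = out.column_values("v")
        assert v[0] == "" and v[2] == "" and re.fullmatch(r"[0-9a-f]{64}", v[1])

    def test_fresh_production_runs_give_different_tokens(self):
        t = one_column(["0022113344"])
        a = pseudonymize_column(t, "v", RunSecrets.production()).column_values("v")
        b = pseudonymize_column(t, "v", RunSecrets.production()).column_values("v")
        assert a != b

    def test_salt_must_be_16_bytes(self):
        with pytest.raises(ValueError, match="16 bytes"):
            RunSecrets.for_testing(0, salt=b"short")


class TestCombinedShift:
    def test_admissible_offsets_are_plus_minus_3_to_6(self):
        assert sorted(COMBINED_OFFSETS) == [-6, -5, -4, -3, 3, 4, 5, 6]

    @pytest.mark.parametrize(
        "before,after",
        [("01.04.2021", "05.04.2021"), ("27.12.2015", "01.01.2016")],
    )
    def test_published_examples_are_admissible_outcomes(self, before, after):
        # the printed example outputs correspond to offsets +4 and +5
        d0 = date(int(before[6:]), int(before[3:5]), int(before[:2]))
        d1 = date(int(after[6:]), int(after[3:5]), int(after[:2]))
        assert (d1 - d0).days in COMBINED_OFFSETS
        rng = Random(0)
        outcomes = {shift_date_combined(before, rng) for _ in range(500)}
        assert after in outcomes

    def test_output_never_equals_input_and_bounds_hold(self):
        rng = Random(42)
        d0 = date(2020, 6, 15)
        for _ in range(2000):
            out = shift_date_combined("15.06.2020", rng)
            d1 = date(int(out[6:]), int(out[3:5]), int(out[:2]))
            assert 3 <= abs((d1 - d0).days) <= 6

    def test_format_preserved_across_year_rollover(self):
        rng = Random(7)
        for value in ("29.12.2019", "02.01.2020", "28.02.2020", "31.12.1999"):
            out = shift_date_combined(value, rng)
            assert re.fullmatch(r"\d{2}\.\d{2}\.\d{4}", out)

    def test_uniformity_not_rejected_at_alpha_0_001(self):
        from scipy.stats import chisquare

        rng = Random(99)
        base = date(2015, 5, 20)
        counts = {o: 0 for o in COMBINED_OFFSETS}
        for _ in range(10_000):
            out = shift_date_combined("20.05.2015", rng)
            d1 = date(int(out[6:]), int(out[3:5]), int(out[:2]))
            counts[(d1 - base).days] += 1
        assert all(v > 0 for v in counts.values())
        _, p = chisquare(list(counts.values()))
        assert p > 0.001

    @pytest.mark.parametrize("bad", ["", "1.04.2021", "00.13.2020", "31.02.2019", "2021-04-01", "not-a-date"])
    def test_unparsable_dates_raise_typed_error(self, bad):
        with pytest.raises(DateParseError):
            shift_date_combined(bad, Random(0))


class TestSplitShift:
    def test_admissible_offsets_are_plus_minus_2_to_10(self):
        assert sorted(SPLIT_OFFSETS) == sorted(
            s * m for m in range(2, 11) for s in (-1, 1)
        )

    @pytest.mark.parametrize(
        "triple,target",
        [(("25", "04", "2018"), ("30", "04", "2018")),   # offset +5
         (("19", "08", "2020"), ("10", "08", "2020"))],  # offset -9
    )
    def test_published_examples_are_admissible_outcomes(self, triple, target):
        before = date(int(triple[2]), int(triple[1]), int(triple[0]))
        after = date(int(target[2]), int(target[1]), int(target[0]))
        assert (after - before).days in SPLIT_OFFSETS
        rng = Random(1)
        outcomes = {shift_date_split(*triple, rng) for _ in range(800)}
        assert target in outcomes

    def test_bounds_and_validity(self):
        rng = Random(5)
        before = date(2014, 1, 10)
        for _ in range(2000):
            d, m, y = shift_date_split("10", "01", "2014", rng)
            after = date(int(y), int(m), int(d))
            assert 2 <= abs((after - before).days) <= 10

    def test_zero_padding_width_preserved_per_column(self):
        rng = Random(3)
        d, m, y = shift_date_split("05", "03", "2019", rng)
        assert len(d) == 2 and len(m) == 2 and len(y) == 4
        # unpadded input keeps its own width where the value allows
        d2, _, _ = shift_date_split("15", "6", "2019", rng)
        assert len(d2) == 2

    @given(
        day=st.integers(1, 28), month=st.integers(1, 12), year=st.integers(1900, 2099),
        seed=st.integers(0, 2**16),
    )
    def test_output_reparses_and_offset_admissible(self, day, month, year, seed):
        rng = Random(seed)
        d, m, y = shift_date_split(f"{day:02d}", f"{month:02d}", str(year), rng)
        after = date(int(y), int(m), int(d))
        assert (after - date(year, month, day)).days in SPLIT_OFFSETS

    @pytest.mark.parametrize("triple", [("", "", ""), ("31", "02", "2019"), ("x", "01", "2020")])
    def test_invalid_triples_raise_typed_error(self, triple):
        with pytest.raises(DateParseError):
            shift_date_split(*triple, Random(0))


def small_dictionary():
    return DataDictionary(
        entries=[
            FieldEntry("T", "pid", "", Measure.PSEUDONYMIZATION),
            FieldEntry("T", "name", "", Measure.DELETION),
            FieldEntry("T", "diag", "", Measure.DATE_RANDOMIZATION),
            FieldEntry("T", "code", "", Measure.NO_ACTION),
            FieldEntry("T", "bd", "", Measure.DATE_RANDOMIZATION, "b", "day"),
            FieldEntry("T", "bm", "", Measure.DATE_RANDOMIZATION, "b", "month"),
            FieldEntry("T", "by", "", Measure.DATE_RANDOMIZATION, "b", "year"),
        ]
    )


def small_table():
    return RelationalTable.from_rows(
        "T",
        ["pid", "name", "diag", "code", "bd", "bm", "by"],
        [
            ["p1", "Meier", "01.04.2021", "C50.4", "25", "04", "2018"],
            ["p2", "Vogel", "", "C34.9", "", "", ""],
            ["p3", "Lang", "27.12.2015", "C50.8", "19", "08", "2020"],
        ],
    )


class TestApplyMeasures:
    def test_all_no_action_is_identity(self, test_secrets):
        t = small_table()
        d = DataDictionary(
            entries=[FieldEntry("T", c) for c in t.columns]
        )
        out, audit = apply_measures(t, d, test_secrets)
        assert out.data.values.tolist() == t.data.values.tolist()
        assert audit.total_shifts() == 0

    def test_exactly_marked_columns_differ(self, test_secrets):
        t = small_table()
        out, _ = apply_measures(t, small_dictionary(), test_secrets)
        changed = {
            c
            for c in t.columns
            if out.column_values(c) != t.column_values(c)
        }
        # 'code' untouched; all changed columns carry a measure (a date part
        # may keep its value when the shift stays inside the month)
        assert "code" not in changed
        assert {"pid", "name", "diag"} <= changed
        assert changed <= {"pid", "name", "diag", "bd", "bm", "by"}

    def test_empty_cells_pass_through_every_measure(self, test_secrets):
        t = small_table()
        out, _ = apply_measures(t, small_dictionary(), test_secrets)
        row = out.data.iloc[1]
        assert row["diag"] == "" and row["bd"] == "" and row["bm"] == "" and row["by"] == ""

    def test_split_triples_processed_atomically(self, test_secrets):
        t = small_table()
        out, audit = apply_measures(t, small_dictionary(), test_secrets)
        for i in (0, 2):
            before = date(
                int(t.data["by"].iloc[i]),
                int(t.data["bm"].iloc[i]),
                int(t.data["bd"].iloc[i]),
            )
            after = date(
                int(out.data["by"].iloc[i]),
                int(out.data["bm"].iloc[i]),
                int(out.data["bd"].iloc[i]),
            )
            assert 2 <= abs((after - before).days) <= 10
        assert sum(audit.shifts[("T", "b")].values()) == 2

    def test_malformed_date_blanked_and_audited(self, test_secrets):
        t = RelationalTable.from_rows("T", ["diag"], [["00.13.2020"], ["01.04.2021"]])
        d = DataDictionary(entries=[FieldEntry("T", "diag", "", Measure.DATE_RANDOMIZATION)])
        out, audit = apply_measures(t, d, test_secrets, bad_date_policy="blank")
        assert out.data["diag"].iloc[0] == ""
        assert audit.unparsable == {("T", "diag"): 1}

    def test_error_policy_names_field_but_not_value(self, test_secrets):
        t = RelationalTable.from_rows("T", ["diag"], [["SECRET-99.99"]])
        d = DataDictionary(entries=[FieldEntry("T", "diag", "", Measure.DATE_RANDOMIZATION)])
        with pytest.raises(DateParseError) as err:
            apply_measures(t, d, test_secrets, bad_date_policy="error")
        assert "diag" in str(err.value) and "SECRET" not in str(err.value)

    def test_row_count_and_columns_never_change(self, test_secrets):
        t = small_table()
        out, _ = apply_measures(t, small_dictionary(), test_secrets)
        assert out.n_rows == t.n_rows and out.columns == t.columns

    def test_bit_reproducible_with_fixed_seed_and_salt(self):
        t = small_table()
        d = small_dictionary()
        a, _ = apply_measures(t, d, RunSecrets.for_testing(9, ZERO_SALT))
        b, _ = apply_measures(t, d, RunSecrets.for_testing(9, ZERO_SALT))
        assert a.data.values.tolist() == b.data.values.tolist()

    def test_audit_contains_no_values_or_row_indices(self, test_secrets):
        t = small_table()
        _, audit = apply_measures(t, small_dictionary(), test_secrets)
        flat = str(audit.to_dict())
        for leaked in ("p1", "Meier", "01.04.2021", "2018"):
            assert leaked not in flat
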