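import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipogpcr.qpcr import (
    CLASSES,
    CT_SENTINEL,
    ClassificationScheme,
    QpcrError,
    classify_expression,
    condition_contrast,
    ct_class_boundaries,
    housekeeping_reference,
    profile_condition,
    read_ct_table,
    relative_expression,
    summarize_categories,
)
from conftest import HK_MOUSE, make_ct_matrix


class TestReadCtTable:
    def write(self, tmp_path, rows):
        path = tmp_path / "ct.csv"
        path.write_text("sample,gene,Ct\n" + "\n".join(rows) + "\n")
        return path

    def test_toy_long_table(self, tmp_path, toy_manifest):
        rows = [f"s{i},Fzd4,{20 + i}" for i in range(1, 4)]
        rows += [f"s{i},{hk},20" for i in range(1, 4) for hk in HK_MOUSE]
        ct = read_ct_table(self.write(tmp_path, rows), toy_manifest)
        assert ct.values.loc["Fzd4", "s2"] == 22.0
        assert list(ct.values.columns) == ["s1", "s2", "s3"]

    def test_undetermined_becomes_sentinel(self, tmp_path, toy_manifest):
        rows = ["s1,Fzd4,Undetermined"]
        rows += [f"s1,{hk},20" for hk in HK_MOUSE]
        ct = read_ct_table(self.write(tmp_path, rows), toy_manifest)
        assert ct.values.loc["Fzd4", "s1"] == CT_SENTINEL
        assert bool(ct.undetermined.loc["Fzd4", "s1"])

    def test_unassayed_manifest_gene_is_undetermined(self, tmp_path, toy_manifest):
        rows = ["s1,Fzd4,25"] + [f"s1,{hk},20" for hk in HK_MOUSE]
        ct = read_ct_table(self.write(tmp_path, rows), toy_manifest)
        assert bool(ct.undetermined.loc["Adora1", "s1"])

    @pytest.mark.parametrize("bad_ct", ["45", "0", "-3"])
    def test_out_of_range_ct_rejected(self, tmp_path, toy_manifest, bad_ct):
        with pytest.raises(QpcrError, match="row"):
            read_ct_table(
                self.write(tmp_path, [f"s1,Fzd4,{bad_ct}"]), toy_manifest
            )

    def test_duplicate_well_rejected(self, tmp_path, toy_manifest):
        with pytest.raises(QpcrError, match="duplicate"):
            read_ct_table(
                self.write(tmp_path, ["s1,Fzd4,20", "s1,Fzd4,21"]), toy_manifest
            )


class TestHousekeepingReference:
    def test_constant_input(self):
        ct = make_ct_matrix({"Fzd4": 25.0}, hk_ct=20.0)
        ref = housekeeping_reference(ct, HK_MOUSE)
        assert ref.reference_ct.iloc[0] == pytest.approx(20.0)
        assert int(ref.n_used.iloc[0]) == 15

    def test_hand_computed_mean(self):
        """Reference is the arithmetic mean: {19, 21, 13 x 20} -> 20."""
        ct = make_ct_matrix({"Fzd4": 25.0}, hk_ct=20.0)
        ct.values.loc["Actb"] = 19.0
        ct.values.loc["B2m"] = 21.0
        ref = housekeeping_reference(ct, HK_MOUSE)
        assert ref.reference_ct.iloc[0] == pytest.approx(20.0)

    def test_sample_rejected_below_minimum_detected(self):
        ct = make_ct_matrix({"Fzd4": 25.0}, hk_ct=20.0,
                            undetermined=set(HK_MOUSE[:8]))
        with pytest.raises(QpcrError, match="housekeeping"):
            housekeeping_reference(ct, HK_MOUSE)

    def test_undetected_housekeeping_excluded_from_mean(self):
        ct = make_ct_matrix({"Fzd4": 25.0}, hk_ct=20.0,
                            undetermined={"Actb"})
        ct.values.loc["Actb"] = 40.0
        ref = housekeeping_reference(ct, HK_MOUSE)
        assert ref.reference_ct.iloc[0] == pytest.approx(20.0)
        assert int(ref.n_used.iloc[0]) == 14


class TestRelativeExpression:
    def test_identity_case(self):
        assert relative_expression(20.0, 20.0) == pytest.approx(100.0)

    def test_nine_cycles_below_reference(self):
        assert relative_expression(29.0, 20.0) == pytest.approx(
            100.0 * 2 ** -9
        )

    def test_trace_boundary_ct(self):
        """Ct solving 2**-dCt = 1e-4 sits at the 0.01 % boundary."""
        ct = 20.0 + math.log2(1e4)
        assert relative_expression(ct, 20.0) == pytest.approx(0.01, rel=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        ct=st.floats(1.0, 40.0),
        ref=st.floats(10.0, 30.0),
        shift=st.floats(-5.0, 5.0),
    )
    def test_first_principles_oracle_and_shift_invariance(self, ct, ref, shift):
        r = relative_expression(ct, ref)
        oracle = 100.0 * 2.0 ** (-(ct - ref))
        assert r == pytest.approx(oracle, rel=1e-12)
        assert relative_expression(ct + shift, ref + shift) == pytest.approx(
            r, rel=1e-12
        )

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.floats(1.0, 40.0), min_size=2, max_size=10))
    def test_strictly_decreasing_in_ct(self, cts):
        r = [relative_expression(c, 20.0) for c in sorted(cts)]
        assert all(a >= b for a, b in zip(r, r[1:]))


class TestClassification:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.1953, "Expressed"),
            (0.1, "Expressed"),   # boundary joins the higher class
            (0.05, "Trace"),
            (0.01, "Trace"),      # boundary joins the higher class
            (0.0099, "Absent"),
        ],
    )
    def test_strata(self, r, expected):
        assert classify_expression(r) == expected

    def test_negative_r_rejected(self):
        with pytest.raises(QpcrError):
            classify_expression(-0.1)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(QpcrError):
            ClassificationScheme(expressed_threshold=0.01, trace_threshold=0.1)

    def test_ct_boundaries_near_30_and_33_for_reference_20(self):
        ct_e, ct_t = ct_class_boundaries(20.0)
        assert round(ct_e) == 30
        assert round(ct_t) == 33

    @settings(derandomize=True, deadline=None)
    @given(st.floats(1.0, 40.0), st.floats(-3.0, 3.0))
    def test_class_monotone_in_ct(self, ct, shift):
        """As Ct rises past a boundary the class only moves down-stratum."""
        order = {c: i for i, c in enumerate(CLASSES)}
        lo = classify_expression(relative_expression(ct, 20.0))
        hi = classify_expression(
            relative_expression(min(ct + abs(shift), 40.0), 20.0)
        )
        assert order[hi] >= order[lo]


class TestProfileCondition:
    def test_replicates_averaged_then_classified(self):
        """r = {0.15, 0.05} averages to 0.10, inside Expressed (inclusive)."""
        ct = make_ct_matrix({"Fzd4": 25.0}, conditions=("A",), n_replicates=2)
        dct = [-math.log2(0.0015), -math.log2(0.0005)]
        ct.values.loc["Fzd4"] = [20.0 + dct[0], 20.0 + dct[1]]
        prof = profile_condition(ct, "A", HK_MOUSE)
        assert prof.r_of("Fzd4") == pytest.approx(0.10, rel=1e-12)
        assert prof.class_of("Fzd4") == "Expressed"

    def test_all_replicates_undetermined_forces_absent(self):
        ct = make_ct_matrix({"Fzd4": 40.0}, undetermined={"Fzd4"},
                            n_replicates=2)
        prof = profile_condition(ct, "A", HK_MOUSE)
        assert prof.class_of("Fzd4") == "Absent"

    def test_single_replicate_passthrough(self):
        ct = make_ct_matrix({"Fzd4": 29.0})
        prof = profile_condition(ct, "A", HK_MOUSE)
        assert prof.r_of("Fzd4") == pytest.approx(100 * 2 ** -9)

    def test_unknown_condition_rejected(self):
        ct = make_ct_matrix({"Fzd4": 29.0})
        with pytest.raises(QpcrError, match="condition"):
            profile_condition(ct, "missing", HK_MOUSE)


class TestSummarizeCategories:
    def test_toy_counts_sum_to_panel_size(self, toy_manifest):
        ct = make_ct_matrix(
            {"Adora1": 25.0, "Ffar3": 26.0, "Fzd4": 31.0, "Gprc5b": 39.0,
             "Lpar1": 38.0}
        )
        prof = profile_condition(ct, "A", HK_MOUSE)
        counts = summarize_categories(prof, toy_manifest)
        assert counts == {"Expressed": 2, "Trace": 1, "Absent": 2}
        assert sum(counts.values()) == toy_manifest.panel_size

    def test_never_assayed_panel_genes_counted_absent(self, toy_manifest):
        ct = make_ct_matrix({"Adora1": 25.0})
        prof = profile_condition(ct, "A", HK_MOUSE)
        counts = summarize_categories(prof, toy_manifest)
        assert counts["Expressed"] == 1
        assert counts["Absent"] == 4
        assert sum(counts.values()) == 5


class TestConditionContrast:
    def test_one_cycle_shift_gives_unit_logfc(self):
        ct = make_ct_matrix({"Fzd4": 25.0, "Adora1": 27.0},
                            conditions=("d0", "d7"), n_replicates=3)
        d7 = ct.samples_for("d7")
        ct.values.loc["Fzd4", d7] = 24.0  # one cycle lower -> doubled
        ct.values.loc["Fzd4", d7[0]] += 0.01  # break zero variance
        ct.values.loc["Adora1", d7[0]] += 0.01
        out = condition_contrast(ct, "d7", "d0", HK_MOUSE).set_index("gene")
        assert out.loc["Fzd4", "log2_fc"] == pytest.approx(1.0, abs=0.01)
        assert out.loc["Adora1", "log2_fc"] == pytest.approx(0.0, abs=0.01)

    def test_degenerate_variance_flagged_not_dropped(self):
        ct = make_ct_matrix({"Fzd4": 25.0}, conditions=("d0", "d7"),
                            n_replicates=2)
        ct.values.loc["Fzd4", ct.samples_for("d7")] = 23.0
        out = condition_contrast(ct, "d7", "d0", HK_MOUSE).set_index("gene")
        assert bool(out.loc["Fzd4", "degenerate"])
        assert out.loc["Fzd4", "log2_fc"] == pytest.approx(2.0)

    def test_requires_two_replicates(self):
        ct = make_ct_matrix({"Fzd4": 25.0}, conditions=("d0", "d7"),
                            n_replicates=1)
        with pytest.raises(QpcrError, match="replicates"):
            condition_contrast(ct, "d7", "d0", HK_MOUSE)
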