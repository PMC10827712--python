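"""Quantile filtering, Dunn's test, Fisher exact and t comparisons."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from contourqc import (
    CohortRecord,
    annotator_summary,
    dunn_test,
    fisher_exact,
    quantile_split,
    read_cohort_csv,
    two_sample_t,
    write_cohort_csv,
)

from oracles import exact_fisher_two_sided


def make_records(values, key="roughness"):
    records = []
    for i, v in enumerate(values):
        kwargs = {"roughness": 0.1, "length_cm": 20.0}
        kwargs[key] = float(v)
        records.append(CohortRecord(case_id=f"c{i:03d}", annotator="A", **kwargs))
    return records


class TestQuantileSplit:
    def test_248_records_give_62_62_124(self, rng):
        records = make_records(rng.normal(0.1, 0.02, 248).clip(0.001))
        q1 = quantile_split(records, mode="Q1")
        q4 = quantile_split(records, mode="Q4")
        mid = quantile_split(records, mode="middle50")
        assert len(q1) == 62 and len(q4) == 62 and len(mid) == 124

    def test_three_branches_partition_the_input(self, rng):
        records = make_records(rng.normal(0.1, 0.02, 101).clip(0.001))
        q1 = quantile_split(records, mode="Q1")
        q4 = quantile_split(records, mode="Q4")
        mid = quantile_split(records, mode="middle50")
        ids = [r.case_id for r in q1 + q4 + mid]
        assert sorted(ids) == sorted(r.case_id for r in records)
        assert len(set(ids)) == len(records)

    def test_four_distinct_records(self):
        records = make_records([0.4, 0.2, 0.3, 0.1])
        assert [r.roughness for r in quantile_split(records, mode="Q1")] == [0.1]
        assert [r.roughness for r in quantile_split(records, mode="Q4")] == [0.4]

    def test_boundary_ties_fall_on_one_side(self):
        # ten records with heavy ties at the quartile boundaries
        values = [0.1, 0.1, 0.1, 0.2, 0.2, 0.2, 0.2, 0.3, 0.3, 0.3]
        records = make_records(values)
        q1 = quantile_split(records, mode="Q1")
        q4 = quantile_split(records, mode="Q4")
        mid = quantile_split(records, mode="middle50")
        # brute-force: all records sharing a value land in the same branch
        branch = {}
        for name, part in (("Q1", q1), ("Q4", q4), ("mid", mid)):
            for r in part:
                branch[r.case_id] = name
        by_value = {}
        for r in records:
            by_value.setdefault(r.roughness, set()).add(branch[r.case_id])
        assert all(len(branches) == 1 for branches in by_value.values())
        assert len(q1) + len(q4) + len(mid) == 10

    def test_length_key_and_errors(self):
        records = make_records([10, 12, 20, 22], key="length_cm")
        assert [r.length_cm for r in quantile_split(records, key="length_cm", mode="Q1")] == [10.0]
        with pytest.raises(ValueError, match="non-empty"):
            quantile_split([], mode="Q1")
        with pytest.raises(ValueError, match="key"):
            quantile_split(records, key="dice")
        with pytest.raises(ValueError, match="mode"):
            quantile_split(records, mode="Q2")


class TestDunnTest:
    def test_identical_groups_give_zero_z_unit_p(self):
        res = dunn_test([("a", [1.0, 2.0, 3.0]), ("b", [1.0, 2.0, 3.0])])
        assert res.z_matrix[0, 1] == 0.0
        assert res.p_matrix[0, 1] == 1.0

    def test_matches_hand_computed_ranks(self):
        """Groups {1,2,3}, {4,5,6}, {7,8,9}: mean ranks 2, 5, 8, no ties,
        pooled variance N(N+1)/12 = 7.5, SE = sqrt(7.5 * 2/3) = sqrt(5)."""
        res = dunn_test([("g1", [1, 2, 3]), ("g2", [4, 5, 6]), ("g3", [7, 8, 9])])
        se = np.sqrt(5.0)
        for (i, j), dr in {(0, 1): -3.0, (0, 2): -6.0, (1, 2): -3.0}.items():
            z = dr / se
            assert res.z_matrix[i, j] == pytest.approx(z, abs=1e-12)
            assert res.p_matrix[i, j] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_large_location_shift_is_significant(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        c = rng.normal(6, 1, 50)
        res = dunn_test([("a", a), ("b", b), ("c", c)])
        off_diag = res.p_matrix[np.triu_indices(3, k=1)]
        assert (off_diag < 0.01).all()
        assert res.kruskal_p < 0.01

    def test_invariant_to_monotone_transform(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        r1 = dunn_test([("a", a), ("b", b)])
        r2 = dunn_test([("a", np.exp(a)), ("b", np.exp(b))])
        assert r1.z_matrix[0, 1] == pytest.approx(r2.z_matrix[0, 1], abs=1e-12)

    def test_group_order_permutes_matrices(self, rng):
        a, b, c = rng.normal(0, 1, 8), rng.normal(1, 1, 9), rng.normal(2, 1, 10)
        r1 = dunn_test([("a", a), ("b", b), ("c", c)])
        r2 = dunn_test([("c", c), ("a", a), ("b", b)])
        assert r1.p_matrix[0, 1] == pytest.approx(r2.p_matrix[1, 2], abs=1e-15)
        assert r1.z_matrix[0, 2] == pytest.approx(-r2.z_matrix[0, 1], abs=1e-15)

    def test_holm_adjustment_is_monotone_and_larger(self, rng):
        a, b, c = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10), rng.normal(3, 1, 10)
        raw = dunn_test([("a", a), ("b", b), ("c", c)])
        adj = dunn_test([("a", a), ("b", b), ("c", c)], holm=True)
        iu = np.triu_indices(3, k=1)
        assert (adj.p_matrix[iu] >= raw.p_matrix[iu] - 1e-15).all()
        assert adj.adjusted and not raw.adjusted

    def test_mid_ranks_used_for_ties(self):
        # pooled data {1,1,2,2}: mid-ranks 1.5,1.5,3.5,3.5; tie term T=12
        res = dunn_test([("a", [1.0, 2.0]), ("b", [1.0, 2.0])])
        assert res.z_matrix[0, 1] == 0.0

    def test_degenerate_inputs_are_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            dunn_test([("a", [1, 2, 3])])
        with pytest.raises(ValueError, match="2 observations"):
            dunn_test([("a", [1.0]), ("b", [1, 2])])
        with pytest.raises(ValueError, match="identical"):
            dunn_test([("a", [5.0, 5.0]), ("b", [5.0, 5.0])])


class TestFisherExact:
    def test_balanced_table_gives_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        table = [[10, 0], [0, 10]]
        assert fisher_exact(table) == pytest.approx(exact_fisher_two_sided(table), abs=1e-12)
        # only the two extreme tables are as improbable: p = 2 / C(20, 10)
        from math import comb

        assert fisher_exact(table) == pytest.approx(2 / comb(20, 10), abs=1e-15)

    def test_skewed_table_matches_enumeration(self):
        table = [[1, 9], [9, 1]]
        assert fisher_exact(table) == pytest.approx(exact_fisher_two_sided(table), abs=1e-12)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(exact_fisher_two_sided(t), abs=1e-12)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])


class TestTwoSampleT:
    def test_identical_samples_give_zero_t_unit_p(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pooled_variant_matches_hand_arithmetic(self):
        # means 2 and 3, pooled sd 1: t = -1 / sqrt(2/3) = -sqrt(3/2)
        t, p = two_sample_t([1, 2, 3], [2, 3, 4], equal_var=True)
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(1.5), df=4), abs=1e-12)

    def test_separated_normals_are_significant(self, rng):
        t, p = two_sample_t(rng.normal(0, 1, 100), rng.normal(2, 1, 100))
        assert p < 0.001

    def test_welch_is_default(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 5, 40)
        t, p = two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(ref.statistic)) and p == pytest.approx(float(ref.pvalue))

    def test_degenerate_inputs_are_errors(self):
        with pytest.raises(ValueError, match="2 observations"):
            two_sample_t([1.0], [1, 2])
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t([2.0, 2.0], [3.0, 3.0])


class TestCohortIO:
    def test_csv_round_trip(self, tmp_path):
        records = [
            CohortRecord("c1", "A", 20.0, 0.09, dice=0.8),
            CohortRecord("c2", "B", 12.5, 0.11, dice=None),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        back = read_cohort_csv(path)
        assert [r.case_id for r in back] == ["c1", "c2"]
        assert back[0].dice == pytest.approx(0.8) and back[1].dice is None

    def test_summary_reports_mean_sd_per_annotator(self):
        records = [
            CohortRecord("c1", "A", 20.0, 0.10),
            CohortRecord("c2", "A", 22.0, 0.12),
            CohortRecord("c3", "B", 12.0, 0.80),
        ]
        summary = annotator_summary(records).set_index("annotator")
        assert summary.loc["A", "n"] == 2
        assert summary.loc["A", "roughness_mean"] == pytest.approx(0.11)
        assert summary.loc["A", "length_sd_cm"] == pytest.approx(np.sqrt(2.0))
        assert summary.loc["B", "roughness_mean"] == pytest.approx(0.80)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="length_cm"):
            CohortRecord("c", "A", 0.0, 0.1)
        with pytest.raises(ValueError, match="roughness"):
            CohortRecord("c", "A", 10.0, -0.1)
        with pytest.raises(ValueError, match="dice"):
            CohortRecord("c", "A", 10.0, 0.1, dice=1.5)
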