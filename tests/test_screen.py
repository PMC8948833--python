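import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from medimatch import (
    ContingencyTable,
    DetectionMatrix,
    ValidationError,
    aggregate_overlap_metrics,
    bonferroni_threshold,
    build_table,
    fisher_exact_2x2,
    load_reference_hits,
    mutual_best_hits,
    screen_all_pairs,
)
from medimatch.screen import AssociationResult

from oracles import brute_force_mutual_best, fisher_two_sided_exact

import pandas as pd

tables_st = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
)


def _sig2(x):
    return float(f"{x:.1e}")


class TestBuildTable:
    def test_cross_classification(self):
        t = build_table({"a", "b"}, {"b", "c"}, {"a", "b", "c", "d"})
        assert (t.both, t.self_only, t.blood_only, t.neither) == (1, 1, 1, 1)

    def test_disjoint_sets(self):
        t = build_table({"a"}, {"b"}, {"a", "b", "c"})
        assert t.both == 0

    def test_margins_match_published_metformin_row(self):
        t = ContingencyTable(203, 17, 643, 1944)
        assert (t.n_self, t.n_blood, t.n) == (220, 846, 2807)

    def test_outside_cohort_rejected(self):
        with pytest.raises(ValidationError):
            build_table({"z"}, set(), {"a"})


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,published",
        [
            ((203, 17, 643, 1944), 8.7e-92),
            ((2, 0, 1, 2804), 7.6e-7),
        ],
    )
    def test_published_pairs_reproduced(self, table, published):
        p, degenerate = fisher_exact_2x2(ContingencyTable(*table))
        assert not degenerate
        assert _sig2(p) == published

    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2(ContingencyTable(1, 1, 1, 1)) == (1.0, False)

    def test_zero_margin_degenerate(self):
        p, degenerate = fisher_exact_2x2(ContingencyTable(0, 0, 5, 10))
        assert (p, degenerate) == (1.0, True)

    def test_small_table_equals_enumeration(self):
        p, _ = fisher_exact_2x2(ContingencyTable(3, 1, 2, 10))
        assert p == pytest.approx(fisher_two_sided_exact(3, 1, 2, 10), rel=1e-9)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(tables_st)
    def test_matches_exact_enumeration(self, cells):
        p, _ = fisher_exact_2x2(ContingencyTable(*cells))
        assert p == pytest.approx(fisher_two_sided_exact(*cells), rel=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(tables_st)
    def test_transpose_invariance(self, cells):
        a, b, c, d = cells
        p1, _ = fisher_exact_2x2(ContingencyTable(a, b, c, d))
        p2, _ = fisher_exact_2x2(ContingencyTable(a, c, b, d))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(80):
            cells = rng.integers(0, 60, size=4)
            t = ContingencyTable(*map(int, cells))
            p, degenerate = fisher_exact_2x2(t)
            if degenerate:
                continue
            ref = scipy_fisher([[t.both, t.self_only],
                                [t.blood_only, t.neither]])[1]
            assert p == pytest.approx(ref, rel=1e-7)

    def test_no_underflow_for_extreme_tables(self):
        p, _ = fisher_exact_2x2(ContingencyTable(80, 0, 0, 2727))
        assert 0.0 < p < 1e-100

    def test_enrichment_monotonicity(self):
        # shifting mass onto the diagonal at fixed margins makes an
        # already-enriched table more extreme
        p_lo, _ = fisher_exact_2x2(ContingencyTable(10, 5, 5, 80))
        p_hi, _ = fisher_exact_2x2(ContingencyTable(11, 4, 4, 81))
        assert p_hi < p_lo


class TestBonferroni:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0.05, 394, 119), 1.1e-6),
            ((0.05, 394, 40), 3.2e-6),
            ((0.05, 1, 1), 5.0e-2),
        ],
    )
    def test_thresholds(self, args, expected):
        assert _sig2(bonferroni_threshold(*args)) == expected

    def test_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0, 10)


def _grid_results(p_grid, both_grid=None):
    results = []
    n_rows, n_cols = len(p_grid), len(p_grid[0])
    if both_grid is None:
        both_grid = [[0] * n_cols for _ in range(n_rows)]
    for i in range(n_rows):
        for j in range(n_cols):
            results.append(
                AssociationResult(
                    medication_item=f"med{i:03d}",
                    metabolite_id=f"met{j:03d}",
                    table=ContingencyTable(both_grid[i][j], 1, 1, 1),
                    p_value=p_grid[i][j],
                )
            )
    return results


class TestMutualBestHits:
    def test_dominated_row_left_unmatched(self):
        # med0's best is met0 (1e-10); med1's best is also met0 (1e-8),
        # so med1 stays unmatched even though met1 is free
        results = _grid_results([[1e-10, 0.5], [1e-8, 0.9]])
        flagged = mutual_best_hits(results)
        assert [(r.medication_item, r.metabolite_id) for r in flagged] == [
            ("med000", "met000")
        ]

    def test_single_pair_flagged(self):
        results = _grid_results([[0.01]])
        assert len(mutual_best_hits(results)) == 1

    def test_tie_broken_by_larger_both_then_id(self):
        results = _grid_results(
            [[1e-5, 1e-5, 1e-5]], both_grid=[[1, 3, 3]]
        )
        flagged = mutual_best_hits(results)
        assert [(r.medication_item, r.metabolite_id) for r in flagged] == [
            ("med000", "met001")
        ]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.integers(1, 12), st.integers(1, 12), st.randoms(use_true_random=False)
    )
    def test_equals_brute_force_and_is_matching(self, n_rows, n_cols, rnd):
        p_grid = [
            [rnd.choice([1e-8, 1e-4, 0.05, 0.5, 1.0]) for _ in range(n_cols)]
            for _ in range(n_rows)
        ]
        results = _grid_results(p_grid)
        flagged = mutual_best_hits(results)
        got = {
            (int(r.medication_item[3:]), int(r.metabolite_id[3:]))
            for r in flagged
        }
        assert got == brute_force_mutual_best(p_grid)
        meds = [r.medication_item for r in flagged]
        mets = [r.metabolite_id for r in flagged]
        assert len(meds) == len(set(meds)) and len(mets) == len(set(mets))

    def test_invariant_under_grid_permutation(self):
        rng = np.random.default_rng(5)
        p_grid = rng.random((6, 7)).tolist()
        base = {
            (r.medication_item, r.metabolite_id)
            for r in mutual_best_hits(_grid_results(p_grid))
        }
        perm = rng.permutation(6)
        permuted = [p_grid[i] for i in perm]
        results = []
        for i in range(6):
            for j in range(7):
                results.append(
                    AssociationResult(
                        medication_item=f"med{perm[i]:03d}",
                        metabolite_id=f"met{j:03d}",
                        table=ContingencyTable(0, 1, 1, 1),
                        p_value=permuted[i][j],
                    )
                )
        assert {
            (r.medication_item, r.metabolite_id) for r in mutual_best_hits(results)
        } == base


class TestScreenAllPairs:
    @staticmethod
    def _det(frame):
        return DetectionMatrix(detected=frame)

    def test_full_grid_of_results(self):
        cohort = {f"P{i}" for i in range(10)}
        det = self._det(
            pd.DataFrame(
                {"m1": [True] * 5 + [False] * 5, "m2": [False] * 10},
                index=sorted(cohort),
            )
        )
        results = screen_all_pairs(
            {"drugA": {"P0"}, "drugB": {"P1"}}, det, cohort
        )
        assert len(results) == 4

    def test_empty_cohort_rejected(self):
        det = self._det(pd.DataFrame({"m1": []}, dtype=bool))
        with pytest.raises(ValidationError):
            screen_all_pairs({"d": set()}, det, set())

    def test_zero_margin_pairs_retained_with_p_one(self):
        cohort = {"P0", "P1"}
        det = self._det(
            pd.DataFrame({"m1": [False, False]}, index=["P0", "P1"])
        )
        (r,) = [
            r for r in screen_all_pairs({"d": {"P0"}}, det, cohort)
        ]
        assert r.p_value == 1.0 and r.degenerate


class TestAggregateMetrics:
    def test_published_pairs_reproduce_printed_means(self):
        m = aggregate_overlap_metrics(load_reference_hits())
        assert round(100 * m["detected_given_reported"], 1) == 79.4
        assert round(100 * m["reported_given_detected"], 1) == 29.5
        assert round(100 * m["self_only_frac"], 1) == 7.4
        assert round(100 * m["blood_only_frac"], 1) == 65.8

    def test_perfect_single_pair(self):
        hit = AssociationResult(
            "d", "m", ContingencyTable(1, 0, 0, 9), p_value=0.1
        )
        m = aggregate_overlap_metrics([hit])
        assert m["detected_given_reported"] == 1.0
        assert m["reported_given_detected"] == 1.0
        assert m["self_only_frac"] == 0.0
        assert m["blood_only_frac"] == 0.0

    def test_zero_margin_pair_excluded_from_affected_mean(self):
        hits = [
            AssociationResult("d1", "m1", ContingencyTable(1, 1, 0, 8), 0.5),
            AssociationResult("d2", "m2", ContingencyTable(0, 0, 2, 8), 1.0),
        ]
        m = aggregate_overlap_metrics(hits)
        assert m["detected_given_reported"] == 0.5  # second pair has N_self=0
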