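import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convloss import convergence as cv
from convloss.errors import InvalidArgumentError, NoSingleLossError

FN = cv.FocalNodes("FA", "A", "F")


def reps_from_triplets(triplets):
    return [{"FA": a, "A": b, "F": c} for a, b, c in triplets]


class TestScenarios:
    def test_unanimous_101(self):
        table = cv.classify_scenarios({"og": reps_from_triplets([(1, 0, 1)] * 500)}, FN)
        row = table.loc["og"]
        assert row["majority"] == (1, 0, 1)
        assert row["support"] == 1.0
        assert not row["tie"]

    def test_majority_counting(self):
        reps = reps_from_triplets([(1, 0, 0)] * 300 + [(1, 1, 0)] * 200)
        row = cv.classify_scenarios({"og": reps}, FN).loc["og"]
        assert row["majority"] == (1, 0, 0)
        assert np.isclose(row["support"], 0.6)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        reps = reps_from_triplets(rng.integers(0, 2, size=(50, 3)))
        table = cv.classify_scenarios({"og": reps}, FN)
        keys = ["".join(map(str, t)) for t in cv.TRIPLETS]
        assert np.isclose(table.loc["og", keys].sum(), 1.0)

    def test_tie_breaks_toward_more_presences(self):
        reps = reps_from_triplets([(1, 0, 0)] * 250 + [(1, 1, 0)] * 250)
        row = cv.classify_scenarios({"og": reps}, FN).loc["og"]
        assert row["majority"] == (1, 1, 0)
        assert row["tie"]

    def test_commonly_lost_selection(self):
        data = {f"L{i}": reps_from_triplets([(1, 0, 0)] * 10) for i in range(137)}
        data["keep"] = reps_from_triplets([(1, 1, 1)] * 10)
        data["never"] = reps_from_triplets([(0, 0, 0)] * 10)
        table = cv.classify_scenarios(data, FN)
        lost = cv.select_commonly_lost(table)
        assert len(lost) == 137 and "keep" not in lost and "never" not in lost

    def test_category_split(self):
        data = {"m1": reps_from_triplets([(1, 0, 0)] * 5),
                "n1": reps_from_triplets([(1, 0, 0)] * 5)}
        table = cv.classify_scenarios(data, FN)
        split = cv.select_commonly_lost(table, {"m1": "metabolic", "n1": "non-metabolic"})
        assert split == {"metabolic": {"m1"}, "non-metabolic": {"n1"}}


PATH5 = [("n0", "n1"), ("n1", "n2"), ("n2", "n3"), ("n3", "n4"), ("n4", "n5")]


def path_reps(seqs):
    return [{f"n{i}": s for i, s in enumerate(seq)} for seq in seqs]


class TestAssignLossBranch:
    def test_clean_single_loss(self):
        reps = path_reps([[1, 1, 1, 0, 0, 0]] * 10)
        branch, support, tie, nq = cv.assign_loss_branch(reps, PATH5)
        assert (branch, support, tie, nq) == (3, 1.0, False, 10)

    def test_gain_and_double_loss_excluded_from_voting(self):
        reps = path_reps([[1, 0, 1, 0, 0, 0]] * 5 + [[1, 1, 1, 0, 0, 0]] * 5)
        branch, support, _, nq = cv.assign_loss_branch(reps, PATH5)
        assert nq == 5 and branch == 3 and support == 1.0

    def test_plurality_vote(self):
        reps = path_reps([[1, 0, 0, 0, 0, 0]] * 6 + [[1, 1, 1, 0, 0, 0]] * 4)
        branch, support, _, _ = cv.assign_loss_branch(reps, PATH5)
        assert branch == 2 - 1 or branch == 1  # branch 1, support 0.6
        assert np.isclose(support, 0.6)

    def test_vote_tie_breaks_earlier_branch(self):
        reps = path_reps([[1, 0, 0, 0, 0, 0]] * 5 + [[1, 1, 1, 0, 0, 0]] * 5)
        branch, _, tie, _ = cv.assign_loss_branch(reps, PATH5)
        assert branch == 1 and tie

    def test_no_qualifying_replicate_raises(self):
        reps = path_reps([[0, 1, 0, 1, 0, 1]] * 4)
        with pytest.raises(NoSingleLossError):
            cv.assign_loss_branch(reps, PATH5)


class TestLossOrderSimilarity:
    def test_identical_distinct_ranks(self):
        r = {f"o{i}": i for i in range(5)}
        assert cv.loss_order_similarity(r, r) == 1.0

    def test_fully_reversed_ranks(self):
        ra = {f"o{i}": i for i in range(5)}
        rf = {f"o{i}": 5 - i for i in range(5)}
        assert cv.loss_order_similarity(ra, rf) == 0.0

    def test_tie_rule_hand_enumerated(self):
        # pairs (x,y): 0 vs -; (x,z): - vs -; (y,z): - vs 0  ->  S = 1/3
        ra = {"x": 1, "y": 1, "z": 2}
        rf = {"x": 1, "y": 2, "z": 2}
        assert np.isclose(cv.loss_order_similarity(ra, rf), 1 / 3)

    def test_exclude_ties_variant(self):
        ra = {"x": 1, "y": 1, "z": 2}
        rf = {"x": 1, "y": 2, "z": 2}
        # only (x,z) untied in both: concordant -> 1/1
        assert cv.loss_order_similarity(ra, rf, ties="exclude") == 1.0

    def test_too_few_ogs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cv.loss_order_similarity({"x": 1}, {"x": 1})

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        ra = {f"o{i}": int(rng.integers(1, 6)) for i in range(n)}
        rf = {f"o{i}": int(rng.integers(1, 8)) for i in range(n)}
        s = cv.loss_order_similarity(ra, rf)
        assert 0.0 <= s <= 1.0
        assert s == cv.loss_order_similarity(rf, ra)


class TestPermutationTest:
    def test_planted_identical_orders_significant(self):
        rng = np.random.default_rng(1)
        ranks = {f"o{i}": int(rng.integers(1, 7)) for i in range(20)}
        res = cv.permutation_pvalue(ranks, ranks, n_perm=10_000, seed=2)
        assert res.s_obs == 1.0
        assert res.p < 0.01

    def test_minimum_similarity_has_p_one(self):
        ra = {f"o{i}": i for i in range(8)}
        rf = {f"o{i}": 8 - i for i in range(8)}
        res = cv.permutation_pvalue(ra, rf, n_perm=500, seed=3)
        assert res.s_obs == 0.0
        assert res.p == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(4)
        ra = {f"o{i}": int(rng.integers(1, 7)) for i in range(15)}
        rf = {f"o{i}": int(rng.integers(1, 9)) for i in range(15)}
        r1 = cv.permutation_pvalue(ra, rf, n_perm=1000, seed=5)
        r2 = cv.permutation_pvalue(ra, rf, n_perm=1000, seed=5)
        assert r1.p == r2.p and r1.s_obs == r2.s_obs

    def test_null_calibration(self):
        # type-I error of the permutation p over random assignments
        rng = np.random.default_rng(42)
        hits = 0
        N = 1000
        for _ in range(N):
            ra = {f"o{j}": int(rng.integers(1, 7)) for j in range(20)}
            rf = {f"o{j}": int(rng.integers(1, 9)) for j in range(20)}
            res = cv.permutation_pvalue(ra, rf, n_perm=200, seed=int(rng.integers(2**31)))
            hits += res.p < 0.05
        assert 0.03 <= hits / N <= 0.07


class TestOverlapAndTiming:
    def test_independent_table(self):
        universe = {f"g{i}" for i in range(40)}
        lost_a = {f"g{i}" for i in range(20)}
        lost_f = {f"g{i}" for i in range(10, 30)}
        table, stat, p = cv.overlap_contingency(lost_a, lost_f, universe)
        assert table.tolist() == [[10, 10], [10, 10]]
        assert stat == 0.0 and p == 1.0

    def test_planted_overlap_significant(self):
        universe = {f"g{i}" for i in range(2000)}
        shared = {f"g{i}" for i in range(30)}
        lost_a = shared | {f"g{i}" for i in range(100, 120)}
        lost_f = shared | {f"g{i}" for i in range(200, 220)}
        _, _, p = cv.overlap_contingency(lost_a, lost_f, universe)
        assert p < 1e-10

    def test_jaccard_cells(self):
        aa = {"a": 1, "b": 1, "c": 1, "d": 2}
        ff = {"b": 1, "c": 1, "d": 1, "x": 2}
        res = cv.branch_jaccard(aa, {**ff, "a": 1}, 2, 2)
        # A1 = {a,b,c}, F1 = {a,b,c,d} -> 3/4
        assert np.isclose(res.matrix.loc[1, 1], 3 / 4)

    def test_jaccard_identical_and_disjoint(self):
        aa = {"a": 1, "b": 1}
        res = cv.branch_jaccard(aa, aa, 2, 2)
        assert res.matrix.loc[1, 1] == 1.0
        assert res.matrix.loc[2, 2] == 0.0 and res.empty_union.loc[2, 2]

    def test_category_timing_means_and_ranks(self):
        assign_a = {"g1": 1, "g2": 3, "g3": 5}
        assign_f = {"g1": 2, "g2": 2, "g3": 6}
        cats = {"g1": "C1", "g2": "C1", "g3": "C2"}
        t = cv.category_loss_timing(assign_a, assign_f, cats)
        assert np.isclose(t.loc["C1", "mean_timing_a"], 2.0)
        assert (t["rank_diff"] == 0).all()

    def test_swapped_categories_have_max_rank_diff(self):
        assign_a = {"g1": 1, "g2": 5, "g3": 3}
        assign_f = {"g1": 5, "g2": 1, "g3": 3}
        cats = {"g1": "C1", "g2": "C2", "g3": "C3"}
        t = cv.category_loss_timing(assign_a, assign_f, cats)
        assert t.loc["C1", "rank_diff"] == t["rank_diff"].max() == 2.0
        assert t.loc["C3", "rank_diff"] == 0.0
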