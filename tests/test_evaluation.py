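import numpy as np
import pytest

from condrec.decoding import ConditionSet
from condrec.evaluation import (
    EXACT,
    MAJOR,
    OFF_BY_ONE,
    bin_mae,
    end_to_end_correct,
    off_by_n_accuracy,
    reaction_level_category,
    relaxed_set_equal,
    strict_set_equal,
    topk_accuracy,
    win_rate,
)


def make_cs(agents=(0, 1), temp=5, rbins=(2, 7), abins=None):
    agents = frozenset(agents)
    if abins is None:
        abins = tuple((a, 3) for a in sorted(agents))
    return ConditionSet(
        agents=agents, temperature_bin=temp, reactant_bins=tuple(rbins), agent_bins=abins
    )


class TestRelaxedSetEqual:
    def test_water_disregarded(self):
        assert relaxed_set_equal({"[Pd]", "O=C([O-])[O-].[K+].[K+]", "O"},
                                 {"[Pd]", "O=C([O-])[O-].[K+].[K+]"})

    def test_distinct_agents_not_equal(self):
        assert not relaxed_set_equal({"[Pd]"}, {"[Ni]"})

    def test_identity(self):
        assert relaxed_set_equal({"CCO", "O"}, {"O", "CCO"})

    def test_symmetric_and_implied_by_strict(self):
        rng = np.random.default_rng(0)
        pool = ["CCO", "CO", "O", "[Pd]", "ClCCl"]
        for _ in range(50):
            a = set(rng.choice(pool, size=rng.integers(0, 4), replace=False))
            b = set(rng.choice(pool, size=rng.integers(0, 4), replace=False))
            assert relaxed_set_equal(a, b) == relaxed_set_equal(b, a)
            if strict_set_equal(a, b):
                assert relaxed_set_equal(a, b)


class TestTopKAccuracy:
    def test_rank_position_counts(self):
        preds = [[{"A"}, {"B"}, {"C"}]]
        truths = [{"C"}]
        assert topk_accuracy(preds, truths, 2) == 0.0
        assert topk_accuracy(preds, truths, 3) == 1.0

    def test_perfect_rank_one(self):
        preds = [[{"A"}], [{"B"}]]
        truths = [{"A"}, {"B"}]
        for k in (1, 2, 5):
            assert topk_accuracy(preds, truths, k) == 1.0

    def test_curve_matches_brute_force_count(self):
        rng = np.random.default_rng(1)
        ranks = rng.integers(1, 12, size=10)  # truth position per query
        preds = [[{("x", r)} if r == rank else {("y", r)} for r in range(1, 12)]
                 for rank in ranks]
        truths = [{("x", int(rank))} for rank in ranks]
        for k in range(1, 12):
            expected = float(np.mean(ranks <= k))
            assert topk_accuracy(preds, truths, k) == pytest.approx(expected)

    def test_nondecreasing_in_k(self):
        rng = np.random.default_rng(2)
        ranks = rng.integers(1, 8, size=30)
        preds = [[{r} for r in range(1, 8)] for _ in ranks]
        truths = [{int(r)} for r in ranks]
        accs = [topk_accuracy(preds, truths, k) for k in range(1, 8)]
        assert accs == sorted(accs)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            topk_accuracy([], [], 0)


class TestOffByNAndMae:
    def test_exact_predictions(self):
        assert off_by_n_accuracy([3, 5], [3, 5], 0) == 1.0
        assert bin_mae([3, 5], [3, 5]) == 0.0

    def test_single_pair_two_bins_apart(self):
        assert off_by_n_accuracy([12], [14], 1) == 0.0
        assert off_by_n_accuracy([12], [14], 2) == 1.0
        assert bin_mae([12], [14]) == 2.0

    def test_monotone_in_n_random_fixture(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 30, size=1000)
        true = rng.integers(0, 30, size=1000)
        accs = [off_by_n_accuracy(pred, true, n) for n in range(30)]
        assert accs == sorted(accs)
        assert accs[-1] == 1.0
        # brute-force comparator
        for n in (0, 1, 5):
            expected = sum(abs(int(p) - int(t)) <= n for p, t in zip(pred, true)) / 1000
            assert off_by_n_accuracy(pred, true, n) == pytest.approx(expected)
        assert bin_mae(pred, true) == pytest.approx(
            sum(abs(int(p) - int(t)) for p, t in zip(pred, true)) / 1000
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            off_by_n_accuracy([1], [1, 2], 1)


class TestReactionLevelCategories:
    @pytest.mark.parametrize(
        "pred, true, expected",
        [((3, 5), (3, 5), EXACT), ((3, 6), (3, 5), OFF_BY_ONE), ((3, 8), (3, 5), MAJOR)],
    )
    def test_defining_examples(self, pred, true, expected):
        assert reaction_level_category(pred, true) == expected

    def test_categories_partition_random_fixture(self):
        rng = np.random.default_rng(4)
        counts = {EXACT: 0, OFF_BY_ONE: 0, MAJOR: 0}
        n = 1000
        for _ in range(n):
            k = rng.integers(1, 4)
            pred = rng.integers(0, 15, size=k)
            true = rng.integers(0, 15, size=k)
            cat = reaction_level_category(pred, true)
            counts[cat] += 1
            devs = np.abs(pred - true)  # independent comparator
            if devs.max(initial=0) == 0:
                assert cat == EXACT
            elif devs.max() <= 1:
                assert cat == OFF_BY_ONE
            else:
                assert cat == MAJOR
        assert sum(counts.values()) == n

    def test_misaligned_components(self):
        with pytest.raises(ValueError):
            reaction_level_category((1, 2), (1,))


class TestEndToEndCorrect:
    def test_identical_condition_sets_all_true(self):
        cs = make_cs()
        v = end_to_end_correct(cs, cs)
        assert v.overall and v.agents and v.temperature and v.reactant_amounts and v.agent_amounts

    def test_reactant_bins_compared_as_multiset(self):
        v = end_to_end_correct(make_cs(rbins=(2, 5)), make_cs(rbins=(5, 2)))
        assert v.reactant_amounts

    def test_multiset_not_just_set(self):
        v = end_to_end_correct(make_cs(rbins=(2, 2, 5)), make_cs(rbins=(2, 5, 5)))
        assert not v.reactant_amounts

    def test_agent_bin_mismatch_fails_stage4_only(self):
        pred = make_cs(abins=((0, 3), (1, 4)))
        truth = make_cs(abins=((0, 3), (1, 5)))
        v = end_to_end_correct(pred, truth)
        assert v.agents and not v.agent_amounts and not v.overall

    def test_agrees_with_field_by_field_comparator(self):
        from collections import Counter

        rng = np.random.default_rng(5)
        for _ in range(1000):
            def rand_cs():
                agents = frozenset(int(a) for a in rng.choice(6, size=rng.integers(1, 4), replace=False))
                return ConditionSet(
                    agents=agents,
                    temperature_bin=int(rng.integers(0, 4)),
                    reactant_bins=tuple(int(b) for b in rng.integers(0, 3, size=2)),
                    agent_bins=tuple((a, int(rng.integers(0, 3))) for a in sorted(agents)),
                )

            pred, truth = rand_cs(), rand_cs()
            v = end_to_end_correct(pred, truth)
            assert v.agents == (pred.agents == truth.agents)
            assert v.temperature == (pred.temperature_bin == truth.temperature_bin)
            assert v.reactant_amounts == (
                Counter(pred.reactant_bins) == Counter(truth.reactant_bins)
            )
            assert v.agent_amounts == (
                pred.agents == truth.agents and dict(pred.agent_bins) == dict(truth.agent_bins)
            )
            assert v.overall == (
                v.agents and v.temperature and v.reactant_amounts and v.agent_amounts
            )


class TestWinRate:
    def _preds(self, correct, truth):
        return [truth] if correct else [make_cs(agents=(4, 5), temp=29)]

    def test_sweep_wins_give_wilson_lower_bound_above_half(self):
        truth = make_cs()
        truths = [truth] * 10
        a = [self._preds(True, truth) for _ in truths]
        b = [self._preds(False, truth) for _ in truths]
        res = win_rate(a, b, truths)[None]
        assert res.win_rate == 1.0
        assert res.ci_low == pytest.approx(0.722, abs=5e-3)
        assert res.ci_low > 0.5

    def test_all_ties_split_to_half(self):
        truth = make_cs()
        truths = [truth] * 8
        a = [self._preds(True, truth) for _ in truths]
        res = win_rate(a, a, truths)[None]
        assert res.win_rate == 0.5

    def test_neither_correct_excluded(self):
        truth = make_cs()
        a = [self._preds(False, truth)]
        assert win_rate(a, a, [truth]) == {}

    def test_tie_exclusion_mode(self):
        truth = make_cs()
        truths = [truth] * 4
        a = [self._preds(True, truth) for _ in truths]
        b = [self._preds(c, truth) for c in (True, True, False, False)]
        res = win_rate(a, b, truths, tie_mode="exclude")[None]
        assert res.n_counted == 2 and res.win_rate == 1.0

    def test_grouped_results(self):
        truth = make_cs()
        truths = [truth] * 4
        groups = ["g1", "g1", "g2", "g2"]
        a = [self._preds(c, truth) for c in (True, True, False, True)]
        b = [self._preds(c, truth) for c in (False, False, True, False)]
        res = win_rate(a, b, truths, groups=groups)
        assert res["g1"].win_rate == 1.0
        assert res["g2"].win_rate == 0.5

    def test_matches_brute_force_tally_random_fixture(self):
        rng = np.random.default_rng(6)
        truth = make_cs()
        flags = rng.random((1000, 2)) < 0.5
        a = [self._preds(bool(f[0]), truth) for f in flags]
        b = [self._preds(bool(f[1]), truth) for f in flags]
        res = win_rate(a, b, [truth] * 1000)[None]
        wins = sum(1.0 if fa and not fb else 0.5 if fa and fb else 0.0
                   for fa, fb in flags if fa or fb)
        counted = sum(1 for fa, fb in flags if fa or fb)
        assert res.n_counted == counted
        assert res.win_rate == pytest.approx(wins / counted)
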