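import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condrec.decoding import (
    AgentSetHypothesis,
    ConditionSet,
    ConfidenceWeights,
    StageOutputs,
    beam_search_agents,
    combine_conditions,
    confidence_score,
    fit_confidence_weights,
    top_m_joint_assignment,
)


def random_step_fn(n_agents: int, seed: int):
    """Stub stage-1 scorer: a fixed random map from partial sets to probs."""
    rng = np.random.default_rng(seed)
    w = rng.normal(size=(n_agents + 1, n_agents))
    b = rng.normal(size=n_agents + 1)

    def step(multihot):
        return 1.0 / (1.0 + np.exp(-(w @ multihot + b)))

    return step


def brute_force_merged_sets(step_fn, n_agents, max_len):
    """Sum joint probabilities over every ordered decode of each set."""
    totals: dict = {}

    def rec(chosen: tuple, prob: float):
        s = frozenset(chosen)
        mh = np.zeros(n_agents)
        mh[list(s)] = 1.0
        probs = step_fn(mh)
        totals[s] = totals.get(s, 0.0) + prob * float(probs[n_agents])
        if len(s) < max_len:
            for a in range(n_agents):
                if a not in s:
                    rec(chosen + (a,), prob * float(probs[a]))

    rec((), 1.0)
    return totals


class TestBeamSearch:
    @pytest.mark.parametrize("seed", range(5))
    def test_wide_beam_equals_exhaustive_enumeration(self, seed):
        n_agents, max_len = 3, 3
        step = random_step_fn(n_agents, seed)
        hyps = beam_search_agents(step, n_agents, width=60, max_len=max_len)
        oracle = brute_force_merged_sets(step, n_agents, max_len)
        assert {h.agents for h in hyps} == set(oracle)
        for h in hyps:
            assert h.probability == pytest.approx(oracle[h.agents], abs=1e-12)
        probs = [h.probability for h in hyps]
        assert probs == sorted(probs, reverse=True)

    def test_order_merging_sums_probabilities(self):
        # two agents whose selection probabilities depend on what was chosen
        table = {
            frozenset(): np.array([0.5, 0.2, 0.1]),
            frozenset({0}): np.array([0.0, 0.2, 0.3]),
            frozenset({1}): np.array([0.5, 0.0, 0.4]),
            frozenset({0, 1}): np.array([0.0, 0.0, 1.0]),
        }
        step = lambda mh: table[frozenset(np.flatnonzero(mh))]
        hyps = {h.agents: h.probability for h in beam_search_agents(step, 2, width=10, max_len=2)}
        # {0,1} via 0→1 (0.5*0.2) plus via 1→0 (0.2*0.5), then EOS prob 1
        assert hyps[frozenset({0, 1})] == pytest.approx(0.5 * 0.2 + 0.2 * 0.5)

    def test_immediate_eos_yields_empty_set_on_top(self):
        step = lambda mh: np.concatenate([np.full(4, 0.01), [1.0]])
        hyps = beam_search_agents(step, 4, width=5, max_len=3)
        assert hyps[0].agents == frozenset()

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            beam_search_agents(random_step_fn(3, 0), 3, width=0)

    def test_merged_probabilities_bounded_when_step_normalized(self):
        rng = np.random.default_rng(8)

        def normalized_step(mh):
            raw = rng.random(6)  # varies per call; normalization is what matters
            raw[np.flatnonzero(mh)] = 0.0
            return raw / raw.sum()

        # freeze per-set outputs so the step is a function of the set
        cache = {}

        def step(mh):
            key = frozenset(np.flatnonzero(mh))
            if key not in cache:
                cache[key] = normalized_step(mh)
            return cache[key]

        hyps = beam_search_agents(step, 5, width=200, max_len=5)
        assert sum(h.probability for h in hyps) <= 1.0 + 1e-9


class TestTopMJoint:
    def test_single_component(self):
        out = top_m_joint_assignment([np.array([0.7, 0.3])], m=2)
        assert out == [((0,), pytest.approx(0.7)), ((1,), pytest.approx(0.3))]

    def test_two_components_enumerated(self):
        dists = [np.array([0.6, 0.4]), np.array([0.6, 0.4])]
        out = top_m_joint_assignment(dists, m=2)
        assert out[0] == ((0, 0), pytest.approx(0.36))
        assert out[1][1] == pytest.approx(0.24)

    def test_m1_is_componentwise_argmax(self):
        rng = np.random.default_rng(3)
        dists = [rng.dirichlet(np.ones(5)) for _ in range(4)]
        out = top_m_joint_assignment(dists, m=1)
        assert out[0][0] == tuple(int(np.argmax(d)) for d in dists)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_vs_brute_force_m2_four_components(self, seed):
        rng = np.random.default_rng(seed)
        dists = [rng.dirichlet(np.ones(4)) for _ in range(4)]
        out = top_m_joint_assignment(dists, m=2)
        joints = sorted(
            (
                (bins, float(np.prod([d[b] for d, b in zip(dists, bins)])))
                for bins in itertools.product(range(4), repeat=4)
            ),
            key=lambda kv: (-kv[1], kv[0]),
        )
        for (bins, p), (obins, op) in zip(out, joints[:2]):
            assert bins == obins and p == pytest.approx(op, abs=1e-12)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            top_m_joint_assignment([np.array([])], m=1)

    def test_no_components_gives_empty_assignment(self):
        assert top_m_joint_assignment([], m=2) == [((), 1.0)]


class TestConfidenceScore:
    def test_equal_confidences(self):
        assert confidence_score((0.5, 0.5, 0.5, 0.5)) == pytest.approx(0.5)

    def test_degenerate_weights_pick_one_stage(self):
        w = ConfidenceWeights(1, 0, 0, 0)
        assert confidence_score((0.37, 0.9, 0.1, 0.5), w) == pytest.approx(0.37)

    def test_geometric_mean_value(self):
        c = (0.9, 0.8, 0.7, 0.6)
        assert confidence_score(c) == pytest.approx((0.9 * 0.8 * 0.7 * 0.6) ** 0.25)
        assert confidence_score(c) == pytest.approx(0.74156, abs=1e-4)

    def test_nonpositive_confidence_rejected(self):
        with pytest.raises(ValueError):
            confidence_score((0.5, 0.0, 0.5, 0.5))

    @given(
        st.floats(0.01, 1.0), st.floats(0.01, 1.0), st.floats(0.01, 1.0),
        st.floats(0.01, 0.99), st.floats(1.5, 4.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_scale_invariant(self, c1, c2, c3, c4, scale):
        base = confidence_score((c1, c2, c3, c4))
        higher = confidence_score((c1, c2, c3, min(1.0, c4 * 1.1)))
        assert higher >= base
        w = ConfidenceWeights(0.5, 1.0, 2.0, 0.25)
        ws = ConfidenceWeights(0.5 * scale, 1.0 * scale, 2.0 * scale, 0.25 * scale)
        assert confidence_score((c1, c2, c3, c4), w) == pytest.approx(
            confidence_score((c1, c2, c3, c4), ws)
        )

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            ConfidenceWeights(0, 0, 0, 0)


def make_stage_outputs(n_sets=10, n_temp=30, n_react=2, seed=0, n_agents_per_set=2):
    rng = np.random.default_rng(seed)
    outs = []
    for i in range(n_sets):
        agents = frozenset(range(i, i + n_agents_per_set))
        outs.append(
            StageOutputs(
                agent_hypothesis=AgentSetHypothesis(agents, float(rng.uniform(0.1, 1.0))),
                temperature_dist=rng.dirichlet(np.ones(n_temp)),
                reactant_dists=tuple(rng.dirichlet(np.ones(15)) for _ in range(n_react)),
                agent_dists=tuple((a, rng.dirichlet(np.ones(27))) for a in sorted(agents)),
            )
        )
    return outs


class TestCombineConditions:
    def test_full_beams_give_80_candidates(self):
        cands = combine_conditions(make_stage_outputs(10), counts=(10, 2, 2, 2))
        assert len(cands) == 80

    def test_counts_1111_give_single_candidate(self):
        assert len(combine_conditions(make_stage_outputs(10), counts=(1, 1, 1, 1))) == 1

    def test_fewer_agent_sets_shrink_output(self):
        cands = combine_conditions(make_stage_outputs(4), counts=(10, 2, 2, 2))
        assert len(cands) == 4 * 8

    def test_ranking_by_score_descending(self):
        cands = combine_conditions(make_stage_outputs(10))
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)

    def test_ranking_invariant_to_input_order(self):
        outs = make_stage_outputs(6, seed=4)
        a = combine_conditions(outs, counts=(6, 2, 2, 2))
        b = combine_conditions(outs[::-1], counts=(6, 2, 2, 2))
        assert a == b

    def test_candidate_agent_bins_cover_agent_set(self):
        for c in combine_conditions(make_stage_outputs(5, seed=2)):
            assert frozenset(i for i, _ in c.agent_bins) == c.agents


class TestFitConfidenceWeights:
    def test_single_point_grid(self):
        outs = [make_stage_outputs(2, seed=1)]
        truths = [
            ConditionSet(
                agents=frozenset({0, 1}), temperature_bin=0,
                reactant_bins=(0, 0), agent_bins=((0, 0), (1, 0)),
            )
        ]
        w = ConfidenceWeights(2, 1, 1, 1)
        assert fit_confidence_weights(outs, truths, [w]) == w

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_confidence_weights([], [], [])

    def test_stage1_dominant_validation_selects_high_w1(self):
        # construct: correct candidate is findable only when stage-1 confidence dominates
        rng = np.random.default_rng(7)
        outs_all, truths = [], []
        for q in range(6):
            outs = make_stage_outputs(3, seed=100 + q, n_react=1)
            # truth = the agent set of the *highest-c1* hypothesis, with its
            # argmax bins, so weighting c1 recovers it at rank 1
            best = max(outs, key=lambda o: o.agent_hypothesis.probability)
            truths.append(
                ConditionSet(
                    agents=best.agent_hypothesis.agents,
                    temperature_bin=int(np.argmax(best.temperature_dist)),
                    reactant_bins=(int(np.argmax(best.reactant_dists[0])),),
                    agent_bins=tuple(
                        (a, int(np.argmax(d))) for a, d in best.agent_dists
                    ),
                )
            )
            outs_all.append(outs)
        grid = [ConfidenceWeights(*w) for w in
                [(0.25, 2, 2, 2), (2, 0.25, 0.25, 0.25)]]
        best_w = fit_confidence_weights(outs_all, truths, grid, counts=(3, 1, 1, 1), top_k=1)
        assert best_w.w1 == 2

    def test_unique_optimum_independent_of_grid_order(self):
        outs_all, truths = [], []
        for q in range(6):
            outs = make_stage_outputs(3, seed=100 + q, n_react=1)
            best = max(outs, key=lambda o: o.agent_hypothesis.probability)
            truths.append(
                ConditionSet(
                    agents=best.agent_hypothesis.agents,
                    temperature_bin=int(np.argmax(best.temperature_dist)),
                    reactant_bins=(int(np.argmax(best.reactant_dists[0])),),
                    agent_bins=tuple((a, int(np.argmax(d))) for a, d in best.agent_dists),
                )
            )
            outs_all.append(outs)
        grid = [ConfidenceWeights(*w) for w in [(0.25, 2, 2, 2), (2, 0.25, 0.25, 0.25)]]
        w1 = fit_confidence_weights(outs_all, truths, grid, counts=(3, 1, 1, 1), top_k=1)
        w2 = fit_confidence_weights(outs_all, truths, grid[::-1], counts=(3, 1, 1, 1), top_k=1)
        assert w1 == w2


class TestConditionSetContract:
    def test_agent_bins_must_cover_agents(self):
        with pytest.raises(ValueError):
            ConditionSet(
                agents=frozenset({0, 1}), temperature_bin=0,
                reactant_bins=(0,), agent_bins=((0, 3),),
            )
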