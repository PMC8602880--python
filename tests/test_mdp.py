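import json
import math

import numpy as np
import pytest

from mazetalk.categorical import Categorical, ConditionalTable, DegenerateInputError
from mazetalk.mdp import (
    Factor,
    GenerativeProcess,
    InferenceResult,
    LikelihoodModel,
    MDPModel,
    Modality,
    Policy,
    Preferences,
    StateSpace,
    TransitionModel,
    environment_step,
    expected_free_energy,
    infer_states,
    model_from_dict,
    model_to_dict,
    policy_posterior,
    reflexive_outcome,
    select_action,
)
from mazetalk.tmaze import CONTEXTS, EXTERO, LOCATIONS, REWARDS, SYNTAX, TOKENS, TaskConfig, build_model
from mazetalk.hierarchy import descend
from _oracles import enumerate_state_posterior, random_single_factor_model


def single_factor_model(a, b, n_o=None):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return MDPModel(
        space=StateSpace((Factor("s", tuple(f"s{i}" for i in range(a.shape[1]))),)),
        likelihood=LikelihoodModel(
            (Modality("o", tuple(f"o{i}" for i in range(a.shape[0])), ConditionalTable(a)),)
        ),
        transitions=TransitionModel({"s": b[None]}),
        preferences=Preferences({"o": np.zeros(a.shape[0])}),
        policies=(Policy(({},)),),
    )


class TestInferStates:
    def test_single_step_bayes_with_flat_prior(self):
        a = np.array([[0.7, 0.2], [0.3, 0.8]])
        model = single_factor_model(a, np.eye(2))
        res = infer_states(
            [{"o": 0}],
            model.policies[0],
            model,
            {"s": Categorical(np.full(2, 0.5))},
            horizon=1,
        )
        expected = a[0] / a[0].sum()
        assert np.allclose(res.marginals["s"][0], expected, atol=1e-10)

    def test_uninformative_likelihood_returns_propagated_prior(self):
        # zero evidence: posteriors track the prior through the dynamics —
        # the mechanism that lets slow-level priors re-express as replay
        a = np.full((3, 2), 1 / 3)
        b = np.array([[0.9, 0.4], [0.1, 0.6]])
        prior = np.array([0.3, 0.7])
        model = single_factor_model(a, b)
        res = infer_states(
            [{"o": 1}, {"o": 0}, {"o": 2}],
            model.policies[0],
            model,
            {"s": Categorical(prior)},
            horizon=3,
        )
        expect = prior
        for t in range(3):
            assert np.allclose(res.marginals["s"][t], expect, atol=1e-9)
            expect = b @ expect

    def test_two_state_chain_matches_enumeration(self):
        a = np.array([[0.8, 0.3], [0.2, 0.7]])
        b = np.array([[0.6, 0.2], [0.4, 0.8]])
        prior = np.array([0.5, 0.5])
        model = single_factor_model(a, b)
        obs = [{"o": 0}, {"o": 1}]
        res = infer_states(obs, model.policies[0], model, {"s": Categorical(prior)}, horizon=2)
        want = enumerate_state_posterior(model, obs, model.policies[0], {"s": prior})
        assert np.allclose(res.marginals["s"][:2], want["s"], atol=1e-6)

    def test_random_models_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            model, obs, prior, T = random_single_factor_model(rng)
            res = infer_states(
                obs, model.policies[0], model, {"s": Categorical(prior)}, horizon=T
            )
            want = enumerate_state_posterior(model, obs, model.policies[0], {"s": prior})
            assert np.allclose(res.marginals["s"][:T], want["s"], atol=1e-6)

    def test_free_energy_trace_non_increasing_multi_factor(self, rng):
        # two coupled factors force several coordinate-ascent sweeps
        for _ in range(10):
            n1, n2, n_o, T = 2, 3, 3, 3

            def stoch(shape):
                m = rng.random(shape) + 0.05
                return m / m.sum(axis=0, keepdims=True)

            model = MDPModel(
                space=StateSpace((Factor("u", ("u0", "u1")), Factor("v", ("v0", "v1", "v2")))),
                likelihood=LikelihoodModel(
                    (
                        Modality(
                            "o",
                            tuple(f"o{i}" for i in range(n_o)),
                            ConditionalTable(stoch((n_o, n1, n2))),
                        ),
                    )
                ),
                transitions=TransitionModel(
                    {"u": stoch((n1, n1))[None], "v": stoch((n2, n2))[None]}
                ),
                preferences=Preferences({"o": np.zeros(n_o)}),
                policies=(Policy(({},)),),
            )
            priors = {
                "u": Categorical(np.full(n1, 1 / n1)),
                "v": Categorical(np.full(n2, 1 / n2)),
            }
            obs = [{"o": int(rng.integers(0, n_o))} for _ in range(T)]
            res = infer_states(obs, model.policies[0], model, priors, horizon=T)
            diffs = np.diff(res.f_trace)
            assert np.all(diffs <= 1e-8)


class TestExpectedFreeEnergy:
    def test_ambiguity_zero_for_deterministic_likelihood(self, task_model):
        # every built likelihood column is a delta, so expected entropy is 0
        l1 = task_model.level1_model
        for m in l1.likelihood.names:
            assert np.all(l1.column_entropy(m) == 0.0)

    def test_zero_when_prediction_equals_preference(self):
        a = np.eye(2)
        model = single_factor_model(a, np.eye(2))
        model = MDPModel(
            space=model.space,
            likelihood=model.likelihood,
            transitions=model.transitions,
            preferences=Preferences({"o": np.log(np.array([0.25, 0.75]))}),
            policies=model.policies,
        )
        res = InferenceResult(
            marginals={"s": np.array([[1.0, 0.0], [0.25, 0.75]])},
            pairwise={"s": []},
            free_energy=0.0,
            f_trace=[0.0],
            n_observed=1,
            converged=True,
        )
        g = expected_free_energy(model.policies[0], model, model.preferences, res, horizon=2)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_tmaze_cue_then_right_hand_arithmetic(self, task_model):
        """G of the explore-then-exploit policy at step 1, by hand."""
        model = task_model.level1_model
        priors, _ = descend(task_model.level2_priors, task_model.link, task_model.level2_space)
        cue, right = LOCATIONS.index("cue"), LOCATIONS.index("right")
        policy = next(
            p
            for p in model.policies
            if (p.moves[0]["location"], p.moves[1]["location"]) == (cue, right)
        )
        obs1 = {
            "extero": EXTERO.index("centre"),
            "reward": REWARDS.index("neutral"),
            "heard": TOKENS.index("~"),
            "spoken": TOKENS.index("~"),
        }
        res = infer_states([obs1], policy, model, priors, horizon=3)
        got = expected_free_energy(policy, model, model.preferences, res, horizon=3)

        # independent arithmetic from the preference constants
        cfg = TaskConfig()
        ze = math.exp(cfg.preference_centre) + 4.0
        pe_centre, pe_other = math.exp(cfg.preference_centre) / ze, 1.0 / ze
        zr = 1.0 + math.exp(cfg.preference_attractive) + math.exp(cfg.preference_aversive)
        pr_neu = 1.0 / zr
        pr_att = math.exp(cfg.preference_attractive) / zr
        pr_ave = math.exp(cfg.preference_aversive) / zr
        want = (
            # step 2: at the cue, context still 50/50 -> split cue percept
            0.5 * math.log(0.5 / pe_other) + 0.5 * math.log(0.5 / pe_other)
            + math.log(1.0 / pr_neu)
            # step 3: right arm, reward attractive or aversive at 50/50
            + math.log(1.0 / pe_other)
            + 0.5 * math.log(0.5 / pr_att) + 0.5 * math.log(0.5 / pr_ave)
            # both word modalities predict silence against flat preferences
            + 4.0 * math.log(len(TOKENS))
        )
        assert got == pytest.approx(want, abs=1e-8)


class TestPolicyPosterior:
    def test_uniform_bias_equal_f_is_softmax_neg_g(self):
        g = np.array([1.0, 2.0, 0.5])
        q = policy_posterior(np.ones(3), g, np.zeros(3))
        want = np.exp(-g) / np.exp(-g).sum()
        assert np.allclose(q.probs, want, atol=1e-12)

    def test_delta_bias_wins_regardless_of_g_and_f(self):
        q = policy_posterior(np.array([0.0, 1.0]), np.array([100.0, 0.0]), np.array([50.0, 0.0]))
        assert q.probs[1] == 1.0

    def test_hand_set_three_policies(self):
        e = np.array([0.2, 0.5, 0.3])
        g = np.array([1.0, 2.0, 0.0])
        f = np.array([0.5, 0.0, 1.0])
        w = e * np.exp(-g - f)
        q = policy_posterior(e, g, f)
        assert np.allclose(q.probs, w / w.sum(), atol=1e-12)

    def test_constant_shift_invariance(self):
        e = np.array([0.2, 0.5, 0.3])
        g = np.array([1.0, 2.0, 0.0])
        f = np.array([0.5, 0.0, 1.0])
        a = policy_posterior(e, g, f).probs
        b = policy_posterior(e, g + 3.7, f - 1.2).probs
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_bias_degenerate(self):
        with pytest.raises(DegenerateInputError):
            policy_posterior(np.zeros(2), np.zeros(2), np.zeros(2))


class TestSelectAction:
    @pytest.fixture
    def two_policy_space(self):
        space = StateSpace((Factor("x", ("a", "b"), controllable=True),))
        pols = (Policy(({"x": 0},)), Policy(({"x": 1},)))
        return space, pols

    def test_delta_policy_posterior(self, two_policy_space):
        space, pols = two_policy_space
        act = select_action(Categorical(np.array([0.0, 1.0])), pols, 1, space)
        assert act == {"x": 1}

    def test_split_posterior_same_action(self):
        space = StateSpace((Factor("x", ("a", "b"), controllable=True),))
        pols = (Policy(({"x": 1},)), Policy(({"x": 1},)))
        act = select_action(Categorical(np.array([0.5, 0.5])), pols, 1, space)
        assert act == {"x": 1}

    def test_first_tmaze_action_is_go_cue(self, std_first):
        _, records = std_first
        assert records[0].trial.actions[0]["location"] == LOCATIONS.index("cue")


class TestReflexiveOutcome:
    def test_delta_beliefs_deterministic_likelihood(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = single_factor_model(a, np.eye(2))
        marg = {"s": np.array([[0.0, 1.0]])}
        assert reflexive_outcome(marg, model, "o", 0) == 1

    def test_uniform_beliefs_pick_higher_likelihood_word(self):
        # two states map to words w1/w2 with 0.9/0.1 asymmetry:
        # E[ln P] favours w1 under uniform beliefs
        a = np.array([[0.9, 0.1], [0.1, 0.9]])
        b = np.array([[0.9, 0.5], [0.1, 0.5]])
        model = single_factor_model(b, np.eye(2))
        marg = {"s": np.array([[0.5, 0.5]])}
        assert reflexive_outcome(marg, model, "o", 0) == 0
        # sanity: symmetric table ties and breaks to the lowest index
        model2 = single_factor_model(a, np.eye(2))
        assert reflexive_outcome({"s": np.array([[0.5, 0.5]])}, model2, "o", 0) == 0


class TestEnvironmentStep:
    @pytest.fixture
    def process(self, task_model):
        l1 = task_model.level1_model
        return GenerativeProcess(
            space=l1.space,
            transitions=l1.transitions,
            likelihood=l1.likelihood,
            rng=np.random.default_rng(0),
        )

    @staticmethod
    def states(loc, ctx):
        return {
            "location": loc,
            "context": ctx,
            "query_slot": 0,
            "knowledge": 0,
            "verb": 0,
            "destination": 0,
            "syntax": SYNTAX.index("silent"),
        }

    def test_arm_is_absorbing(self, process):
        left = LOCATIONS.index("left")
        for a in range(4):
            nxt, _ = environment_step(self.states(left, 0), {"location": a}, process)
            assert nxt["location"] == left

    def test_cue_reports_context(self, process):
        cue = LOCATIONS.index("cue")
        right = CONTEXTS.index("right")
        nxt, obs = environment_step(
            self.states(cue, right), {"location": cue}, process
        )
        assert obs["extero"] == EXTERO.index("cue-right")

    def test_centre_go_cue(self, process):
        nxt, obs = environment_step(
            self.states(LOCATIONS.index("centre"), 0),
            {"location": LOCATIONS.index("cue")},
            process,
        )
        assert nxt["location"] == LOCATIONS.index("cue")
        assert obs["reward"] == REWARDS.index("neutral")


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, task_model):
        l1 = task_model.level1_model
        data = json.loads(json.dumps(model_to_dict(l1)))
        back = model_from_dict(data)
        for m in l1.likelihood.modalities:
            assert np.array_equal(m.table.table, back.likelihood[m.name].table.table)
        for k, v in l1.transitions.tables.items():
            assert np.array_equal(v, back.transitions.tables[k])
        for k, v in l1.preferences.log_c.items():
            assert np.array_equal(v, back.preferences.log_c[k])
        assert back.policies == l1.policies
        assert back.space == l1.space
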