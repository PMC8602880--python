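"""Single-level factorised POMDP engine.

A level of the generative model is a discrete state space factorised into
named factors, a likelihood mapping from factor combinations to outcomes in
several modalities, per-factor action-conditioned transition tables, log
preferences over outcomes, and a small space of allowable policies (action
sequences over the controllable factors).

Inference is variational: the posterior over hidden states, conditioned on
each policy, is optimised by coordinate ascent that is mean-field *across*
factors but keeps each factor's trajectory as an exact chain (forward-
backward in log space). Each coordinate update is an exact minimisation of
the variational free energy F given the other factors, so F is
non-increasing over iterations; and for a single-factor model the scheme
reduces to exact smoothing.

Policies are scored by ``softmax(ln E - G - F)`` where E is a prior bias
over policies, G the expected free energy (risk plus ambiguity) of the
policy's remaining steps, and F the accumulated variational free energy of
the observations so far under that policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .categorical import (
    Categorical,
    ConditionalTable,
    DegenerateInputError,
    ShapeError,
    entropy,
    guarded_log,
    kl_divergence,
    softmax,
    tie_break_argmax,
)

logger = logging.getLogger("mazetalk")

#: fixed-point iteration schedule for state inference
MAX_ITERATIONS = 16
F_CONVERGENCE_TOL = 1e-4


# ---------------------------------------------------------------------------
# state space, model components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Factor:
    """One hidden-state factor: a named discrete variable."""

    name: str
    levels: tuple[str, ...]
    controllable: bool = False

    @property
    def n(self) -> int:
        return len(self.levels)

    def index(self, level: str) -> int:
        return self.levels.index(level)


@dataclass(frozen=True)
class StateSpace:
    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if any(f.n < 1 for f in self.factors):
            raise ValueError("every factor needs at least one level")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(f.n for f in self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def factor(self, name: str) -> Factor:
        return self.factors[self.index(name)]

    @property
    def controllable(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors if f.controllable)


@dataclass(frozen=True)
class Modality:
    """One outcome modality: named levels plus P(o | all state factors)."""

    name: str
    levels: tuple[str, ...]
    table: ConditionalTable

    def index(self, level: str) -> int:
        return self.levels.index(level)


@dataclass(frozen=True)
class LikelihoodModel:
    modalities: tuple[Modality, ...]

    def __getitem__(self, name: str) -> Modality:
        for m in self.modalities:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.modalities)


@dataclass(frozen=True)
class TransitionModel:
    """Per factor: array (n_actions, n_next, n_prev); one action when
    uncontrollable."""

    tables: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, t in self.tables.items():
            t = np.asarray(t, dtype=float)
            self.tables[name] = t
            if t.ndim != 3:
                raise ShapeError(f"transition table for {name!r} must be 3-D")
            # every (action, prev) column is a distribution over next states
            ConditionalTable(np.moveaxis(t, 1, 0).reshape(t.shape[1], -1))

    def table(self, factor: str, action: int = 0) -> np.ndarray:
        t = self.tables[factor]
        return t[action if t.shape[0] > 1 else 0]


@dataclass(frozen=True)
class Preferences:
    """Log preferences (C) per modality; only differences matter."""

    log_c: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for k, v in self.log_c.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"preferences for {k!r} must be finite")
            self.log_c[k] = v

    def outcome_prior(self, modality: str) -> Categorical:
        return softmax(self.log_c[modality])


@dataclass(frozen=True)
class Policy:
    """A fixed sequence of control levels for each controllable factor.

    ``moves[t]`` maps factor name to the action taken between time t+1 and
    t+2; beyond the policy's length the final action is repeated (which, for
    move-to-target dynamics, keeps the state where the policy left it).
    """

    moves: tuple[dict[str, int], ...]

    def action_at(self, t: int) -> dict[str, int]:
        """Action applied between time t and t+1 (1-based t)."""
        return self.moves[min(t, len(self.moves)) - 1]


@dataclass(frozen=True)
class MDPModel:
    space: StateSpace
    likelihood: LikelihoodModel
    transitions: TransitionModel
    preferences: Preferences
    policies: tuple[Policy, ...]

    def __post_init__(self) -> None:
        for m in self.likelihood.modalities:
            if m.table.parent_shape != self.space.shape:
                raise ShapeError(
                    f"modality {m.name!r} parents {m.table.parent_shape} "
                    f"do not match state space {self.space.shape}"
                )
        # cached guarded logs of the likelihood tensors
        object.__setattr__(
            self,
            "_log_a",
            {m.name: guarded_log(m.table.table) for m in self.likelihood.modalities},
        )
        # cached per-modality column-entropy tensors (exact 0 ln 0 = 0)
        amb = {}
        for m in self.likelihood.modalities:
            t = m.table.table
            amb[m.name] = -np.sum(np.where(t > 0, t * np.log(np.where(t > 0, t, 1.0)), 0.0), axis=0)
        object.__setattr__(self, "_column_entropy", amb)

    def log_likelihood(self, modality: str) -> np.ndarray:
        return self._log_a[modality]

    def column_entropy(self, modality: str) -> np.ndarray:
        return self._column_entropy[modality]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _contract_all(tensor: np.ndarray, marginals: list[np.ndarray]) -> float:
    out = tensor
    for m in reversed(marginals):
        out = out @ m
    return float(out)


def _contract_except(tensor: np.ndarray, marginals: list[np.ndarray], keep: int) -> np.ndarray:
    """Contract every axis except ``keep`` with the matching marginal."""
    out = np.moveaxis(tensor, keep, 0)
    others = [m for i, m in enumerate(marginals) if i != keep]
    for m in reversed(others):
        out = out @ m
    return out


# ---------------------------------------------------------------------------
# state inference (per policy)
# ---------------------------------------------------------------------------


@dataclass
class InferenceResult:
    """Posterior over one policy's state trajectory.

    ``marginals[f]`` has shape (horizon, n_levels): rows 1..n_observed are
    smoothed posteriors, later rows are forward predictions under the
    policy. ``free_energy`` is the variational free energy of the observed
    segment; ``f_trace`` its value after each coordinate-ascent sweep.
    """

    marginals: dict[str, np.ndarray]
    pairwise: dict[str, list[np.ndarray]]
    free_energy: float
    f_trace: list[float]
    n_observed: int
    converged: bool


def _forward_backward(
    log_prior: np.ndarray,
    log_trans: list[np.ndarray],
    emissions: np.ndarray,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Exact smoothing of one factor chain in log space.

    log_trans[t] is ln B for the step from time t+1 to t+2 (shape next x
    prev); emissions has shape (T, n). Returns (marginals (T, n), pairwise
    joints xi[t] with shape (prev, next) for each step).
    """
    T, n = emissions.shape
    alpha = np.zeros((T, n))
    alpha[0] = log_prior + emissions[0]
    for t in range(1, T):
        alpha[t] = emissions[t] + logsumexp(alpha[t - 1][None, :] + log_trans[t - 1], axis=1)
    beta = np.zeros((T, n))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp((beta[t + 1] + emissions[t + 1])[:, None] + log_trans[t], axis=0)
    log_post = alpha + beta
    log_z = logsumexp(log_post[-1])
    marg = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
    pairwise = []
    for t in range(T - 1):
        lx = (
            alpha[t][None, :]
            + log_trans[t]
            + (beta[t + 1] + emissions[t + 1])[:, None]
            - log_z
        )
        xi = np.exp(lx).T  # (prev, next)
        xi /= max(xi.sum(), 1e-300)
        pairwise.append(xi)
    return marg, pairwise


def infer_states(
    observations: list[dict[str, int]],
    policy: Policy,
    model: MDPModel,
    initial_priors: dict[str, Categorical],
    horizon: int,
    max_iterations: int = MAX_ITERATIONS,
    tol: float = F_CONVERGENCE_TOL,
) -> InferenceResult:
    """Variational state posterior under one policy given observations so far.

    Coordinate ascent over per-factor chains: each factor's trajectory is
    re-smoothed exactly (forward-backward) against the mean-field
    expectation of the log likelihood under the other factors' current
    marginals. The returned free energy evaluates
    ``KL[Q(s|pi) || P(s|pi)] - E_Q[ln P(o|s)]`` at the returned posterior
    and is non-increasing across sweeps.
    """
    space = model.space
    n_obs = len(observations)
    if n_obs < 1:
        raise ValueError("need at least one observation")
    if n_obs > horizon:
        raise ValueError("more observations than the horizon allows")

    names = space.names
    sizes = dict(zip(names, space.shape))
    log_priors = {f: guarded_log(initial_priors[f].probs) for f in names}
    # per-factor transition matrices for each step of the observed window
    log_trans: dict[str, list[np.ndarray]] = {}
    trans: dict[str, list[np.ndarray]] = {}
    for f in names:
        ctrl = space.factor(f).controllable
        mats = []
        for t in range(1, horizon):
            a = policy.action_at(t).get(f, 0) if ctrl else 0
            mats.append(model.transitions.table(f, a))
        trans[f] = mats
        log_trans[f] = [guarded_log(m) for m in mats]

    # initialise marginals at the prior propagated forward
    marg: dict[str, np.ndarray] = {}
    for f in names:
        rows = np.zeros((n_obs, sizes[f]))
        rows[0] = initial_priors[f].probs
        for t in range(1, n_obs):
            rows[t] = trans[f][t - 1] @ rows[t - 1]
        marg[f] = rows

    pairwise: dict[str, list[np.ndarray]] = {f: [] for f in names}

    def emissions_for(f: int) -> np.ndarray:
        fname = names[f]
        h = np.zeros((n_obs, sizes[fname]))
        for t, obs in enumerate(observations):
            row = np.zeros(sizes[fname])
            for mod, o in obs.items():
                ln_a = model.log_likelihood(mod)[o]
                row += _contract_except(ln_a, [marg[g][t] for g in names], f)
            h[t] = row
        return h

    def free_energy() -> float:
        e_ln_q = 0.0
        e_ln_p = 0.0
        for f in names:
            q1 = marg[f][0]
            nz = q1 > 0
            e_ln_q += float(np.sum(q1[nz] * np.log(q1[nz])))
            e_ln_p += float(np.sum(q1 * log_priors[f]))
            for t, xi in enumerate(pairwise[f]):
                nzx = xi > 0
                prev = marg[f][t]
                cond = xi / np.where(prev[:, None] > 0, prev[:, None], 1.0)
                e_ln_q += float(np.sum(xi[nzx] * np.log(cond[nzx])))
                e_ln_p += float(np.sum(xi * log_trans[f][t].T))
        for t, obs in enumerate(observations):
            for mod, o in obs.items():
                e_ln_p += _contract_all(
                    model.log_likelihood(mod)[o], [marg[g][t] for g in names]
                )
        return e_ln_q - e_ln_p

    f_trace: list[float] = []
    converged = False
    for _ in range(max_iterations):
        for f_idx, fname in enumerate(names):
            h = emissions_for(f_idx)
            m, xi = _forward_backward(log_priors[fname], log_trans[fname], h)
            marg[fname] = m
            pairwise[fname] = xi
        f_now = free_energy()
        if f_trace and abs(f_trace[-1] - f_now) < tol:
            f_trace.append(f_now)
            converged = True
            break
        f_trace.append(f_now)
    if not converged and len(f_trace) >= max_iterations:
        # a warning, not an error: the last iterate is still a usable bound
        logger.warning("state inference did not converge in %d sweeps", max_iterations)

    # forward predictions for the un-observed remainder of the horizon
    full: dict[str, np.ndarray] = {}
    for f in names:
        rows = np.zeros((horizon, sizes[f]))
        rows[:n_obs] = marg[f]
        for t in range(n_obs, horizon):
            rows[t] = trans[f][t - 1] @ rows[t - 1]
        full[f] = rows

    return InferenceResult(
        marginals=full,
        pairwise=pairwise,
        free_energy=f_trace[-1],
        f_trace=f_trace,
        n_observed=n_obs,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# expected free energy, policy posterior, action
# ---------------------------------------------------------------------------


def expected_free_energy(
    policy: Policy,
    model: MDPModel,
    preferences: Preferences,
    posteriors: InferenceResult,
    horizon: int,
    return_components: bool = False,
):
    """G = sum over future steps and modalities of risk + ambiguity.

    Risk is the KL divergence from the predicted outcome distribution to
    the softmax-normalised preferences; ambiguity the expected entropy of
    the likelihood columns under the predicted states.
    """
    names = model.space.names
    risk_total = 0.0
    amb_total = 0.0
    for t in range(posteriors.n_observed, horizon):
        marginals = [posteriors.marginals[f][t] for f in names]
        for m in model.likelihood.modalities:
            q_o = m.table.table
            for mv in reversed(marginals):
                q_o = q_o @ mv
            risk_total += kl_divergence(
                Categorical(q_o / q_o.sum()), preferences.outcome_prior(m.name)
            )
            amb_total += _contract_all(model.column_entropy(m.name), marginals)
    if return_components:
        return risk_total + amb_total, risk_total, amb_total
    return risk_total + amb_total


def policy_posterior(
    bias: np.ndarray, g_values: np.ndarray, f_values: np.ndarray
) -> Categorical:
    """Q(pi) = softmax(ln E - G - F) over the policy space."""
    e = np.asarray(bias, dtype=float)
    g = np.asarray(g_values, dtype=float)
    f = np.asarray(f_values, dtype=float)
    if not (e.shape == g.shape == f.shape):
        raise ShapeError("bias, G and F must have the same length")
    if np.any(e < 0):
        raise ValueError("policy bias weights must be non-negative")
    if e.sum() <= 0:
        raise DegenerateInputError("all policy bias weights are zero")
    with np.errstate(divide="ignore"):
        ln_e = np.where(e > 0, np.log(np.where(e > 0, e, 1.0)), -np.inf)
    return softmax(ln_e - g - f)


def select_action(
    q_pi: Categorical,
    policies: tuple[Policy, ...],
    t: int,
    space: StateSpace,
) -> dict[str, int]:
    """Most probable action at step t under the action marginal of Q(pi)."""
    actions: dict[str, int] = {}
    for fname in space.controllable:
        n_actions = max(p.action_at(t)[fname] for p in policies) + 1
        weight = np.zeros(n_actions)
        for p, q in zip(policies, q_pi.probs):
            weight[p.action_at(t)[fname]] += q
        actions[fname] = tie_break_argmax(weight)
    return actions


def reflexive_outcome(
    marginals: dict[str, np.ndarray],
    model: MDPModel,
    modality: str,
    t: int,
) -> int:
    """Outcome maximising expected log likelihood under current beliefs.

    The self-generated (spoken) outcome of Eq-style reflexive action: the
    agent emits whatever word its beliefs best predict, ties breaking to
    the lowest index.
    """
    names = model.space.names
    ms = [marginals[f][t] for f in names]
    ln_a = model.log_likelihood(modality)
    scores = np.array([_contract_all(ln_a[o], ms) for o in range(ln_a.shape[0])])
    return tie_break_argmax(scores)


# ---------------------------------------------------------------------------
# generative process (environment)
# ---------------------------------------------------------------------------


@dataclass
class GenerativeProcess:
    """True-state mirror of a model: transition + likelihood tables.

    Deterministic when the tables are deltas; otherwise outcomes and
    transitions are sampled with the supplied generator.
    """

    space: StateSpace
    transitions: TransitionModel
    likelihood: LikelihoodModel
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def _draw(self, probs: np.ndarray) -> int:
        if probs.max() >= 1.0 - 1e-12:
            return int(np.argmax(probs))
        return int(self.rng.choice(probs.shape[0], p=probs / probs.sum()))


def environment_step(
    true_states: dict[str, int],
    actions: dict[str, int],
    process: GenerativeProcess,
) -> tuple[dict[str, int], dict[str, int]]:
    """Propagate the true states one step and emit observations."""
    nxt: dict[str, int] = {}
    for f in process.space.names:
        a = actions.get(f, 0) if process.space.factor(f).controllable else 0
        col = process.transitions.table(f, a)[:, true_states[f]]
        nxt[f] = process._draw(col)
    obs: dict[str, int] = {}
    idx = tuple(nxt[f] for f in process.space.names)
    for m in process.likelihood.modalities:
        obs[m.name] = process._draw(m.table.table[(slice(None), *idx)])
    return nxt, obs


# ---------------------------------------------------------------------------
# one level-1 trial
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """Everything realised and believed during one level-1 trial (epoch)."""

    observations: list[dict[str, int]]
    actions: list[dict[str, int]]
    spoken: list[int | None]
    q_pi_per_time: list[Categorical]
    f_per_policy: np.ndarray
    g_per_policy: np.ndarray
    results: list[InferenceResult]
    #: smoothed end-of-trial beliefs, policy-averaged: factor -> (horizon, n)
    mixture_marginals: dict[str, np.ndarray]
    #: beliefs as they were held: row t is the belief about time t formed at
    #: step t (the raster a recording during the trial would show)
    online_marginals: dict[str, np.ndarray]
    bias: np.ndarray
    f_traces: list[list[float]]
    horizon: int

    @property
    def q_pi(self) -> Categorical:
        return self.q_pi_per_time[-1]

    def map_policy(self) -> int:
        return self.q_pi.argmax()


def _mixture(results: list[InferenceResult], q_pi: Categorical, names) -> dict[str, np.ndarray]:
    out = {}
    for f in names:
        out[f] = sum(q * r.marginals[f] for q, r in zip(q_pi.probs, results))
    return out


def run_trial(
    model: MDPModel,
    priors: dict[str, Categorical],
    bias: np.ndarray,
    environment,
    horizon: int,
    speak_modality: str | None = None,
) -> TrialRecord:
    """Run one trial: observe, infer per policy, score policies, act.

    At each time step the agent (optionally) generates a spoken outcome
    reflexively from its predictive beliefs, receives the environment's
    observations, re-infers its state posterior and policy posterior, and
    (before the final step) selects and enacts the most probable action.
    """
    names = model.space.names
    policies = model.policies
    observations: list[dict[str, int]] = []
    actions_taken: list[dict[str, int]] = []
    spoken_tokens: list[int | None] = []
    q_pi_per_time: list[Categorical] = []
    results: list[InferenceResult] = [None] * len(policies)  # type: ignore
    f_vals = np.zeros(len(policies))
    g_vals = np.zeros(len(policies))
    online = {f: np.zeros((horizon, model.space.factor(f).n)) for f in names}
    q_pi = None

    for t in range(1, horizon + 1):
        spoken = None
        if speak_modality is not None and environment.agent_speaks(t):
            if t == 1 or q_pi is None:
                pred = {f: np.tile(priors[f].probs, (horizon, 1)) for f in names}
            else:
                pred = _mixture(results, q_pi, names)
            spoken = reflexive_outcome(pred, model, speak_modality, t - 1)
        spoken_tokens.append(spoken)

        obs = environment.observe(t, spoken)
        observations.append(obs)

        for i, pol in enumerate(policies):
            res = infer_states(observations, pol, model, priors, horizon)
            results[i] = res
            f_vals[i] = res.free_energy
            g_vals[i] = expected_free_energy(pol, model, model.preferences, res, horizon)
        q_pi = policy_posterior(bias, g_vals, f_vals)
        q_pi_per_time.append(q_pi)
        mix_now = _mixture(results, q_pi, names)
        for f in names:
            online[f][t - 1] = mix_now[f][t - 1]

        if t < horizon:
            act = select_action(q_pi, policies, t, model.space)
            actions_taken.append(act)
            environment.apply_action(act)

    return TrialRecord(
        observations=observations,
        actions=actions_taken,
        spoken=spoken_tokens,
        q_pi_per_time=q_pi_per_time,
        f_per_policy=f_vals.copy(),
        g_per_policy=g_vals.copy(),
        results=list(results),
        mixture_marginals=_mixture(results, q_pi, names),
        online_marginals=online,
        bias=np.asarray(bias, dtype=float).copy(),
        f_traces=[r.f_trace for r in results],
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# serialisation of model tables
# ---------------------------------------------------------------------------


def model_to_dict(model: MDPModel) -> dict:
    """Plain-data description of a model; bit-exact round-trip with
    :func:`model_from_dict`."""
    return {
        "factors": [
            {"name": f.name, "levels": list(f.levels), "controllable": f.controllable}
            for f in model.space.factors
        ],
        "modalities": [
            {"name": m.name, "levels": list(m.levels), "table": m.table.table.tolist()}
            for m in model.likelihood.modalities
        ],
        "transitions": {k: v.tolist() for k, v in model.transitions.tables.items()},
        "preferences": {k: v.tolist() for k, v in model.preferences.log_c.items()},
        "policies": [
            [dict(step) for step in p.moves] for p in model.policies
        ],
    }


def model_from_dict(data: dict) -> MDPModel:
    space = StateSpace(
        tuple(
            Factor(f["name"], tuple(f["levels"]), bool(f["controllable"]))
            for f in data["factors"]
        )
    )
    likelihood = LikelihoodModel(
        tuple(
            Modality(m["name"], tuple(m["levels"]), ConditionalTable(np.array(m["table"])))
            for m in data["modalities"]
        )
    )
    transitions = TransitionModel({k: np.array(v) for k, v in data["transitions"].items()})
    prefs = Preferences({k: np.array(v) for k, v in data["preferences"].items()})
    policies = tuple(
        Policy(tuple({k: int(a) for k, a in step.items()} for step in p))
        for p in data["policies"]
    )
    return MDPModel(space, likelihood, transitions, prefs, policies)
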