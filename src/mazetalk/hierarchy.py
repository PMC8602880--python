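"""Deep temporal (two-level) composition.

The slow level is a small MDP over narrative epochs with no policies of its
own: its factors (narrative stage, the two maze moves, the reward side, the
query type) evolve by fixed transitions. A link maps slow-level factor
tuples to (i) empirical initial-state priors for every fast-level factor
and (ii) an empirical bias E over the fast level's policies. After each
epoch the fast level's posterior over initial states and policies is turned
into a log-evidence table over slow-level tuples; the slow posterior is
updated once per epoch (adiabatic scheduling), projected back onto
per-factor marginals, and propagated to the next epoch through the slow
transitions as the next empirical prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categorical import (
    Categorical,
    ConditionalTable,
    ShapeError,
    expect_over_factors,
    guarded_log,
    softmax,
    tie_break_argmax,
)
from .mdp import MDPModel, StateSpace, TransitionModel, TrialRecord, run_trial


@dataclass(frozen=True)
class LevelLink:
    """Slow-to-fast mappings.

    ``state_links[f]`` gives the fast factor f's initial-state distribution
    conditioned on the full slow-level factor tuple; ``policy_link`` gives
    the bias over fast-level policies conditioned on the same tuple.
    """

    state_links: dict[str, ConditionalTable]
    policy_link: ConditionalTable


@dataclass(frozen=True)
class HierarchicalModel:
    level2_space: StateSpace
    level2_transitions: TransitionModel
    level2_priors: dict[str, Categorical]
    level1_model: MDPModel
    link: LevelLink
    epoch_horizons: dict[str, int]
    speak_modality: str | None = None

    def __post_init__(self) -> None:
        shape = self.level2_space.shape
        for f, t in self.link.state_links.items():
            if t.parent_shape != shape:
                raise ShapeError(f"link for {f!r} does not match the slow state space")
            if t.n_outcomes != self.level1_model.space.factor(f).n:
                raise ShapeError(f"link for {f!r} does not match the fast factor size")
        if self.link.policy_link.parent_shape != shape:
            raise ShapeError("policy link does not match the slow state space")
        if self.link.policy_link.n_outcomes != len(self.level1_model.policies):
            raise ShapeError("policy link does not match the policy count")


@dataclass
class EpochRecord:
    """One slow-level time step: priors, the fast trial, and the update."""

    index: int
    epoch_type: str
    prior_marginals: dict[str, Categorical]
    trial: TrialRecord
    log_evidence: np.ndarray
    posterior_marginals: dict[str, Categorical]
    joint_map: dict[str, str]
    joint_map_prob: float
    level1_priors: dict[str, Categorical]
    level1_bias: np.ndarray


def descend(
    level2_marginals: dict[str, Categorical],
    link: LevelLink,
    level2_space: StateSpace,
) -> tuple[dict[str, Categorical], np.ndarray]:
    """Empirical fast-level priors and policy bias from slow beliefs."""
    order = [level2_marginals[f] for f in level2_space.names]
    priors = {f: expect_over_factors(t, order) for f, t in link.state_links.items()}
    bias = expect_over_factors(link.policy_link, order)
    return priors, bias.probs


def ascend(
    trial: TrialRecord,
    link: LevelLink,
    level2_space: StateSpace,
) -> np.ndarray:
    """Log evidence each slow tuple earns from a completed fast trial.

    The link predicts the fast level's initial states and its policy, so
    the evidence is the expected log prediction of the inferred initial
    state per linked factor plus the expected log bias of the inferred
    policy posterior.
    """
    evidence = np.zeros(level2_space.shape)
    for f, table in link.state_links.items():
        q1 = trial.mixture_marginals[f][0]
        evidence += np.tensordot(q1, guarded_log(table.table), axes=(0, 0))
    evidence += np.tensordot(
        trial.q_pi.probs, guarded_log(link.policy_link.table), axes=(0, 0)
    )
    return evidence


def update_level2(
    prior_marginals: dict[str, Categorical],
    log_evidence: np.ndarray,
    level2_space: StateSpace,
) -> tuple[dict[str, Categorical], dict[str, str], float]:
    """Slow posterior: softmax(ln prior + evidence), then factor marginals.

    Returns the mean-field projection, the MAP tuple of the joint (before
    projection) as level names, and that tuple's joint probability.
    """
    shape = level2_space.shape
    if log_evidence.shape != shape:
        raise ShapeError("evidence table does not match the slow state space")
    ln_joint = log_evidence.copy()
    for axis, f in enumerate(level2_space.names):
        vec = guarded_log(prior_marginals[f].probs)
        ln_joint += vec.reshape([-1 if i == axis else 1 for i in range(len(shape))])
    joint = softmax(ln_joint.ravel()).probs.reshape(shape)
    marginals: dict[str, Categorical] = {}
    for axis, f in enumerate(level2_space.names):
        axes = tuple(i for i in range(len(shape)) if i != axis)
        marginals[f] = Categorical(joint.sum(axis=axes))
    flat_idx = tie_break_argmax(joint.ravel())
    map_idx = np.unravel_index(flat_idx, shape)
    map_tuple = {
        f: level2_space.factor(f).levels[i]
        for f, i in zip(level2_space.names, map_idx)
    }
    return marginals, map_tuple, float(joint[map_idx])


def advance_epoch(
    posterior_marginals: dict[str, Categorical],
    level2_transitions: TransitionModel,
    level2_space: StateSpace,
) -> dict[str, Categorical]:
    """Propagate slow beliefs to the next epoch through the slow dynamics."""
    out = {}
    for f in level2_space.names:
        b = level2_transitions.table(f, 0)
        out[f] = Categorical(b @ posterior_marginals[f].probs)
    return out


def run_hierarchy(
    model: HierarchicalModel,
    environment,
    n_epochs: int | None = None,
) -> list[EpochRecord]:
    """descend -> run the fast trial -> ascend -> update -> advance.

    The slow posterior is touched exactly once per epoch, at its end
    (the adiabatic assumption); ``environment.epoch_plan`` names the true
    epoch types, which fix the fast horizons and the environment's
    behaviour.
    """
    plan = list(environment.epoch_plan)
    if n_epochs is not None:
        plan = plan[:n_epochs]
    if len(plan) < 1:
        raise ValueError("need at least one epoch")

    records: list[EpochRecord] = []
    prior = {f: model.level2_priors[f] for f in model.level2_space.names}
    for k, epoch_type in enumerate(plan):
        horizon = model.epoch_horizons[epoch_type]
        priors1, bias = descend(prior, model.link, model.level2_space)
        environment.begin_epoch(k, epoch_type)
        trial = run_trial(
            model.level1_model,
            priors1,
            bias,
            environment,
            horizon,
            speak_modality=model.speak_modality,
        )
        evidence = ascend(trial, model.link, model.level2_space)
        posterior, map_tuple, map_prob = update_level2(
            prior, evidence, model.level2_space
        )
        records.append(
            EpochRecord(
                index=k,
                epoch_type=epoch_type,
                prior_marginals=dict(prior),
                trial=trial,
                log_evidence=evidence,
                posterior_marginals=posterior,
                joint_map=map_tuple,
                joint_map_prob=map_prob,
                level1_priors=priors1,
                level1_bias=bias,
            )
        )
        prior = advance_epoch(posterior, model.level2_transitions, model.level2_space)
    return records
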