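"""Independent brute-force oracles used to check the variational machinery.

Everything here works by exhaustive enumeration of joint assignments, so it
is exact (up to float arithmetic) and shares no code path with the
package's message passing.
"""

from __future__ import annotations

import itertools

import numpy as np

from mazetalk.mdp import MDPModel, Policy


def enumerate_state_posterior(
    model: MDPModel,
    observations: list[dict[str, int]],
    policy: Policy,
    priors: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Exact smoothed marginals by summing over every joint state sequence."""
    space = model.space
    names = space.names
    T = len(observations)
    sizes = [space.factor(f).n for f in names]

    per_factor_seqs = [list(itertools.product(range(n), repeat=T)) for n in sizes]
    marginals = {f: np.zeros((T, n)) for f, n in zip(names, sizes)}
    total = 0.0
    for joint in itertools.product(*per_factor_seqs):
        p = 1.0
        for fi, fname in enumerate(names):
            seq = joint[fi]
            p *= priors[fname][seq[0]]
            ctrl = space.factor(fname).controllable
            for t in range(1, T):
                a = policy.action_at(t).get(fname, 0) if ctrl else 0
                p *= model.transitions.table(fname, a)[seq[t], seq[t - 1]]
            if p == 0.0:
                break
        if p == 0.0:
            continue
        for t, obs in enumerate(observations):
            idx = tuple(joint[fi][t] for fi in range(len(names)))
            for mod, o in obs.items():
                p *= model.likelihood[mod].table.table[(o, *idx)]
            if p == 0.0:
                break
        if p == 0.0:
            continue
        total += p
        for fi, fname in enumerate(names):
            for t in range(T):
                marginals[fname][t, joint[fi][t]] += p
    if total <= 0.0:
        raise ValueError("observations impossible under the model")
    for fname in names:
        marginals[fname] /= total
    return marginals


def enumerate_expectation(table: np.ndarray, marginals: list[np.ndarray]) -> np.ndarray:
    """E[P(o | parents)] by summing over every parent tuple."""
    out = np.zeros(table.shape[0])
    for idx in itertools.product(*(range(n) for n in table.shape[1:])):
        w = 1.0
        for m, i in zip(marginals, idx):
            w *= m[i]
        out += w * table[(slice(None), *idx)]
    return out


def enumerate_two_move_sequences() -> set[tuple[int, int]]:
    """All two-move maze trajectories from the centre, arms absorbing.

    Locations: 0 centre, 1 left arm, 2 right arm, 3 cue; a move targets a
    location, but from an arm every move stays put.
    """
    arms = {1, 2}

    def step(loc: int, target: int) -> int:
        return loc if loc in arms else target

    seqs = set()
    for a1 in range(4):
        for a2 in range(4):
            l1 = step(0, a1)
            l2 = step(l1, a2)
            # identify a policy by the locations it actually visits
            seqs.add((l1, l2))
    return seqs


def random_single_factor_model(rng: np.random.Generator):
    """A random 1-factor chain model (<= 3 states/observations/steps)."""
    from mazetalk.categorical import ConditionalTable
    from mazetalk.mdp import (
        Factor,
        LikelihoodModel,
        Modality,
        Preferences,
        StateSpace,
        TransitionModel,
    )

    n_s = int(rng.integers(2, 4))
    n_o = int(rng.integers(2, 4))
    T = int(rng.integers(1, 4))

    def stoch(shape):
        m = rng.random(shape) + 0.05
        return m / m.sum(axis=0, keepdims=True)

    a = stoch((n_o, n_s))
    b = stoch((n_s, n_s))[None]
    prior = stoch((n_s,))
    model = MDPModel(
        space=StateSpace((Factor("s", tuple(f"s{i}" for i in range(n_s))),)),
        likelihood=LikelihoodModel(
            (Modality("o", tuple(f"o{i}" for i in range(n_o)), ConditionalTable(a)),)
        ),
        transitions=TransitionModel({"s": b}),
        preferences=Preferences({"o": np.zeros(n_o)}),
        policies=(Policy(({},)),),
    )
    obs = [{"o": int(rng.integers(0, n_o))} for _ in range(T)]
    return model, obs, prior, T
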