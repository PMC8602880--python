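"""Exact categorical probability primitives.

Everything downstream — state inference, expected free energy, the
hierarchical links — is built from four operations on discrete
distributions: normalisation, softmax, KL divergence and entropy, plus
mean-field expectations of conditional tables under per-factor marginals.

Conventions
-----------
* Probability vectors are 1-D ``numpy`` arrays summing to one within
  ``PROB_TOL``.
* Logarithms of model parameters are guarded as ``ln(x + LOG_EPS)`` so that
  structural zeros stay finite; entropy and KL use the exact ``0 ln 0 = 0``
  convention so that closed-form identities (zero entropy of a delta, zero
  KL between identical distributions, zero ambiguity of a deterministic
  likelihood) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOG_EPS",
    "PROB_TOL",
    "Categorical",
    "ConditionalTable",
    "DegenerateInputError",
    "ShapeError",
    "entropy",
    "expect_over_factors",
    "guarded_log",
    "kl_divergence",
    "normalize",
    "softmax",
]

#: additive guard inside logs of model parameters (keeps KL finite for
#: structural zeros)
LOG_EPS = 1e-16

#: tolerance for "sums to one" invariant checks
PROB_TOL = 1e-10

#: two categorical values closer than this are treated as tied (ties break
#: to the lowest index, for reproducibility)
TIE_TOL = 1e-12


class DegenerateInputError(ValueError):
    """Raised when an operation receives an all-zero / all-excluded input."""


class ShapeError(ValueError):
    """Raised when distribution or table shapes are incompatible."""


def guarded_log(x: np.ndarray | float) -> np.ndarray:
    """``ln(x + LOG_EPS)`` — the guarded logarithm used on model tables."""
    return np.log(np.asarray(x, dtype=float) + LOG_EPS)


@dataclass(frozen=True)
class Categorical:
    """A distribution over the levels of one labelled discrete variable."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1:
            raise ShapeError(f"Categorical must be 1-D, got shape {p.shape}")
        if np.any(p < -PROB_TOL):
            raise ValueError("Categorical entries must be non-negative")
        if abs(p.sum() - 1.0) > PROB_TOL:
            raise ValueError(f"Categorical entries sum to {p.sum()!r}, not 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def argmax(self) -> int:
        """Index of the largest entry; ties (within TIE_TOL) break low."""
        return tie_break_argmax(self.probs)


def tie_break_argmax(values: np.ndarray) -> int:
    """Lowest index attaining the maximum, treating near-ties as exact."""
    v = np.asarray(values, dtype=float)
    return int(np.flatnonzero(v >= v.max() - TIE_TOL)[0])


def normalize(weights: np.ndarray) -> Categorical:
    """Scale non-negative weights into a probability vector."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("normalize requires non-negative weights")
    total = w.sum()
    if total <= 0.0:
        raise DegenerateInputError("cannot normalize an all-zero vector")
    return Categorical(w / total)


def softmax(log_weights: np.ndarray) -> Categorical:
    """exp-then-normalise; invariant to adding a constant.

    Entries of ``-inf`` mean "excluded option"; an all ``-inf`` input is
    degenerate.
    """
    lw = np.asarray(log_weights, dtype=float)
    if np.any(np.isnan(lw)) or np.any(lw == np.inf):
        raise ValueError("softmax requires entries in [-inf, inf)")
    m = lw.max()
    if m == -np.inf:
        raise DegenerateInputError("softmax of all -inf weights")
    w = np.exp(lw - m)
    return Categorical(w / w.sum())


def _as_probs(p: Categorical | np.ndarray) -> np.ndarray:
    return p.probs if isinstance(p, Categorical) else np.asarray(p, dtype=float)


def kl_divergence(p: Categorical | np.ndarray, q: Categorical | np.ndarray) -> float:
    """KL(p || q) = sum p (ln p - ln q), exactly zero when p == q.

    Entries where q is structurally zero but p is not are scored against the
    LOG_EPS guard, keeping the divergence finite.
    """
    pv, qv = _as_probs(p), _as_probs(q)
    if pv.shape != qv.shape:
        raise ShapeError(f"KL shapes differ: {pv.shape} vs {qv.shape}")
    mask = pv > 0
    q_safe = np.where(qv > 0, qv, LOG_EPS)
    return float(np.sum(pv[mask] * (np.log(pv[mask]) - np.log(q_safe[mask]))))


def entropy(p: Categorical | np.ndarray) -> float:
    """Shannon entropy -sum p ln p with the 0 ln 0 = 0 convention."""
    pv = _as_probs(p)
    mask = pv > 0
    return float(-np.sum(pv[mask] * np.log(pv[mask])))


@dataclass(frozen=True)
class ConditionalTable:
    """P(outcome | parents): axis 0 is the outcome, the rest are parents.

    Every parent tuple's outcome column must itself be a valid Categorical.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", t)
        if t.ndim < 1:
            raise ShapeError("ConditionalTable needs at least an outcome axis")
        if np.any(t < -PROB_TOL):
            raise ValueError("ConditionalTable entries must be non-negative")
        sums = t.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=PROB_TOL, rtol=0.0):
            raise ValueError("ConditionalTable columns must sum to 1")

    @property
    def n_outcomes(self) -> int:
        return self.table.shape[0]

    @property
    def parent_shape(self) -> tuple[int, ...]:
        return self.table.shape[1:]

    def column(self, parents: tuple[int, ...]) -> Categorical:
        """The outcome distribution for one fully specified parent tuple."""
        return Categorical(self.table[(slice(None), *parents)])


def expect_over_factors(
    table: ConditionalTable | np.ndarray,
    marginals: list[Categorical | np.ndarray],
) -> Categorical:
    """Average a conditional table under a product of factor marginals.

    Implements the mean-field expectation E_{prod_f q(s_f)}[P(o | s)] by
    contracting each parent axis with its marginal.
    """
    t = table.table if isinstance(table, ConditionalTable) else np.asarray(table, float)
    if t.ndim - 1 != len(marginals):
        raise ShapeError(
            f"table has {t.ndim - 1} parent axes but {len(marginals)} marginals given"
        )
    out = t
    for m in reversed(marginals):
        mv = _as_probs(m)
        if out.shape[-1] != mv.shape[0]:
            raise ShapeError(
                f"marginal of size {mv.shape[0]} does not match parent axis "
                f"of size {out.shape[-1]}"
            )
        out = out @ mv
    return Categorical(out)


def contract_with_marginals(
    tensor: np.ndarray, marginals: list[Categorical | np.ndarray]
) -> float:
    """E_{prod_f q(s_f)}[tensor] for a tensor indexed by all factors."""
    out = np.asarray(tensor, dtype=float)
    if out.ndim != len(marginals):
        raise ShapeError("tensor rank does not match number of marginals")
    for m in reversed(marginals):
        out = out @ _as_probs(m)
    return float(out)
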