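"""Single-individual choice probabilities under Bayesian estimation and
probability matching.

Each decision-maker estimates, from private (non-social) evidence and from the
behaviours of the other group members, the probability that option ``x`` is
the better of two (or more) options, and then *probability-matches*: it
chooses each option with probability equal to the estimated probability that
the option is best.  Under the independence assumption the posterior odds for
``x`` over ``y`` factorise into a non-social likelihood ratio ``a`` and a
social term ``S`` that is a product of per-behaviour reliability factors

    S = prod_k  s_k ** n_k,

where ``n_k`` counts the individuals currently displaying behaviour ``k`` and
``s_k`` is the behaviour's reliability: the probability the behaviour is
displayed when ``x`` is best divided by the probability it is displayed when
``y`` is best.  The choice probability is then

    P(go to x) = 1 / (1 + (a * S)**-1).

All functions here are pure and operate on scalars or small arrays; they are
composed into group-level processes by :mod:`shoalbayes.group_process`.

Probabilities are computed in log-odds form (``expit`` of a sum of log
factors) throughout, which is overflow-safe for arbitrarily large counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import (
    InfiniteReliabilityError,
    InvalidInputError,
    InvalidParameterError,
    SchemaError,
)

#: Smallest admissible positive parameter; values at or below this are
#: rejected rather than silently clipped, keeping log-domain arithmetic safe.
PARAM_FLOOR = 1e-12

#: Reliability value the stickleback data are best fit by (posterior odds
#: ratio of a conspecific's choice being correct vs mistaken).
DEFAULT_RELIABILITY = 2.5


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= PARAM_FLOOR:
        raise InvalidParameterError(
            f"parameter {name!r} must be positive and finite "
            f"(> {PARAM_FLOOR:g}), got {value!r}"
        )
    return value


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorClass:
    """A discrete behavioural class an observed individual can display.

    Parameters
    ----------
    label:
        Unique short identifier, e.g. ``"go-x"``, ``"go-y"``, ``"undecided"``.
    side:
        The option the behaviour commits to: ``"x"``, ``"y"`` or ``"none"``
        for non-choice behaviours such as indecision.
    """

    label: str
    side: str = "none"

    def __post_init__(self) -> None:
        if self.side not in ("x", "y", "none"):
            raise InvalidInputError(f"side must be x, y or none, got {self.side!r}")


@dataclass(frozen=True)
class ReliabilitySet:
    """Per-behaviour reliability factors with optional mirror pairing.

    ``reliabilities[label]`` is the likelihood ratio of observing the
    behaviour under "x is best" vs "y is best".  ``mirror`` maps a label to
    its side-swapped partner (e.g. ``go-x`` to ``go-y``); mirrored pairs must
    have reciprocal reliabilities, the symmetry the two-option set-up imposes.
    """

    reliabilities: Mapping[str, float]
    mirror: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, s in self.reliabilities.items():
            _check_positive(f"reliability[{label}]", s)
        for a, b in self.mirror.items():
            sa, sb = self.reliabilities[a], self.reliabilities[b]
            if abs(sa * sb - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"mirrored behaviours {a!r}/{b!r} must have reciprocal "
                    f"reliabilities, got {sa} and {sb}"
                )

    def __getitem__(self, label: str) -> float:
        return self.reliabilities[label]


@dataclass(frozen=True)
class SocialState:
    """Counts of individuals per behavioural class seen by a focal decider."""

    counts: Mapping[str, int]
    group_size: int | None = None

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise InvalidInputError(
                    f"count for {label!r} must be a non-negative integer, got {n!r}"
                )
        if self.group_size is not None:
            total = sum(self.counts.values())
            if total > self.group_size - 1:
                raise InvalidInputError(
                    f"{total} observed deciders exceed the N-1 = "
                    f"{self.group_size - 1} visible to a focal individual"
                )

    def delta_n(self, x_label: str = "go-x", y_label: str = "go-y") -> int:
        """Difference between committed counts, n_x - n_y."""
        return self.counts.get(x_label, 0) - self.counts.get(y_label, 0)


# ---------------------------------------------------------------------------
# Core posterior / choice probabilities
# ---------------------------------------------------------------------------


def posterior_best(a: float, rel: ReliabilitySet | Mapping[str, float],
                   state: SocialState | Mapping[str, int]) -> float:
    """Posterior probability that option ``x`` is best (= choice probability).

    Computes ``1 / (1 + (a * S)**-1)`` with ``S = prod_k s_k**n_k``.  Under
    probability matching this is also the probability of choosing ``x``.

    Parameters
    ----------
    a:
        Non-social likelihood ratio for ``x`` over ``y`` (1 when the set-up
        is symmetric).
    rel:
        Reliability per behaviour label.
    state:
        Observed counts per behaviour label; every label present must have a
        reliability entry.
    """
    a = _check_positive("a", a)
    rels = rel.reliabilities if isinstance(rel, ReliabilitySet) else rel
    counts = state.counts if isinstance(state, SocialState) else state
    log_odds = math.log(a)
    for label, n in counts.items():
        if label not in rels:
            raise SchemaError(f"behaviour {label!r} has no reliability entry")
        if n < 0:
            raise InvalidInputError(f"negative count for behaviour {label!r}")
        s = _check_positive(f"reliability[{label}]", rels[label])
        log_odds += n * math.log(s)
    return float(expit(log_odds))


def follow_prob_symmetric(s: float, delta_n) -> float:
    """Probability of choosing ``x`` in a symmetric two-option set-up.

    The sigmoid ``1 / (1 + s**(-delta_n))`` of the committed-count difference
    ``delta_n = n_x - n_y``; ``s`` is the conspecific reliability.  Accepts
    scalar or array ``delta_n``.
    """
    s = _check_positive("s", s)
    out = expit(np.asarray(delta_n, dtype=float) * math.log(s))
    return float(out) if out.ndim == 0 else out


def choice_prob_two_replicas(s: float, rho: float, delta_n_fish: int,
                             attractive_side: str = "x") -> float:
    """Choice probability with one attractive and one plain replica.

    Two modified replicas sit on opposite sides; only their reliability
    *ratio* ``rho = s_r / s_R`` (less- over more-attractive) is identifiable.
    With the attractive replica at ``x``:

        P(go to x) = 1 / (1 + rho * s**(-delta_n_fish)),

    where ``delta_n_fish`` counts real fish only.  ``rho < 1`` pulls the
    decision toward the attractive replica's side; ``rho = 1`` recovers the
    plain symmetric rule.
    """
    s = _check_positive("s", s)
    rho = _check_positive("rho", rho)
    if attractive_side not in ("x", "y"):
        raise InvalidInputError(f"attractive_side must be 'x' or 'y', got {attractive_side!r}")
    sign = 1.0 if attractive_side == "x" else -1.0
    return float(expit(delta_n_fish * math.log(s) - sign * math.log(rho)))


def choice_prob_asymmetric(a: float, s: float, delta_n: int) -> float:
    """Choice probability when the two sites differ (e.g. predator at one).

    ``1 / (1 + a**-1 * s**(-delta_n))``; replicas are pooled into the counts,
    as fish follow replicas as much as real fish.
    """
    a = _check_positive("a", a)
    s = _check_positive("s", s)
    return float(expit(math.log(a) + delta_n * math.log(s)))


def choice_prob_asymmetric_full(a: float, s_x: float, s_y: float, s_u: float,
                                n_x: int, n_y: int, n_u: int = 0) -> float:
    """Asymmetric rule with side-specific and indecision reliabilities.

    ``1 / (1 + a**-1 * s_x**(-n_x) * s_y**(n_y) * s_u**(-n_u))``.  Setting
    ``s_x = s_y = s`` and ``s_u = 1`` recovers :func:`choice_prob_asymmetric`.
    The indecision reliability ``s_u`` defaults to uninformative (1) in the
    rest of the package: model comparison rejects it on the fish data.
    """
    a = _check_positive("a", a)
    s_x = _check_positive("s_x", s_x)
    s_y = _check_positive("s_y", s_y)
    s_u = _check_positive("s_u", s_u)
    for name, n in (("n_x", n_x), ("n_y", n_y), ("n_u", n_u)):
        if n < 0:
            raise InvalidInputError(f"{name} must be non-negative, got {n}")
    log_odds = (math.log(a) + n_x * math.log(s_x) - n_y * math.log(s_y)
                + n_u * math.log(s_u))
    return float(expit(log_odds))


def choice_prob_fish_replica(a: float, s_f: float, s_rep: float,
                             delta_n_fish: int, delta_n_replica: int) -> float:
    """Choice probability with distinct reliabilities for fish and replicas.

    ``1 / (1 + a**-1 * s_f**(-dn_fish) * s_rep**(-dn_replica))``; with
    ``s_f = s_rep`` it reduces to :func:`choice_prob_asymmetric` on the
    pooled count difference.
    """
    a = _check_positive("a", a)
    s_f = _check_positive("s_f", s_f)
    s_rep = _check_positive("s_rep", s_rep)
    log_odds = (math.log(a) + delta_n_fish * math.log(s_f)
                + delta_n_replica * math.log(s_rep))
    return float(expit(log_odds))


def choice_prob_multi(s: float, counts: Sequence[int],
                      weights: Sequence[float] | None = None) -> np.ndarray:
    """Choice probabilities over ``n >= 2`` options.

    ``P_i = w_i * s**c_i / sum_j w_j * s**c_j`` with per-option non-social
    weights ``w`` (all ones by default).  For two options with unit weights
    this is :func:`follow_prob_symmetric` of the count difference.
    """
    s = _check_positive("s", s)
    c = np.asarray(counts)
    if c.ndim != 1 or c.size < 2:
        raise InvalidInputError("counts must be a vector of length >= 2")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
        raise InvalidInputError("counts must be non-negative integers")
    if weights is None:
        logw = np.zeros(c.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != c.shape:
            raise InvalidInputError("weights must match counts in length")
        if np.any(w <= PARAM_FLOOR) or not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be positive and finite")
        logw = np.log(w)
    logits = logw + c * math.log(s)
    logits -= logits.max()  # shift for overflow safety
    p = np.exp(logits)
    return p / p.sum()


def reliability_from_rates(p_correct: float, p_incorrect: float) -> float:
    """Reliability as the ratio of correct-choice to mistake probability.

    A conspecific that goes to the better side with probability 0.625 and to
    the worse side with probability 0.25 has reliability 2.5: its choice is
    2.5 times likelier when correct than when mistaken.
    """
    if not (0.0 < p_correct < 1.0):
        raise InvalidInputError(f"p_correct must be in (0, 1), got {p_correct!r}")
    if p_incorrect == 0.0:
        raise InfiniteReliabilityError(
            "p_incorrect = 0 implies infinite reliability; refusing to cap"
        )
    if not (0.0 < p_incorrect < 1.0):
        raise InvalidInputError(f"p_incorrect must be in (0, 1), got {p_incorrect!r}")
    return p_correct / p_incorrect


# ---------------------------------------------------------------------------
# Parameterised model wrapper
# ---------------------------------------------------------------------------

VARIANTS = (
    "symmetric",
    "two-replica",
    "asymmetric",
    "asymmetric-full",
    "fish-replica",
    "multi-option",
)

#: Free parameters read by each variant.
VARIANT_PARAMS = {
    "symmetric": ("s",),
    "two-replica": ("s", "rho"),
    "asymmetric": ("a", "s"),
    "asymmetric-full": ("a", "s_x", "s_y", "s_u"),
    "fish-replica": ("a", "s_f", "s_rep"),
    "multi-option": ("s",),
}


@dataclass(frozen=True)
class DecisionModel:
    """An individual decision rule: a variant tag plus its parameters.

    The group-level machinery calls :meth:`prob_x` with the focal
    individual's view of the current state; the variant decides which counts
    and parameters enter the log-odds.
    """

    variant: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidParameterError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        missing = [p for p in VARIANT_PARAMS[self.variant] if p not in self.params]
        if missing:
            raise InvalidParameterError(
                f"variant {self.variant!r} requires parameters {missing}"
            )
        for name in VARIANT_PARAMS[self.variant]:
            _check_positive(name, self.params[name])

    def replace(self, **updates: float) -> "DecisionModel":
        """Return a copy with some parameters replaced (used by fitting)."""
        new = dict(self.params)
        new.update(updates)
        return DecisionModel(self.variant, new)

    def prob_x(self, n_fish_x: int, n_fish_y: int, n_rep_x: int = 0,
               n_rep_y: int = 0, n_undecided: int = 0,
               attractive_side: str = "x") -> float:
        """Probability that the focal individual goes to ``x``."""
        p = self.params
        if self.variant == "symmetric":
            return follow_prob_symmetric(
                p["s"], (n_fish_x + n_rep_x) - (n_fish_y + n_rep_y))
        if self.variant == "two-replica":
            return choice_prob_two_replicas(
                p["s"], p["rho"], n_fish_x - n_fish_y, attractive_side)
        if self.variant == "asymmetric":
            return choice_prob_asymmetric(
                p["a"], p["s"], (n_fish_x + n_rep_x) - (n_fish_y + n_rep_y))
        if self.variant == "asymmetric-full":
            return choice_prob_asymmetric_full(
                p["a"], p["s_x"], p["s_y"], p["s_u"],
                n_fish_x + n_rep_x, n_fish_y + n_rep_y, n_undecided)
        if self.variant == "fish-replica":
            return choice_prob_fish_replica(
                p["a"], p["s_f"], p["s_rep"],
                n_fish_x - n_fish_y, n_rep_x - n_rep_y)
        raise InvalidParameterError(
            f"variant {self.variant!r} is not a two-option rule")
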