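"""Recursive decision model that keeps track of decision-order dependencies.

The independence model treats the behaviours of previous deciders as
conditionally independent given which option is best.  Here the focal
individual instead evaluates the *ordered sequence* of prior decisions,
modelling every earlier decider as a Bayesian probability-matcher itself:
the t-th decider is assumed to have seen the sequence up to t-1 and to carry
a private bias ``a_dep`` toward the best option (its reciprocal under the
opposite hypothesis).  Each observed decision then multiplies the focal
individual's posterior odds by the likelihood ratio

    r_t = p_t(b_t | x best) / p_t(b_t | y best),

and the running product ``S`` replaces the count-based social term.  Two
histories with identical head-counts can carry different evidence, which is
what produces minority following: after a long run toward one side, a lone
dissenter is highly informative.

The recursion has exactly as many free parameters as the corresponding
independence model: one ``a_dep`` per actor type (all real fish share one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .decision_core import _check_positive
from .errors import InvalidInputError, InvalidParameterError, SchemaError

#: Actor-type label used for real group members.
FISH = "fish"

#: Hard cap on exact path enumeration for initial states (orderings grow
#: factorially; beyond this an error is raised rather than approximating).
MAX_INITIAL_DECIDERS = 12

Decision = tuple[str, str]  # (actor_type, "go-x" | "go-y")


def _check_behavior(behavior: str) -> str:
    if behavior not in ("go-x", "go-y"):
        raise InvalidInputError(
            f"dependency sequences contain only choice behaviours, got {behavior!r}"
        )
    return behavior


@dataclass(frozen=True)
class AssumedBias:
    """Per-actor-type assumed non-social bias toward the best option.

    Under the hypothesis "x is best" an actor of this type is assumed to
    carry non-social evidence ``a_dep`` for x; under "y is best" the
    reciprocal.  This single reciprocal constraint keeps the symmetric model
    at one parameter.
    """

    a_dep: float

    def __post_init__(self) -> None:
        _check_positive("a_dep", self.a_dep)


@dataclass(frozen=True)
class RecursiveState:
    """Running social term after ``t`` observed decisions; S = 1 at t = 0."""

    S: float = 1.0
    t: int = 0

    def __post_init__(self) -> None:
        if not (self.S > 0.0 and math.isfinite(self.S)):
            raise InvalidInputError(f"social term S must be positive, got {self.S!r}")


def _bias_of(biases, actor_type: str) -> float:
    if isinstance(biases, (int, float)):
        return _check_positive("a_dep", biases)
    if isinstance(biases, AssumedBias):
        return biases.a_dep
    try:
        entry = biases[actor_type]
    except (KeyError, TypeError):
        raise SchemaError(f"no assumed bias for actor type {actor_type!r}")
    return entry.a_dep if isinstance(entry, AssumedBias) else _check_positive(
        f"a_dep[{actor_type}]", entry)


def step_probabilities(state: RecursiveState | float,
                       actor_bias: AssumedBias | float) -> tuple[float, float]:
    """Probability the next decider goes to x, under each hypothesis.

    Returns ``(p(go-x | x best), p(go-x | y best))``.  Under "x best" the
    actor's assumed bias multiplies the running social term S; under
    "y best" its reciprocal does.
    """
    S = state.S if isinstance(state, RecursiveState) else float(state)
    if not (S > 0.0 and math.isfinite(S)):
        raise InvalidInputError(f"social term S must be positive, got {S!r}")
    a = actor_bias.a_dep if isinstance(actor_bias, AssumedBias) else float(actor_bias)
    _check_positive("a_dep", a)
    log_s = math.log(S)
    p_x_given_x = float(expit(math.log(a) + log_s))
    p_x_given_y = float(expit(-math.log(a) + log_s))
    return p_x_given_x, p_x_given_y


def sequence_social_term(seq: Sequence[Decision | str],
                         biases: Mapping[str, AssumedBias] | float) -> RecursiveState:
    """Fold a decision sequence into its social term.

    ``seq`` holds ``(actor_type, behaviour)`` pairs (a bare behaviour string
    is shorthand for a real fish).  At each step the likelihood ratio of the
    observed behaviour under the two hypotheses multiplies S.  The fold is
    order-sensitive: permuted sequences generally yield different S.
    """
    S = 1.0
    t = 0
    for item in seq:
        if isinstance(item, str):
            actor_type, behavior = FISH, item
        else:
            actor_type, behavior = item
        _check_behavior(behavior)
        a = _bias_of(biases, actor_type)
        p_x_X, p_x_Y = step_probabilities(S, a)
        if behavior == "go-x":
            r = p_x_X / p_x_Y
        else:
            r = (1.0 - p_x_X) / (1.0 - p_x_Y)
        S *= r
        t += 1
    return RecursiveState(S=S, t=t)


def decision_prob_with_dependencies(
        seq: Sequence[Decision | str],
        focal_nonsocial: float = 1.0,
        biases: Mapping[str, AssumedBias] | float = 1.0,
        initial_S: float = 1.0) -> float:
    """Probability the focal individual goes to x after observing ``seq``.

    The focal individual uses its *actual* non-social term (1 in symmetric
    set-ups) with the sequence's social term: ``1 / (1 + (a * S)**-1)``.
    ``initial_S`` carries evidence from a pre-existing configuration (see
    :func:`initial_state_term`).
    """
    a = _check_positive("focal_nonsocial", focal_nonsocial)
    if not (initial_S > 0.0 and math.isfinite(initial_S)):
        raise InvalidInputError("initial_S must be positive")
    state = sequence_social_term(seq, biases)
    return float(expit(math.log(a) + math.log(initial_S * state.S)))


def initial_state_term(initial_counts: Mapping[str, tuple[int, int]] | Sequence[Decision],
                       biases: Mapping[str, AssumedBias] | float,
                       weighting: str = "probability") -> RecursiveState:
    """Social term for an initial configuration of unknown decision order.

    Experiments often start with replicas already committed; the fish cannot
    know in which order that configuration arose.  All orderings consistent
    with the counts are enumerated, each path's S computed by
    :func:`sequence_social_term`, and the paths averaged.

    Parameters
    ----------
    initial_counts:
        Either a mapping ``{actor_type: (n_x, n_y)}`` or an explicit list of
        decisions whose multiset defines the configuration.
    weighting:
        ``"probability"`` (default) weights each ordering by its probability
        under the hypothesis-symmetric marginal (mean of the x-best and
        y-best path probabilities); ``"uniform"`` averages orderings equally.
    """
    if weighting not in ("probability", "uniform"):
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    if isinstance(initial_counts, Mapping):
        decisions: list[Decision] = []
        for actor_type, (n_x, n_y) in initial_counts.items():
            if n_x < 0 or n_y < 0:
                raise InvalidInputError("initial counts must be non-negative")
            decisions += [(actor_type, "go-x")] * n_x + [(actor_type, "go-y")] * n_y
    else:
        decisions = [(FISH, d) if isinstance(d, str) else tuple(d)
                     for d in initial_counts]
    if len(decisions) > MAX_INITIAL_DECIDERS:
        raise InvalidInputError(
            f"exact path averaging supports at most {MAX_INITIAL_DECIDERS} "
            f"initial deciders, got {len(decisions)}"
        )
    if not decisions:
        return RecursiveState()
    orderings = set(permutations(decisions))
    total_w = 0.0
    total_wS = 0.0
    for order in orderings:
        S = 1.0
        prob_X = 1.0  # path probability under "x is best"
        prob_Y = 1.0
        for actor_type, behavior in order:
            _check_behavior(behavior)
            a = _bias_of(biases, actor_type)
            p_x_X, p_x_Y = step_probabilities(S, a)
            if behavior == "go-x":
                r, pX, pY = p_x_X / p_x_Y, p_x_X, p_x_Y
            else:
                r, pX, pY = (1 - p_x_X) / (1 - p_x_Y), 1 - p_x_X, 1 - p_x_Y
            prob_X *= pX
            prob_Y *= pY
            S *= r
        w = 0.5 * (prob_X + prob_Y) if weighting == "probability" else 1.0
        total_w += w
        total_wS += w * S
    return RecursiveState(S=total_wS / total_w, t=len(decisions))


@dataclass(frozen=True)
class DependencyModel:
    """Group decision model with order-dependent social information.

    Parameters
    ----------
    a_dep:
        Assumed bias for real fish.
    replica_biases:
        Assumed bias per replica type label (each replica type may be more
        or less attractive than a real fish).
    a_focal:
        The focal individuals' actual non-social term (1 when symmetric).
    """

    a_dep: float
    replica_biases: Mapping[str, float] = field(default_factory=dict)
    a_focal: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("a_dep", self.a_dep)
        _check_positive("a_focal", self.a_focal)
        for label, b in self.replica_biases.items():
            _check_positive(f"a_dep[{label}]", b)

    @property
    def biases(self) -> dict[str, float]:
        return {FISH: self.a_dep, **self.replica_biases}

    def n_parameters(self) -> int:
        """Free parameters: one bias per actor type (plus a if asymmetric)."""
        k = 1 + len(self.replica_biases)
        if self.a_focal != 1.0:
            k += 1
        return k


def expected_follow_curve(model: DependencyModel | float, group_size: int):
    """Occupancy-weighted next-choice probability as a function of Δn.

    Enumerates every reachable decision sequence of real fish starting from
    the empty state, records each state's next-decision probability
    ``P(go-x)`` and its occupancy probability, and bins states by
    ``delta_n = n_x - n_y``.

    Returns
    -------
    dict mapping ``delta_n`` to ``(mean_probability, [(p, weight), ...])``
    where the mean is occupancy-weighted over states with that Δn.
    """
    if isinstance(model, (int, float)):
        model = DependencyModel(a_dep=float(model))
    if group_size < 2:
        raise InvalidInputError("group_size must be >= 2")
    # frontier: list of (S, delta_n, occupancy probability)
    frontier = [(1.0, 0, 1.0)]
    records: dict[int, list[tuple[float, float]]] = {}
    for _ in range(group_size):
        nxt = []
        for S, dn, w in frontier:
            p_x = float(expit(math.log(model.a_focal) + math.log(S)))
            records.setdefault(dn, []).append((p_x, w))
            p_x_X, p_x_Y = step_probabilities(S, model.a_dep)
            S_x = S * (p_x_X / p_x_Y)
            S_y = S * ((1 - p_x_X) / (1 - p_x_Y))
            nxt.append((S_x, dn + 1, w * p_x))
            nxt.append((S_y, dn - 1, w * (1 - p_x)))
        frontier = nxt
    curve = {}
    for dn, entries in sorted(records.items()):
        total_w = sum(w for _, w in entries)
        mean = sum(p * w for p, w in entries) / total_w
        curve[dn] = (mean, entries)
    return curve
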