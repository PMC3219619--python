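"""Group-level outcome distributions from an individual decision rule.

Group behaviour is obtained by applying the individual rule *sequentially*:
one individual decides, the counts (or the decision sequence) are updated,
and the next individual decides with the refreshed social information.
Replicas are forced deciders — they contribute to the social state but never
to the randomness — and the final configuration records only the real fish.

Two routes are provided: exact enumeration of the decision tree (leaf
probabilities over final configurations) and seeded Monte-Carlo simulation.
For independence models the tree collapses over count-equivalent states, so
enumeration is a small dynamic programme; for the dependency model distinct
histories are distinct nodes and the tree is enumerated in full.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .decision_core import DecisionModel
from .dependency_model import (
    FISH,
    DependencyModel,
    initial_state_term,
    step_probabilities,
)
from .errors import CapacityError, InvalidInputError

#: Exact-enumeration limits.
MAX_N_COUNT_STATE = 20
MAX_N_SEQUENCE_STATE = 12


@dataclass(frozen=True)
class ExperimentConfig:
    """One experimental condition.

    Parameters
    ----------
    group_size:
        Number of real fish that decide (N).
    replicas:
        Replica placements as ``(type_label, side)`` pairs, in the order the
        replicas were moved; sides are ``"x"`` or ``"y"``.
    asymmetry:
        The focal non-social term ``a`` (1 for symmetric designs).
    options:
        Number of options (2 for all stickleback designs).
    initial_fish:
        Fish already committed at the start, as ``(n_x, n_y)``.
    """

    group_size: int
    replicas: tuple[tuple[str, str], ...] = ()
    asymmetry: float = 1.0
    options: int = 2
    initial_fish: tuple[int, int] = (0, 0)
    condition_id: str = ""

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise InvalidInputError("group_size must be >= 1")
        if self.options < 2:
            raise InvalidInputError("options must be >= 2")
        for label, side in self.replicas:
            if side not in ("x", "y"):
                raise InvalidInputError(f"replica side must be x or y, got {side!r}")
        if any(n < 0 for n in self.initial_fish):
            raise InvalidInputError("initial fish counts must be non-negative")

    @property
    def n_rep_x(self) -> int:
        return sum(1 for _, side in self.replicas if side == "x")

    @property
    def n_rep_y(self) -> int:
        return sum(1 for _, side in self.replicas if side == "y")

    @property
    def attractive_side(self) -> str:
        """Side of the more attractive replica in a two-replica design.

        By convention the first listed replica is the more attractive one.
        """
        return self.replicas[0][1] if self.replicas else "x"


@dataclass(frozen=True)
class OutcomeDistribution:
    """Distribution (or counts) over final configurations k fish at x."""

    group_size: int
    probabilities: np.ndarray  # length N+1, index = k fish at x
    provenance: str = "exact"
    counts: np.ndarray | None = None
    condition_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.group_size + 1,):
            raise InvalidInputError("probabilities must have length N + 1")
        if self.provenance == "exact" and abs(p.sum() - 1.0) > 1e-10:
            raise InvalidInputError("exact probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.group_size + 1)


@dataclass
class StateTree:
    """Explicit decision tree: nodes are states, edges carry probabilities."""

    nodes: dict[object, float] = field(default_factory=dict)  # node -> reach prob
    edges: list[tuple[object, object, float]] = field(default_factory=list)
    leaves: dict[object, float] = field(default_factory=dict)

    def to_edge_records(self) -> list[dict]:
        return [{"parent": str(p), "child": str(c), "probability": w}
                for p, c, w in self.edges]


def _stepper(model: DecisionModel, config: ExperimentConfig):
    """Return f(n_fish_x, n_fish_y, n_decided) -> P(next fish goes to x)."""
    n_rep_x, n_rep_y = config.n_rep_x, config.n_rep_y
    side = config.attractive_side
    N = config.group_size

    def p_x(n_fish_x: int, n_fish_y: int) -> float:
        # undecided = fish still waiting for their turn, excluding the focal
        n_undecided = max(N - 1 - n_fish_x - n_fish_y, 0)
        return model.prob_x(n_fish_x, n_fish_y, n_rep_x, n_rep_y,
                            n_undecided, attractive_side=side)

    return p_x


def enumerate_outcomes(model: DecisionModel | DependencyModel,
                       config: ExperimentConfig) -> OutcomeDistribution:
    """Exact distribution over final configurations by tree enumeration.

    Replica decisions are consumed as given; the N real fish decide in
    sequence, each seeing the up-to-date state.  For independence models the
    enumeration is a dynamic programme over fish counts; for the dependency
    model every decision sequence is followed separately.
    """
    N = config.group_size
    if isinstance(model, DependencyModel):
        if N > MAX_N_SEQUENCE_STATE:
            raise CapacityError(
                f"dependency-model enumeration limited to N <= "
                f"{MAX_N_SEQUENCE_STATE}, got {N}")
        return _enumerate_dependency(model, config)
    if N > MAX_N_COUNT_STATE:
        raise CapacityError(
            f"count-state enumeration limited to N <= {MAX_N_COUNT_STATE}, got {N}")
    p_x = _stepper(model, config)
    fx0, fy0 = config.initial_fish
    # states keyed by fish-at-x count; fish-at-y implied by decided total
    probs = {(fx0, fy0): 1.0}
    n_free = N - fx0 - fy0
    if n_free < 0:
        raise InvalidInputError("initial fish exceed group size")
    for _ in range(n_free):
        nxt: dict[tuple[int, int], float] = {}
        for (nx, ny), w in probs.items():
            p = p_x(nx, ny)
            nxt[(nx + 1, ny)] = nxt.get((nx + 1, ny), 0.0) + w * p
            nxt[(nx, ny + 1)] = nxt.get((nx, ny + 1), 0.0) + w * (1.0 - p)
        probs = nxt
    out = np.zeros(N + 1)
    for (nx, ny), w in probs.items():
        out[nx] += w
    return OutcomeDistribution(N, out, provenance="exact",
                               condition_id=config.condition_id)


def _dependency_initial_S(model: DependencyModel, config: ExperimentConfig) -> float:
    """Social term carried by the pre-committed replicas (path-averaged)."""
    if not config.replicas:
        return 1.0
    counts: dict[str, list[int]] = {}
    for label, side in config.replicas:
        c = counts.setdefault(label, [0, 0])
        c[0 if side == "x" else 1] += 1
    mapping = {label: tuple(c) for label, c in counts.items()}
    biases = model.biases
    for label in mapping:
        if label not in biases:
            biases[label] = model.a_dep  # unmodified replicas read as fish
    return initial_state_term(mapping, biases).S


def _enumerate_dependency(model: DependencyModel,
                          config: ExperimentConfig) -> OutcomeDistribution:
    N = config.group_size
    S0 = _dependency_initial_S(model, config)
    frontier = [(S0, 0, 1.0)]  # (S, n_fish_x, reach probability)
    log_a = math.log(model.a_focal * config.asymmetry)
    for _ in range(N):
        nxt = []
        for S, nx, w in frontier:
            p = float(expit(log_a + math.log(S)))
            p_x_X, p_x_Y = step_probabilities(S, model.a_dep)
            nxt.append((S * p_x_X / p_x_Y, nx + 1, w * p))
            nxt.append((S * (1 - p_x_X) / (1 - p_x_Y), nx, w * (1 - p)))
        frontier = nxt
    out = np.zeros(N + 1)
    for S, nx, w in frontier:
        out[nx] += w
    return OutcomeDistribution(N, out, provenance="exact",
                               condition_id=config.condition_id)


def simulate_group(model: DecisionModel | DependencyModel,
                   config: ExperimentConfig, n_reps: int,
                   seed: int) -> OutcomeDistribution:
    """Sample ``n_reps`` independent sequential realizations (seeded).

    The empirical distribution converges to :func:`enumerate_outcomes` as
    ``n_reps`` grows.  Returns counts and the empirical probabilities.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    N = config.group_size
    counts = np.zeros(N + 1, dtype=np.int64)
    if isinstance(model, DependencyModel):
        S0 = _dependency_initial_S(model, config)
        log_a = math.log(model.a_focal * config.asymmetry)
        S = np.full(n_reps, S0)
        nx = np.zeros(n_reps, dtype=np.int64)
        for _ in range(N):
            p = expit(log_a + np.log(S))
            go_x = rng.random(n_reps) < p
            p_x_X = expit(np.log(model.a_dep) + np.log(S))
            p_x_Y = expit(-np.log(model.a_dep) + np.log(S))
            r = np.where(go_x, p_x_X / p_x_Y, (1 - p_x_X) / (1 - p_x_Y))
            S = S * r
            nx += go_x
        np.add.at(counts, nx, 1)
    else:
        p_x = _stepper(model, config)
        fx0, fy0 = config.initial_fish
        n_free = N - fx0 - fy0
        # probability lookup by (n_fish_x, n_fish_y); states are few
        nx = np.full(n_reps, fx0, dtype=np.int64)
        ny = np.full(n_reps, fy0, dtype=np.int64)
        cache: dict[tuple[int, int], float] = {}
        for _ in range(n_free):
            p = np.empty(n_reps)
            for key in set(zip(nx.tolist(), ny.tolist())):
                if key not in cache:
                    cache[key] = p_x(*key)
            for (a, b), val in cache.items():
                mask = (nx == a) & (ny == b)
                p[mask] = val
            go_x = rng.random(n_reps) < p
            nx += go_x
            ny += ~go_x
        np.add.at(counts, nx, 1)
    probs = counts / counts.sum()
    return OutcomeDistribution(N, probs,
                               provenance=f"sampled(n_reps={n_reps}, seed={seed})",
                               counts=counts, condition_id=config.condition_id)


def build_state_tree(model: DecisionModel | DependencyModel,
                     config: ExperimentConfig) -> StateTree:
    """Full decision tree with per-edge probabilities.

    Independence-model nodes are ``(n_fish_x, n_fish_y)`` count states
    (count-equivalent states collapse); dependency-model nodes are decision
    sequences, so equal counts with different histories stay distinct.  The
    marginal leaf distribution equals :func:`enumerate_outcomes`.
    """
    N = config.group_size
    tree = StateTree()
    if isinstance(model, DependencyModel):
        if N > MAX_N_SEQUENCE_STATE:
            raise CapacityError(
                f"dependency-model trees limited to N <= {MAX_N_SEQUENCE_STATE}")
        S0 = _dependency_initial_S(model, config)
        log_a = math.log(model.a_focal * config.asymmetry)
        frontier = [((), S0, 1.0)]
        tree.nodes[()] = 1.0
        for level in range(N):
            nxt = []
            for seq, S, w in frontier:
                p = float(expit(log_a + math.log(S)))
                p_x_X, p_x_Y = step_probabilities(S, model.a_dep)
                for behavior, edge_p, S_new in (
                        ("go-x", p, S * p_x_X / p_x_Y),
                        ("go-y", 1 - p, S * (1 - p_x_X) / (1 - p_x_Y))):
                    child = seq + (behavior,)
                    tree.nodes[child] = w * edge_p
                    tree.edges.append((seq, child, edge_p))
                    nxt.append((child, S_new, w * edge_p))
            frontier = nxt
        for seq, S, w in frontier:
            tree.leaves[seq] = w
    else:
        if N > MAX_N_COUNT_STATE:
            raise CapacityError(
                f"count-state trees limited to N <= {MAX_N_COUNT_STATE}")
        p_x = _stepper(model, config)
        fx0, fy0 = config.initial_fish
        level_states = {(fx0, fy0): 1.0}
        tree.nodes[(fx0, fy0)] = 1.0
        for _ in range(N - fx0 - fy0):
            nxt: dict[tuple[int, int], float] = {}
            for (nx, ny), w in level_states.items():
                p = p_x(nx, ny)
                for child, edge_p in (((nx + 1, ny), p), ((nx, ny + 1), 1 - p)):
                    nxt[child] = nxt.get(child, 0.0) + w * edge_p
                    tree.edges.append(((nx, ny), child, edge_p))
            for child, w in nxt.items():
                tree.nodes[child] = w
            level_states = nxt
        tree.leaves = dict(level_states)
    return tree
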