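"""Qualitative shape of final-configuration distributions.

The distribution of how many group members end at option x can be U-shaped
(mass piled at both extremes — strong herding), J-shaped (one extreme, a
biased start), M-shaped (twin peaks between centre and edges), or bell-shaped
(binomial-like, weak sociality).  Which shape is *seen* also depends on how
the proportion axis is binned: an M can masquerade as a U or a bell when the
binning is too coarse, which matters because real experiments rarely support
more than ~5 bins.

This module rebins exact outcome distributions onto a proportion axis,
classifies the shape with a tolerance-aware monotone-run analysis, maps the
shape regions over the (reliability, group size) plane, and tracks how the
shape evolves as successive individuals commit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decision_core import DecisionModel
from .errors import InvalidInputError
from .group_process import ExperimentConfig, OutcomeDistribution, enumerate_outcomes

#: Absolute tolerance on bin masses when comparing for monotonicity; exact
#: enumeration at s -> 1 produces exact ties, which must read as plateaus.
MASS_TOL = 1e-9

SHAPE_LABELS = ("U", "J", "M", "bell", "flat")


@dataclass(frozen=True)
class BinnedDistribution:
    """Masses aggregated into equal-width bins over proportion-at-x."""

    edges: np.ndarray  # length B+1, covers [0, 1]
    masses: np.ndarray  # length B

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        if e.ndim != 1 or m.ndim != 1 or e.size != m.size + 1:
            raise InvalidInputError("edges must have one more entry than masses")
        if np.any(np.diff(e) <= 0) or abs(e[0]) > 1e-12 or abs(e[-1] - 1) > 1e-12:
            raise InvalidInputError("edges must increase strictly and span [0, 1]")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "masses", m)

    @property
    def n_bins(self) -> int:
        return self.masses.size


def rebin(dist: OutcomeDistribution | np.ndarray, n_bins: int,
          group_size: int | None = None) -> BinnedDistribution:
    """Aggregate an outcome distribution into equal-width proportion bins.

    Outcome ``k`` of ``N`` lands at proportion ``k / N``; bins are half-open
    ``[l, r)`` with the last bin closed, so mass is conserved exactly.
    ``n_bins`` may not exceed the number of distinct outcomes (N + 1).
    """
    if isinstance(dist, OutcomeDistribution):
        probs = dist.probabilities
        N = dist.group_size
    else:
        probs = np.asarray(dist, dtype=float)
        N = (group_size if group_size is not None else probs.size - 1)
        if probs.size != N + 1:
            raise InvalidInputError("probability vector must have length N + 1")
    if not (2 <= n_bins <= N + 1):
        raise InvalidInputError(
            f"n_bins must lie in [2, N + 1] = [2, {N + 1}], got {n_bins}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    proportions = np.arange(N + 1) / N
    idx = np.minimum((proportions * n_bins).astype(int), n_bins - 1)
    masses = np.zeros(n_bins)
    np.add.at(masses, idx, probs)
    return BinnedDistribution(edges=edges, masses=masses)


def _collapsed_runs(masses: np.ndarray) -> list[int]:
    """Signs (+1/-1) of successive mass differences, plateaus dropped and
    consecutive equal signs merged."""
    diffs = np.diff(masses)
    signs = [0 if abs(d) <= MASS_TOL else (1 if d > 0 else -1) for d in diffs]
    runs: list[int] = []
    for sgn in signs:
        if sgn == 0:
            continue
        if not runs or runs[-1] != sgn:
            runs.append(sgn)
    return runs


def _center_indices(n_bins: int) -> tuple[int, ...]:
    if n_bins % 2:
        return (n_bins // 2,)
    return (n_bins // 2 - 1, n_bins // 2)


def classify_shape(binned: BinnedDistribution | Sequence[float]) -> str:
    """Classify a binned distribution as U, J, M, bell or flat.

    The masses are reduced to their sequence of monotone runs (with plateau
    tolerance :data:`MASS_TOL`); the run pattern decides the label:

    * no runs — flat;
    * single run — J (monotone toward one edge);
    * down-then-up with the valley at the centre — U; with the valley
      off-centre — J (a biased extremes-heavy distribution keeps a small
      hook at the minor edge, the classic J silhouette);
    * up-then-down — bell (single interior maximum);
    * up-down-up-down with both interior peaks above centre and edges — M;
    * anything else — flat (ambiguous).

    Plateau ties therefore break toward the simpler label (U or bell over M).
    """
    masses = binned.masses if isinstance(binned, BinnedDistribution) else \
        np.asarray(binned, dtype=float)
    runs = _collapsed_runs(masses)
    center = _center_indices(masses.size)
    center_min = min(masses[i] for i in center)
    if not runs:
        return "flat"
    if runs in ([1], [-1]):
        return "J"
    if runs == [-1, 1]:
        # central valley reads as U; an off-centre valley is a biased
        # extremes-heavy distribution, i.e. J with a hook
        if center_min <= masses.min() + MASS_TOL:
            return "U"
        return "J"
    if runs == [1, -1]:
        return "bell"
    if runs == [1, -1, 1, -1]:
        # locate the two peaks: maxima of the two rising runs
        diffs = np.diff(masses)
        peaks = []
        rising = False
        for i, d in enumerate(diffs):
            if d > MASS_TOL:
                rising = True
            elif d < -MASS_TOL and rising:
                peaks.append(i)
                rising = False
        edge_max = max(masses[0], masses[-1])
        if (len(peaks) == 2
                and all(masses[p] > center_min + MASS_TOL for p in peaks)
                and all(masses[p] > edge_max + MASS_TOL for p in peaks)):
            return "M"
        return "flat"
    return "flat"


def min_bins_for_M(probs: np.ndarray, group_size: int, max_bins: int) -> int | None:
    """Smallest bin count at which the distribution reads as M, if any."""
    for b in range(2, min(max_bins, group_size + 1) + 1):
        if classify_shape(rebin(probs, b, group_size)) == "M":
            return b
    return None


def phase_diagram(s_grid: Sequence[float], n_grid: Sequence[int],
                  max_bins: int | None = None):
    """Shape label over the (reliability, group size) plane.

    For each cell the symmetric model is enumerated from an empty start, the
    distribution classified at the finest admissible binning, and the minimum
    bin count at which an M shape is visible recorded (None if never).

    Returns a dict mapping ``(s, N)`` to ``(label, min_bins_for_M)``.
    """
    out = {}
    for N in n_grid:
        for s in s_grid:
            model = DecisionModel("symmetric", {"s": float(s)})
            dist = enumerate_outcomes(model, ExperimentConfig(group_size=int(N)))
            bins = N + 1 if max_bins is None else min(max_bins, N + 1)
            label = classify_shape(rebin(dist, bins))
            mmin = min_bins_for_M(dist.probabilities, N, bins)
            out[(float(s), int(N))] = (label, mmin)
    return out


def partial_distributions(s: float, n_max: int) -> list[np.ndarray]:
    """Exact distribution of x-counts after each successive decider.

    Element ``t-1`` is the length-``t+1`` probability vector over the number
    at x among the first ``t`` deciders (symmetric rule, empty start).
    """
    from .decision_core import follow_prob_symmetric

    if n_max < 2:
        raise InvalidInputError("n_max must be >= 2")
    out = []
    level = {0: 1.0}  # n_x -> probability, after t deciders (t fixed per loop)
    for t in range(n_max):
        nxt: dict[int, float] = {}
        for nx, w in level.items():
            ny = t - nx
            p = follow_prob_symmetric(s, nx - ny)
            nxt[nx + 1] = nxt.get(nx + 1, 0.0) + w * p
            nxt[nx] = nxt.get(nx, 0.0) + w * (1.0 - p)
        level = nxt
        vec = np.zeros(t + 2)
        for nx, w in level.items():
            vec[nx] = w
        out.append(vec)
    return out


def shape_dynamics(s: float, n_max: int, n_bins: int = 5) -> list[str]:
    """Shape label as deciders accumulate, at a fixed bin count.

    Stages are classified only when the ``t + 1`` distinct outcomes divide
    evenly into ``n_bins`` bins (t + 1 a multiple of ``n_bins``): at other
    stages unequal bin occupancy injects spurious peaks and valleys that
    reflect the binning, not the process.  Returns the labels at stages
    ``t = n_bins - 1, 2 n_bins - 1, ...`` up to ``n_max`` deciders.
    """
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    labels = []
    for t, vec in enumerate(partial_distributions(s, n_max), start=1):
        if (t + 1) % n_bins:
            continue
        labels.append(classify_shape(rebin(vec, n_bins, t)))
    if not labels:
        raise InvalidInputError(
            f"n_max={n_max} reaches no stage with t + 1 divisible by {n_bins}")
    return labels


def dynamics_regime(s: float, n_max: int, n_bins: int = 5) -> str:
    """Compress a shape-dynamics trajectory into its regime.

    Returns ``"U-always"``, ``"M-then-U"``, ``"bell-M-U"`` or ``"other"``,
    the three regimes being: U from the first deciders onward; M first then
    U; bell, then M, then U (progressively weaker reliabilities).
    """
    labels = shape_dynamics(s, n_max, n_bins)
    distinct = []
    for lab in labels:
        if not distinct or distinct[-1] != lab:
            distinct.append(lab)
    if distinct == ["U"]:
        return "U-always"
    if distinct == ["M", "U"]:
        return "M-then-U"
    if distinct == ["bell", "M", "U"]:
        return "bell-M-U"
    return "other"
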