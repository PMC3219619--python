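"""Maximum-likelihood fitting and model comparison.

Observed data are count tables of final configurations over a set of
experimental conditions (20 repetitions per condition in the stickleback
designs).  The likelihood of a parameter vector is the product over
conditions of the multinomial probability of the observed counts under the
exactly enumerated outcome distribution.  Fitting is by coordinate ascent:
each parameter is optimised separately by bounded scalar maximisation (in
log-parameter space, since all parameters are positive rates/ratios) and the
sweep repeats until the log-likelihood stops improving.

Model comparison uses the Bayesian Information Criterion in its
"select-largest" form, BIC_i = L_i - (k_i / 2) ln n, where L_i is the
maximised log-likelihood, k_i the number of free parameters and n the number
of measurements (one per repetition).  Normalised exponentiated BIC scores
("BIC weights") read as the probability that each model is the best of the
compared set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .decision_core import DecisionModel, VARIANT_PARAMS
from .dependency_model import DependencyModel
from .errors import InvalidInputError, InvalidParameterError
from .group_process import ExperimentConfig, enumerate_outcomes, simulate_group

#: Floor applied to predicted probabilities inside logarithms.
PROB_FLOOR = 1e-300

#: Convergence tolerance on the log-likelihood between full sweeps.
SWEEP_TOL = 1e-8
MAX_SWEEPS = 200


@dataclass(frozen=True)
class ObservedDataset:
    """Final-configuration counts for a set of conditions."""

    conditions: tuple[ExperimentConfig, ...]
    counts: tuple[np.ndarray, ...]  # per condition, length N+1, index k at x

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.counts):
            raise InvalidInputError("one count vector required per condition")
        frozen = []
        for cfg, c in zip(self.conditions, self.counts):
            c = np.asarray(c)
            if c.shape != (cfg.group_size + 1,):
                raise InvalidInputError(
                    f"condition {cfg.condition_id!r}: counts must have length N + 1")
            if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
                raise InvalidInputError(
                    f"condition {cfg.condition_id!r}: counts must be non-negative integers")
            frozen.append(c)
        object.__setattr__(self, "counts", tuple(frozen))

    @property
    def n_measurements(self) -> int:
        """Total repetitions across conditions (one measurement each)."""
        return int(sum(c.sum() for c in self.counts))

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    variant: str
    params: dict[str, float]
    log_likelihood: float
    k: int
    n: int
    converged: bool
    n_sweeps: int
    bounds_hit: dict[str, bool] = field(default_factory=dict)
    floor_hit: bool = False
    trace: list[float] = field(default_factory=list)
    bic_value: float | None = None
    bic_weight: float | None = None

    @property
    def bic(self) -> float:
        return bic(self.log_likelihood, self.k, self.n)


@dataclass(frozen=True)
class ConfidenceBand:
    """Simulation-based per-configuration proportion band."""

    level: float
    lower: tuple[np.ndarray, ...]  # per condition
    upper: tuple[np.ndarray, ...]
    n_sim: int


# ---------------------------------------------------------------------------
# Likelihood and goodness of fit
# ---------------------------------------------------------------------------


def _build_model(variant: str, params: Mapping[str, float]):
    if variant == "dependency":
        extra = {k: v for k, v in params.items() if k.startswith("a_dep_")}
        return DependencyModel(
            a_dep=params["a_dep"],
            replica_biases={k[len("a_dep_"):]: v for k, v in extra.items()},
            a_focal=params.get("a", 1.0))
    return DecisionModel(variant, {k: params[k] for k in VARIANT_PARAMS[variant]})


def predicted_distributions(variant: str, params: Mapping[str, float],
                            conditions: Sequence[ExperimentConfig]):
    """Exact outcome probabilities for each condition at given parameters."""
    model = _build_model(variant, params)
    return [enumerate_outcomes(model, cfg).probabilities for cfg in conditions]


def log_likelihood(variant: str, params: Mapping[str, float],
                   data: ObservedDataset) -> float:
    """Multinomial log-probability of the observed count tables.

    The multinomial coefficient is included; it is constant in the
    parameters, so it shifts but never reorders likelihoods.  Predicted
    probabilities are floored at :data:`PROB_FLOOR` inside the logs, so a
    structurally impossible observation reports -inf rather than raising.
    """
    preds = predicted_distributions(variant, params, data.conditions)
    total = 0.0
    for p, c in zip(preds, data.counts):
        n = c.sum()
        coef = gammaln(n + 1) - gammaln(c + 1).sum()
        total += coef + float(np.sum(c * np.log(np.maximum(p, PROB_FLOOR))))
    return total


def rmse(variant: str, params: Mapping[str, float],
         data: ObservedDataset) -> float:
    """Root mean squared error between predicted probabilities and observed
    proportions, pooled over all conditions and configurations."""
    preds = predicted_distributions(variant, params, data.conditions)
    sq, m = 0.0, 0
    for p, c in zip(preds, data.counts):
        obs = c / c.sum()
        sq += float(np.sum((p - obs) ** 2))
        m += p.size
    return math.sqrt(sq / m)


# ---------------------------------------------------------------------------
# Coordinate-ascent fitting
# ---------------------------------------------------------------------------

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "s": (1e-3, 1e3), "a": (1e-3, 1e3), "rho": (1e-3, 1e3),
    "s_x": (1e-3, 1e3), "s_y": (1e-3, 1e3), "s_u": (1e-3, 1e3),
    "s_f": (1e-3, 1e3), "s_rep": (1e-3, 1e3), "a_dep": (1e-3, 1e3),
}


def _bounds_for(name: str, bounds) -> tuple[float, float]:
    if bounds and name in bounds:
        lo, hi = bounds[name]
    elif name.startswith("a_dep"):
        lo, hi = DEFAULT_BOUNDS["a_dep"]
    else:
        lo, hi = DEFAULT_BOUNDS.get(name, (1e-3, 1e3))
    if not (0 < lo < hi and math.isfinite(hi)):
        raise InvalidParameterError(f"bounds for {name!r} must be finite and positive")
    return lo, hi


def fit(variant: str, data: ObservedDataset,
        init: Mapping[str, float],
        free: Sequence[str] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        tol: float = SWEEP_TOL, max_sweeps: int = MAX_SWEEPS) -> FitResult:
    """Maximise the likelihood by coordinate ascent over the parameters.

    Each sweep optimises every free parameter in turn with bounded scalar
    maximisation in log-parameter space; sweeps repeat until the
    log-likelihood improves by less than ``tol``.  Parameters named in
    ``init`` but not in ``free`` are held fixed (the frozen-parameter
    protocol) and excluded from the parameter count ``k``.
    """
    params = dict(init)
    free = list(free) if free is not None else list(params)
    if not free:
        raise InvalidParameterError("at least one parameter must be free")
    for name in free:
        if name not in params:
            raise InvalidParameterError(f"free parameter {name!r} missing from init")

    ll = log_likelihood(variant, params, data)
    trace = [ll]
    bounds_hit = {name: False for name in free}
    converged = False
    sweeps = 0
    current = ll
    for sweeps in range(1, max_sweeps + 1):
        for name in free:
            lo, hi = _bounds_for(name, bounds)

            def neg(logv, _name=name):
                trial = dict(params)
                trial[_name] = math.exp(logv)
                return -log_likelihood(variant, trial, data)

            res = minimize_scalar(neg, bounds=(math.log(lo), math.log(hi)),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            best = math.exp(res.x)
            if -res.fun >= current:
                params[name] = best
                current = -res.fun
            edge = min(best / lo, hi / best)
            bounds_hit[name] = bounds_hit[name] or edge < 1.001
        new_ll = current
        trace.append(new_ll)
        if new_ll < ll - 1e-9:
            raise RuntimeError("coordinate ascent decreased the log-likelihood")
        if new_ll - ll < tol:
            converged = True
            ll = new_ll
            break
        ll = new_ll

    preds = predicted_distributions(variant, params, data.conditions)
    floor_hit = any(np.any((p <= PROB_FLOOR) & (c > 0))
                    for p, c in zip(preds, data.counts))
    return FitResult(variant=variant, params=params, log_likelihood=ll,
                     k=len(free), n=data.n_measurements, converged=converged,
                     n_sweeps=sweeps, bounds_hit=bounds_hit,
                     floor_hit=floor_hit, trace=trace)


def fit_multistart(variant: str, data: ObservedDataset,
                   init: Mapping[str, float], n_starts: int, seed: int,
                   free: Sequence[str] | None = None,
                   bounds: Mapping[str, tuple[float, float]] | None = None,
                   **kwargs) -> FitResult:
    """Run :func:`fit` from several random initial points, keep the best."""
    rng = np.random.default_rng(seed)
    free_names = list(free) if free is not None else list(init)
    best: FitResult | None = None
    for i in range(max(n_starts, 1)):
        start = dict(init)
        if i > 0:
            for name in free_names:
                lo, hi = _bounds_for(name, bounds)
                # log-uniform draw within a moderate sub-range of the bounds
                start[name] = math.exp(rng.uniform(
                    math.log(max(lo, 0.1)), math.log(min(hi, 10.0))))
        result = fit(variant, data, start, free=free_names, bounds=bounds, **kwargs)
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    return best


# ---------------------------------------------------------------------------
# BIC and model comparison
# ---------------------------------------------------------------------------


def bic(logprob: float, k: int, n: int) -> float:
    """BIC in the select-largest convention, L - (k/2) ln n."""
    if n < 1 or k < 0:
        raise InvalidInputError("need n >= 1 and k >= 0")
    return logprob - 0.5 * k * math.log(n)


def bic_classic(logprob: float, k: int, n: int) -> float:
    """The common minimise-me convention, -2L + k ln n.

    Equal to ``-2 * bic(...)``; rankings are identical with the order
    reversed (smaller is better here).
    """
    return -2.0 * bic(logprob, k, n)


def bic_weights(bics: Sequence[float]) -> np.ndarray:
    """Normalised exponentiated BIC scores (shifted log domain).

    Interpretable as the probability that each model of the compared set is
    the most correct one.
    """
    b = np.asarray(bics, dtype=float)
    if b.size == 0:
        raise InvalidInputError("need at least one BIC value")
    w = np.exp(b - b.max())
    return w / w.sum()


def model_selection_study(candidates: Sequence[dict], data: ObservedDataset,
                          **fit_kwargs) -> list[FitResult]:
    """Fit every candidate to the same data, rank by BIC.

    Each candidate is a dict with keys ``variant``, ``init`` and optionally
    ``free`` and ``bounds``.  Fixed (frozen) parameters are excluded from
    ``k``.  Results come back sorted best-first, with ``bic_value`` and
    ``bic_weight`` filled in.
    """
    results = []
    for cand in candidates:
        res = fit(cand["variant"], data, cand["init"],
                  free=cand.get("free"), bounds=cand.get("bounds"), **fit_kwargs)
        results.append(res)
    ns = {r.n for r in results}
    if len(ns) != 1:
        raise InvalidInputError("candidates were scored on differing n; comparison invalid")
    scores = [r.bic for r in results]
    weights = bic_weights(scores)
    for r, b, w in zip(results, scores, weights):
        r.bic_value = b
        r.bic_weight = float(w)
    return sorted(results, key=lambda r: r.bic_value, reverse=True)


def confidence_band(variant: str, params: Mapping[str, float],
                    conditions: Sequence[ExperimentConfig],
                    repetitions: int | Sequence[int] = 20,
                    level: float = 0.95, n_sim: int = 1000,
                    seed: int = 0) -> ConfidenceBand:
    """Simulation band around the model's predicted proportions.

    Simulates ``n_sim`` replicate experiments with the design's repetition
    counts, and takes per-configuration empirical quantiles of the observed
    proportions at ``(1 - level)/2`` and ``(1 + level)/2``.
    """
    if not (0.0 < level < 1.0):
        raise InvalidInputError("level must be in (0, 1)")
    model = _build_model(variant, params)
    reps = ([repetitions] * len(conditions)
            if isinstance(repetitions, int) else list(repetitions))
    rng = np.random.default_rng(seed)
    lowers, uppers = [], []
    for cfg, n_rep in zip(conditions, reps):
        p = enumerate_outcomes(model, cfg).probabilities
        sims = rng.multinomial(n_rep, p, size=n_sim) / n_rep
        lowers.append(np.quantile(sims, (1 - level) / 2, axis=0))
        uppers.append(np.quantile(sims, (1 + level) / 2, axis=0))
    return ConfidenceBand(level=level, lower=tuple(lowers),
                          upper=tuple(uppers), n_sim=n_sim)


def expected_counts_dataset(variant: str, params: Mapping[str, float],
                            conditions: Sequence[ExperimentConfig],
                            repetitions: int = 20) -> ObservedDataset:
    """Idealised dataset whose counts match the model's expectations.

    Expected proportions times repetitions are rounded to integers with
    largest-remainder correction so every condition still totals exactly
    ``repetitions``.  Used for self-consistency (parameter-recovery) checks.
    """
    preds = predicted_distributions(variant, params, conditions)
    tables = []
    for p in preds:
        raw = p * repetitions
        base = np.floor(raw).astype(np.int64)
        short = repetitions - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
        tables.append(base)
    return ObservedDataset(tuple(conditions), tuple(tables))
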