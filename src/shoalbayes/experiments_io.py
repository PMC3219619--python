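"""Study configuration, synthetic-experiment generation, and file I/O.

The stickleback experiments this package emulates have no deposited raw
data, so synthetic studies generated from the models themselves stand in for
them: a study design (conditions, repetitions, seed), a generating model,
and the resulting count tables, with the ground-truth parameters kept for
recovery tests.

On disk a dataset is a CSV of counts (``condition_id,k_at_x,count``) plus a
JSON sidecar describing each condition; writing then reading reproduces the
dataset exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decision_core import DecisionModel
from .dependency_model import DependencyModel
from .errors import InvalidInputError, SchemaError
from .group_process import ExperimentConfig, simulate_group
from .inference import ObservedDataset

log = logging.getLogger("shoalbayes")

SCHEMA_VERSION = 1

#: Replica ratios (left : right) of the symmetric stickleback design.
SYMMETRIC_RATIOS = ((1, 1), (2, 2), (0, 1), (1, 2), (0, 2), (1, 3), (0, 3))

#: Group sizes used across the stickleback experiments.
GROUP_SIZES = (2, 4, 8)

#: Repetitions per condition in the source experiments.
DEFAULT_REPETITIONS = 20

#: Fitted attractiveness ratios (less- over more-attractive replica) for the
#: ten replica pairs of the two-replica experiments, row by row.
TWO_REPLICA_RATIOS = (0.35, 0.7, 0.5, 0.52, 0.69, 0.75, 0.43, 0.55, 0.78, 0.43)

# The symmetric experiments cover 19 of the 21 (group size x ratio) cells;
# which two cells were absent is a design reconstruction (see methods note).
_SYMMETRIC_OMITTED = ((2, (2, 2)), (2, (0, 3)))


@dataclass(frozen=True)
class StudyConfig:
    """A full study: conditions, repetitions per condition, seed."""

    conditions: tuple[ExperimentConfig, ...]
    repetitions: int = DEFAULT_REPETITIONS
    seed: int | None = None
    name: str = "study"

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise InvalidInputError("repetitions must be >= 1")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("condition_ids must be unique")


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated dataset plus the ground truth that produced it."""

    config: StudyConfig
    dataset: ObservedDataset
    variant: str
    true_params: Mapping[str, float]


def default_stickleback_design(repetitions: int = DEFAULT_REPETITIONS) -> StudyConfig:
    """The 19-condition symmetric design: replicas to each side, 20 reps.

    Group sizes 2, 4 and 8 crossed with replica ratios 1:1, 2:2, 0:1, 1:2,
    0:2, 1:3 and 0:3 (left:right), minus the two cells absent from the
    source experiments.
    """
    conditions = []
    for N in GROUP_SIZES:
        for rx, ry in SYMMETRIC_RATIOS:
            if (N, (rx, ry)) in _SYMMETRIC_OMITTED:
                continue
            replicas = tuple([("replica", "x")] * rx + [("replica", "y")] * ry)
            conditions.append(ExperimentConfig(
                group_size=N, replicas=replicas,
                condition_id=f"N{N}_r{rx}v{ry}"))
    assert len(conditions) == 19
    return StudyConfig(tuple(conditions), repetitions=repetitions,
                       name="symmetric")


def two_replica_design(repetitions: int = DEFAULT_REPETITIONS) -> StudyConfig:
    """Ten replica-pair rows x three group sizes, one pair per condition.

    Each row places one more-attractive replica ("R") on x and one
    less-attractive replica ("r") on y; the rows carry the ten fitted
    attractiveness ratios.
    """
    conditions = []
    for row in range(1, len(TWO_REPLICA_RATIOS) + 1):
        for N in GROUP_SIZES:
            conditions.append(ExperimentConfig(
                group_size=N,
                replicas=(("R", "x"), ("r", "y")),
                condition_id=f"pair{row}_N{N}"))
    return StudyConfig(tuple(conditions), repetitions=repetitions,
                       name="two-replica")


def predator_design(repetitions: int = DEFAULT_REPETITIONS) -> StudyConfig:
    """Asymmetric design: a predator at y, replicas sent toward x.

    Group sizes 2, 4 and 8 crossed with 0-3 replicas going to the safe
    side; the asymmetry enters through the fitted non-social term, not the
    geometry recorded here.
    """
    conditions = []
    for N in GROUP_SIZES:
        for r in (0, 1, 2, 3):
            replicas = tuple([("replica", "x")] * r)
            conditions.append(ExperimentConfig(
                group_size=N, replicas=replicas,
                condition_id=f"pred_N{N}_r{r}"))
    return StudyConfig(tuple(conditions), repetitions=repetitions,
                       name="predator")


def generate_synthetic_dataset(config: StudyConfig,
                               variant: str,
                               params: Mapping[str, float],
                               seed: int | None = None) -> SyntheticStudy:
    """Simulate every condition of a study and keep the ground truth.

    One repetition-count table per condition, produced by seeded sequential
    simulation; the per-condition streams are derived from the study seed so
    the whole study is reproducible.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise InvalidInputError("a seed is required to generate a synthetic study")
    from .inference import _build_model  # shared variant dispatch

    model = _build_model(variant, params)
    ss = np.random.SeedSequence(seed)
    tables = []
    for cfg, child in zip(config.conditions,
                          ss.spawn(len(config.conditions))):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        dist = simulate_group(model, cfg, config.repetitions, sub_seed)
        tables.append(dist.counts)
        log.info("simulated %s: N=%d reps=%d seed=%d", cfg.condition_id,
                 cfg.group_size, config.repetitions, sub_seed)
    dataset = ObservedDataset(config.conditions, tuple(tables))
    return SyntheticStudy(config=config, dataset=dataset, variant=variant,
                          true_params=dict(params))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _config_to_json(cfg: ExperimentConfig) -> dict:
    return {
        "condition_id": cfg.condition_id,
        "group_size": cfg.group_size,
        "replicas": [list(r) for r in cfg.replicas],
        "asymmetry": cfg.asymmetry,
        "options": cfg.options,
        "initial_fish": list(cfg.initial_fish),
    }


def _config_from_json(rec: dict) -> ExperimentConfig:
    try:
        return ExperimentConfig(
            group_size=rec["group_size"],
            replicas=tuple(tuple(r) for r in rec.get("replicas", [])),
            asymmetry=rec.get("asymmetry", 1.0),
            options=rec.get("options", 2),
            initial_fish=tuple(rec.get("initial_fish", (0, 0))),
            condition_id=rec["condition_id"],
        )
    except KeyError as exc:
        raise SchemaError(f"condition record missing field {exc}") from exc


def write_dataset(data: ObservedDataset, csv_path: str | Path,
                  sidecar_path: str | Path | None = None) -> None:
    """Write counts as CSV plus a JSON sidecar of condition configs."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else \
        csv_path.with_suffix(".json")
    rows = []
    for cfg, counts in zip(data.conditions, data.counts):
        for k, c in enumerate(counts):
            rows.append({"condition_id": cfg.condition_id, "k_at_x": k,
                         "count": int(c)})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    sidecar = {"schema_version": SCHEMA_VERSION,
               "conditions": [_config_to_json(c) for c in data.conditions]}
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def read_dataset(csv_path: str | Path,
                 sidecar_path: str | Path | None = None) -> ObservedDataset:
    """Read a dataset written by :func:`write_dataset` (strict validation)."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else \
        csv_path.with_suffix(".json")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except FileNotFoundError as exc:
        raise SchemaError(f"missing JSON sidecar {sidecar_path}") from exc
    if "conditions" not in sidecar:
        raise SchemaError(f"{sidecar_path}: no 'conditions' field")
    conditions = [_config_from_json(r) for r in sidecar["conditions"]]
    by_id = {c.condition_id: c for c in conditions}

    df = pd.read_csv(csv_path)
    required = {"condition_id", "k_at_x", "count"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{csv_path}: missing columns {sorted(required - set(df.columns))}")
    tables = {cid: np.zeros(by_id[cid].group_size + 1, dtype=np.int64)
              for cid in by_id}
    for row in df.itertuples():
        line = row.Index + 2  # header is line 1
        cid = row.condition_id
        if cid not in by_id:
            raise SchemaError(f"{csv_path} line {line}: unknown condition_id {cid!r}")
        if row.count < 0 or int(row.count) != row.count:
            raise SchemaError(
                f"{csv_path} line {line}: count must be a non-negative integer")
        k = int(row.k_at_x)
        if not (0 <= k <= by_id[cid].group_size):
            raise SchemaError(
                f"{csv_path} line {line}: k_at_x={k} outside 0..N for {cid!r}")
        tables[cid][k] += int(row.count)
    return ObservedDataset(tuple(conditions),
                           tuple(tables[c.condition_id] for c in conditions))


def outcome_table(distributions) -> pd.DataFrame:
    """Tabulate outcome distributions as condition_id / k_at_x / value rows."""
    rows = []
    for dist in distributions:
        values = dist.counts if dist.counts is not None else dist.probabilities
        for k, v in enumerate(values):
            rows.append({"condition_id": dist.condition_id, "k_at_x": k,
                         "probability_or_count": v,
                         "provenance": dist.provenance})
    return pd.DataFrame(rows)
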