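"""Synthetic cohorts for a five-task individual-differences battery.

The battery comprises a physical-prediction task (judging which way an
unstable block tower will fall), two spatial tests (paper folding, mental
rotation) and two complex-span working-memory tasks (spatial and verbal),
each of which also carries a secondary processing judgement (shape symmetry
and lexical decision respectively).

The generator gives every simulated participant three latent abilities on a
standard-normal scale:

* ``s`` — spatial ability, loading on both spatial tests and on the towers
  task;
* ``w`` — working-memory ability, loading on both span tasks;
* ``u`` — a physics-unique component, independent of ``s`` and ``w`` by
  construction, loading only on the towers task.

Each task's true ability is ``theta = l_s*s + l_w*w + l_u*u``.  A scoring
unit (one tower video, one test item, one selection, one span trial) is
answered correctly with probability

    P(correct) = c + (1 - c) * logistic(theta - b)

the three-parameter-logistic response function, where ``c`` is the task's
guessing floor (it differs across tasks because the response formats differ)
and ``b`` is a per-item difficulty drawn once per cohort.  Working-memory
trials additionally shift ``b`` by a linear function of set size so that
longer spans are harder.

Because ``u`` is independent of the other factors, "unique variance" has an
exact meaning in this model, and recovery of a nonzero ``u`` loading by the
residual split-half analysis can be tested against ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit

from .errors import ConfigurationError

TASKS = ("towers", "paper_folding", "mental_rotation", "wm_spatial", "wm_verbal")
SPATIAL_TASKS = ("paper_folding", "mental_rotation")
WM_TASKS = ("wm_spatial", "wm_verbal")
#: secondary processing judgement attached to each complex-span task
SECONDARY_MEASURES = {"wm_spatial": "symmetry", "wm_verbal": "lexical"}

TOWER_BLOCK_COUNTS = (11, 13, 15, 17, 19, 21)
TOWER_SIDES = ("gray", "white")
WM_SET_SIZES = (3, 4, 5, 6, 7, 8)

TRIAL_COLUMNS = ("participant_id", "task", "item_id", "stratum", "unit_kind", "correct")


class TaskSchedule(BaseModel):
    """Item counts per stratum for one task, with optional difficulty shifts.

    ``strata`` maps a stratum (trial-type) label to the number of primary
    scoring units it contains.  ``stratum_shift`` adds a fixed offset to the
    item difficulty of every unit in a stratum (used to make longer
    working-memory spans harder).
    """

    model_config = ConfigDict(frozen=True)

    strata: dict[str, int]
    stratum_shift: dict[str, float] = Field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return sum(self.strata.values())

    @model_validator(mode="after")
    def _check(self) -> "TaskSchedule":
        if not self.strata:
            raise ConfigurationError("a task schedule needs at least one stratum")
        for label, count in self.strata.items():
            if count <= 0:
                raise ConfigurationError(f"stratum {label!r} has non-positive count {count}")
        unknown = set(self.stratum_shift) - set(self.strata)
        if unknown:
            raise ConfigurationError(f"stratum_shift refers to unknown strata: {sorted(unknown)}")
        return self


class Loadings(BaseModel):
    """Weights of one task's true score on the latent factors (s, w, u)."""

    model_config = ConfigDict(frozen=True)

    s: float = 0.0
    w: float = 0.0
    u: float = 0.0


class SecondaryConfig(BaseModel):
    """Generative parameters for the secondary (processing) judgements.

    Each participant gets a stable secondary accuracy drawn from
    ``Normal(mean_accuracy, sd_accuracy)`` clipped to [0, 1]; participants
    listed in ``outlier_ids`` (positional indices into the cohort) are forced
    to ``outlier_accuracy`` instead, which is how tests plant inattentive
    responders for the screening rule to catch.
    """

    model_config = ConfigDict(frozen=True)

    n_units: int = Field(default=132, gt=0)
    mean_accuracy: float = Field(default=0.93, ge=0.0, le=1.0)
    sd_accuracy: float = Field(default=0.03, ge=0.0)
    outlier_ids: tuple[int, ...] = ()
    outlier_accuracy: float = Field(default=0.5, ge=0.0, le=1.0)


class CohortConfig(BaseModel):
    """Full generative specification of a synthetic cohort.

    All per-task dictionaries must share the same task set (a subset of
    :data:`TASKS`).  Only the towers task may load on the physics-unique
    factor ``u``; that restriction is what makes "unique variance" in the
    towers task identifiable.
    """

    model_config = ConfigDict(frozen=True)

    n_participants: int = Field(default=100, gt=0)
    latent_sd: dict[str, float] = Field(default_factory=lambda: {"s": 1.0, "w": 1.0, "u": 1.0})
    latent_corr: float = Field(default=0.3, ge=-1.0, le=1.0)
    loadings: dict[str, Loadings]
    item_difficulty_mean: dict[str, float]
    item_difficulty_sd: dict[str, float]
    chance_floor: dict[str, float]
    schedule: dict[str, TaskSchedule]
    secondary: SecondaryConfig = SecondaryConfig()
    seed: int = 0

    @field_validator("latent_sd")
    @classmethod
    def _check_latent_sd(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"s", "w", "u"}:
            raise ConfigurationError("latent_sd must have exactly the keys s, w, u")
        if any(sd < 0 for sd in v.values()):
            raise ConfigurationError("latent standard deviations must be non-negative")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        tasks = set(self.schedule)
        unknown = tasks - set(TASKS)
        if unknown:
            raise ConfigurationError(f"unknown tasks in schedule: {sorted(unknown)}")
        for name, mapping in (
            ("loadings", self.loadings),
            ("item_difficulty_mean", self.item_difficulty_mean),
            ("item_difficulty_sd", self.item_difficulty_sd),
            ("chance_floor", self.chance_floor),
        ):
            if set(mapping) != tasks:
                raise ConfigurationError(
                    f"{name} must cover exactly the scheduled tasks {sorted(tasks)}"
                )
        for task, c in self.chance_floor.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigurationError(f"chance floor for {task} must be in [0, 1], got {c}")
        for task, sd in self.item_difficulty_sd.items():
            if sd < 0:
                raise ConfigurationError(f"item_difficulty_sd for {task} must be >= 0")
        for task, load in self.loadings.items():
            if task != "towers" and load.u != 0.0:
                raise ConfigurationError(
                    f"only the towers task may load on the unique factor u; {task} has u={load.u}"
                )
        return self

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        text = self.model_dump_json(indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))


def scheduled_units(config: CohortConfig) -> dict[str, int]:
    """Number of primary scoring units per task implied by a config."""
    return {task: sched.n_units for task, sched in config.schedule.items()}


def default_config(
    n_participants: int = 100,
    latent_corr: float = 0.3,
    u_loading: float = 0.6,
    wm_setsize_slope: float = 0.35,
    seed: int = 0,
) -> CohortConfig:
    """Battery-matched default configuration.

    The schedule reproduces the published battery: 48 tower videos in 12
    strata of 4 (six block counts of 11-21 crossed with the two landing
    sides), 20 paper-folding items, 48 mental-rotation selections (24 items
    with two correct choices each), and 24 complex-span trials per
    working-memory task (four at each set size 3-8) with 132 secondary
    judgements each.  Chance floors follow the response formats: 1/2 for
    towers and mental rotation, 1/5 for paper folding, and 2^-12 for the
    span tasks (a random subset of the 12 response cells must equal the
    target set exactly).

    Difficulty and loading defaults are illustrative, chosen so that mean
    accuracies sit well between chance and ceiling (towers near 0.79) and
    the task intercorrelation pattern is realistic: spatial tasks correlate
    with towers and with each other, span tasks correlate strongly with each
    other and modestly with the spatial tasks.  ``u_loading`` scales the
    physics-unique component; set it to 0 for a null cohort in which towers
    variance is fully explained by ``s`` and ``w``.
    """
    towers_strata = {
        f"{blocks:02d}_{side}": 4 for blocks in TOWER_BLOCK_COUNTS for side in TOWER_SIDES
    }
    wm_strata = {f"set{k}": 4 for k in WM_SET_SIZES}
    wm_shift = {f"set{k}": wm_setsize_slope * (k - np.mean(WM_SET_SIZES)) for k in WM_SET_SIZES}
    return CohortConfig(
        n_participants=n_participants,
        latent_corr=latent_corr,
        loadings={
            "towers": Loadings(s=0.6, w=0.0, u=u_loading),
            "paper_folding": Loadings(s=0.9),
            "mental_rotation": Loadings(s=0.9),
            "wm_spatial": Loadings(w=1.1),
            "wm_verbal": Loadings(w=1.1),
        },
        item_difficulty_mean={
            "towers": -0.33,
            "paper_folding": 0.0,
            "mental_rotation": -0.4,
            "wm_spatial": -0.5,
            "wm_verbal": -0.5,
        },
        item_difficulty_sd={
            "towers": 1.0,
            "paper_folding": 1.0,
            "mental_rotation": 1.0,
            "wm_spatial": 0.5,
            "wm_verbal": 0.5,
        },
        chance_floor={
            "towers": 0.5,
            "paper_folding": 0.2,
            "mental_rotation": 0.5,
            "wm_spatial": 2.0 ** -12,
            "wm_verbal": 2.0 ** -12,
        },
        schedule={
            "towers": TaskSchedule(strata=towers_strata),
            "paper_folding": TaskSchedule(strata={"all": 20}),
            "mental_rotation": TaskSchedule(strata={"all": 48}),
            "wm_spatial": TaskSchedule(strata=wm_strata, stratum_shift=wm_shift),
            "wm_verbal": TaskSchedule(strata=wm_strata, stratum_shift=wm_shift),
        },
        seed=seed,
    )


def _seed_streams(seed: int) -> list[np.random.SeedSequence]:
    """Independent child streams: abilities, item difficulties, responses, secondary."""
    return np.random.SeedSequence(seed).spawn(4)


def draw_abilities(config: CohortConfig) -> pd.DataFrame:
    """Draw the latent ability table for a cohort.

    Returns one row per participant with columns ``participant_id``, the
    latent factors ``s``, ``w``, ``u``, and a ``theta_<task>`` column per
    scheduled task.  (s, w) are bivariate normal with the configured
    standard deviations and correlation; u is independent normal.
    """
    sd_s, sd_w, sd_u = (config.latent_sd[k] for k in ("s", "w", "u"))
    cov = np.array(
        [
            [sd_s**2, config.latent_corr * sd_s * sd_w],
            [config.latent_corr * sd_s * sd_w, sd_w**2],
        ]
    )
    if np.linalg.eigvalsh(cov).min() < -1e-12:
        raise ConfigurationError("latent covariance is not positive semi-definite")

    rng = np.random.default_rng(_seed_streams(config.seed)[0])
    n = config.n_participants
    # "eigh" handles singular covariances (zero sd, |corr| = 1) as well
    sw = rng.multivariate_normal(np.zeros(2), cov, size=n, method="eigh")
    u = rng.normal(0.0, sd_u, size=n)

    out = pd.DataFrame(
        {
            "participant_id": [f"p{i:04d}" for i in range(n)],
            "s": sw[:, 0],
            "w": sw[:, 1],
            "u": u,
        }
    )
    for task in config.schedule:
        load = config.loadings[task]
        out[f"theta_{task}"] = load.s * out["s"] + load.w * out["w"] + load.u * out["u"]
    return out


def draw_item_difficulties(config: CohortConfig) -> pd.DataFrame:
    """Draw the fixed per-cohort item table (one row per primary unit).

    Difficulties are ``Normal(mean_task, sd_task)`` plus any per-stratum
    shift.  The table is a deterministic function of the config seed and is
    shared by every participant, which is what makes item-level split-half
    analyses meaningful.
    """
    rng = np.random.default_rng(_seed_streams(config.seed)[1])
    rows = []
    for task, sched in config.schedule.items():
        labels: list[str] = []
        shifts: list[float] = []
        for stratum, count in sched.strata.items():
            labels.extend([stratum] * count)
            shifts.extend([sched.stratum_shift.get(stratum, 0.0)] * count)
        n_items = len(labels)
        b = (
            config.item_difficulty_mean[task]
            + config.item_difficulty_sd[task] * rng.standard_normal(n_items)
            + np.asarray(shifts)
        )
        rows.append(
            pd.DataFrame(
                {
                    "task": task,
                    "item_id": [f"{task}_{i + 1:03d}" for i in range(n_items)],
                    "stratum": labels,
                    "difficulty": b,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def response_probability(theta: np.ndarray, difficulty: np.ndarray, chance: float) -> np.ndarray:
    """3PL response function: ``c + (1 - c) * logistic(theta - b)``."""
    return chance + (1.0 - chance) * expit(np.asarray(theta) - np.asarray(difficulty))


def simulate_trials(abilities: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Simulate the full trial table for a cohort.

    Primary units are Bernoulli draws from the 3PL response function; the
    secondary symmetry/lexical judgements are Bernoulli at each
    participant's stable secondary accuracy.  The output is a long-format
    table with columns :data:`TRIAL_COLUMNS`, byte-identical across calls
    with the same config (including seed).
    """
    for task in config.schedule:
        if task not in config.loadings:
            raise ConfigurationError(f"no loadings configured for scheduled task {task!r}")

    items = draw_item_difficulties(config)
    streams = _seed_streams(config.seed)
    rng_resp = np.random.default_rng(streams[2])
    rng_sec = np.random.default_rng(streams[3])

    pids = abilities["participant_id"].to_numpy()
    n = len(pids)
    frames = []
    for task in config.schedule:
        task_items = items[items["task"] == task]
        theta = abilities[f"theta_{task}"].to_numpy()
        p = response_probability(
            theta[:, None], task_items["difficulty"].to_numpy()[None, :], config.chance_floor[task]
        )
        correct = (rng_resp.random(p.shape) < p).astype(np.int64)
        m = len(task_items)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, m),
                    "task": task,
                    "item_id": np.tile(task_items["item_id"].to_numpy(), n),
                    "stratum": np.tile(task_items["stratum"].to_numpy(), n),
                    "unit_kind": "primary",
                    "correct": correct.ravel(),
                }
            )
        )

    sec = config.secondary
    for task in WM_TASKS:
        if task not in config.schedule:
            continue
        measure = SECONDARY_MEASURES[task]
        acc = np.clip(
            rng_sec.normal(sec.mean_accuracy, sec.sd_accuracy, size=n), 0.0, 1.0
        )
        for idx in sec.outlier_ids:
            acc[idx] = sec.outlier_accuracy
        correct = (rng_sec.random((n, sec.n_units)) < acc[:, None]).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, sec.n_units),
                    "task": task,
                    "item_id": np.tile(
                        [f"{measure}_{i + 1:03d}" for i in range(sec.n_units)], n
                    ),
                    "stratum": "secondary",
                    "unit_kind": "secondary",
                    "correct": correct.ravel(),
                }
            )
        )

    out = pd.concat(frames, ignore_index=True)
    return out[list(TRIAL_COLUMNS)]


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: draw abilities and simulate trials in one call."""
    abilities = draw_abilities(config)
    return abilities, simulate_trials(abilities, config)
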