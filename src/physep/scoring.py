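"""Scoring and participant screening for the five-task battery.

Every task is scored as the fraction of correct primary scoring units out
of the scheduled number: 48 tower judgements, 20 paper-folding items, 48
mental-rotation selections (two per item, so a single correct choice earns
partial credit), and 24 span trials per working-memory task.  A span trial
is a single primary unit whose correctness already encodes the exact-set
rule — all target positions selected and no others — so no partial credit
exists within a span trial, and recall order is ignored.

Screening uses the secondary processing judgements of the two span tasks
(shape symmetry, lexical decision): a participant is excluded when their
accuracy on either measure falls more than ``k_sd`` standard deviations
below the cohort mean (default 5).  Thresholds are computed once on the
full cohort and applied in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import SECONDARY_MEASURES, SPATIAL_TASKS, WM_TASKS
from .errors import IncompleteDataError, PhysepError, TrialTableError

#: primary scoring units per task in the standard battery (the accuracy denominators)
SCHEDULED_UNITS = {
    "towers": 48,
    "paper_folding": 20,
    "mental_rotation": 48,
    "wm_spatial": 24,
    "wm_verbal": 24,
}


def chance_level(task: str) -> float:
    """Accuracy expected from uniform random responding on one task.

    towers
        one of two sides: 1/2.
    paper_folding
        one of five options: 1/5.
    mental_rotation
        two of four options are selected and exactly two are correct; the
        expected fraction of correct selections, enumerated over the six
        unordered pairs, is 1/2.
    wm_spatial / wm_verbal
        a uniformly random subset of the 12 response cells must equal the
        target set exactly: 2**-12 (about 0.024%).
    """
    if task == "towers":
        return 0.5
    if task == "paper_folding":
        return 1.0 / 5.0
    if task == "mental_rotation":
        correct = {0, 1}
        pairs = list(combinations(range(4), 2))
        return float(np.mean([len(correct.intersection(p)) / 2.0 for p in pairs]))
    if task in WM_TASKS:
        return 2.0 ** -12
    raise PhysepError(f"unknown task {task!r}")


def _primary(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["unit_kind"] == "primary"]


def score_primary(
    trials: pd.DataFrame, expected_units: dict[str, int] | None = None
) -> pd.DataFrame:
    """Compute the participants x tasks accuracy matrix.

    Parameters
    ----------
    trials
        Long-format trial table (see :data:`physep.cohort.TRIAL_COLUMNS`).
    expected_units
        Scheduled primary-unit count per task; defaults to the standard
        battery (:data:`SCHEDULED_UNITS`).  Every participant must have
        exactly that many primary units for every task present, otherwise an
        :class:`IncompleteDataError` names the offender.

    Returns
    -------
    DataFrame with one row per participant: ``participant_id``, one accuracy
    column per task, plus ``combined_spatial`` (mean of the two spatial
    accuracies) and ``combined_wm`` (mean of the two span accuracies) when
    their components are present.
    """
    prim = _primary(trials)
    if prim.empty:
        raise TrialTableError("trial table contains no primary units")

    dup = prim.duplicated(subset=["participant_id", "task", "item_id"])
    if dup.any():
        row = prim[dup].iloc[0]
        raise TrialTableError(
            f"duplicate primary unit: participant {row['participant_id']} "
            f"task {row['task']} item {row['item_id']}"
        )

    expected = SCHEDULED_UNITS if expected_units is None else expected_units
    counts = prim.groupby(["participant_id", "task"], sort=True).size()
    for (pid, task), n in counts.items():
        if task not in expected:
            raise TrialTableError(f"task {task!r} has no scheduled unit count")
        if n != expected[task]:
            raise IncompleteDataError(
                f"participant {pid} has {n} primary units for task {task}, "
                f"expected {expected[task]}"
            )
    # every participant must have every task that appears in the table
    wide = prim.groupby(["participant_id", "task"], sort=True)["correct"].mean().unstack()
    if wide.isna().any().any():
        pid = wide.index[wide.isna().any(axis=1)][0]
        task = wide.columns[wide.loc[pid].isna()][0]
        raise IncompleteDataError(f"participant {pid} has no units for task {task}")

    scores = wide.reset_index()
    scores.columns.name = None
    if all(t in scores for t in SPATIAL_TASKS):
        scores["combined_spatial"] = scores[list(SPATIAL_TASKS)].mean(axis=1)
    if all(t in scores for t in WM_TASKS):
        scores["combined_wm"] = scores[list(WM_TASKS)].mean(axis=1)
    return scores


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the secondary-task attention screen.

    ``thresholds`` maps each secondary measure to the cutoff
    ``mean - k_sd * SD`` computed once on the full cohort;
    ``secondary_accuracy`` holds each participant's accuracy per measure.
    """

    excluded_ids: tuple[str, ...]
    secondary_accuracy: pd.DataFrame
    thresholds: dict[str, float]
    k_sd: float


def screen_participants(trials: pd.DataFrame, k_sd: float = 5.0) -> ScreenResult:
    """Flag participants far below the cohort on either secondary measure.

    For each secondary measure the cohort mean and sample standard deviation
    are computed and participants below ``mean - k_sd * SD`` on *either*
    measure are flagged (OR rule).  A measure with zero spread excludes no
    one — there is no evidence any participant ignored it — which also makes
    the screen idempotent: thresholds are frozen, not recomputed after
    exclusion.
    """
    sec = trials[trials["unit_kind"] == "secondary"]
    for task in WM_TASKS:
        if task not in set(sec["task"]):
            raise TrialTableError(f"no secondary units for task {task}; cannot screen")

    acc = sec.groupby(["participant_id", "task"], sort=True)["correct"].mean().unstack()
    acc = acc.rename(columns=SECONDARY_MEASURES)

    thresholds: dict[str, float] = {}
    flagged: set[str] = set()
    for measure in acc.columns:
        mean = float(acc[measure].mean())
        sd = float(acc[measure].std(ddof=1))
        if sd == 0.0:
            thresholds[measure] = float("-inf")
            continue
        thresholds[measure] = mean - k_sd * sd
        flagged.update(acc.index[acc[measure] < thresholds[measure]])

    return ScreenResult(
        excluded_ids=tuple(sorted(flagged)),
        secondary_accuracy=acc,
        thresholds=thresholds,
        k_sd=float(k_sd),
    )


def apply_screen(trials: pd.DataFrame, screen: ScreenResult) -> pd.DataFrame:
    """Drop all rows belonging to screened-out participants."""
    return trials[~trials["participant_id"].isin(screen.excluded_ids)].reset_index(drop=True)
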