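"""Randomised split-half reliability machinery.

Two complementary analyses are provided:

* **participant-level** reliability (:func:`split_half_participants`) splits
  a task's *items* into two halves — balanced within every stratum so each
  half contains an equal mix of trial types — and correlates participants'
  accuracies on the two halves.  Because the halves share no items, the
  correlation is a lower bound on the reliability of the full-length score;
  :func:`spearman_brown` projects it back to full length.

* **item-level** reliability (:func:`split_half_items`) splits the
  *participants* into two groups (no stratification) and correlates per-item
  accuracy between groups, asking whether item difficulty is stable across
  independent samples of people.

One random split plan is drawn per call, mirroring a single randomised
split-half analysis; :func:`average_split_half_r` optionally averages the
correlation over several independent plans for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PhysepError, UndefinedCorrelationError
from .utils import as_seed_sequence


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of each primary item of one task to half 'A' or 'B'.

    Within every stratum the two halves differ by at most one item (exactly
    equal for even strata).  The same plan applies to all participants.
    """

    task: str
    assignment: dict[str, str]

    def half(self, label: str) -> list[str]:
        return [item for item, h in self.assignment.items() if h == label]


def _task_primary(trials: pd.DataFrame, task: str) -> pd.DataFrame:
    sub = trials[(trials["task"] == task) & (trials["unit_kind"] == "primary")]
    if sub.empty:
        raise PhysepError(f"no primary units for task {task!r}")
    return sub


def stratified_split(trials: pd.DataFrame, task: str, seed=None) -> SplitPlan:
    """Randomly split a task's items into halves, balanced within strata.

    Every stratum must contain at least 2 items.  Odd strata put the extra
    item in a randomly chosen half.
    """
    sub = _task_primary(trials, task)
    items = sub[["item_id", "stratum"]].drop_duplicates().sort_values("item_id")
    rng = np.random.default_rng(as_seed_sequence(seed))

    assignment: dict[str, str] = {}
    for stratum, group in items.groupby("stratum", sort=True):
        ids = group["item_id"].to_numpy()
        if len(ids) < 2:
            raise PhysepError(
                f"stratum {stratum!r} of task {task} has {len(ids)} item(s); "
                "cannot form balanced halves"
            )
        rng.shuffle(ids)
        n_a = len(ids) // 2
        if len(ids) % 2 == 1 and rng.random() < 0.5:
            n_a += 1
        for item in ids[:n_a]:
            assignment[item] = "A"
        for item in ids[n_a:]:
            assignment[item] = "B"
    return SplitPlan(task=task, assignment=assignment)


def half_accuracies(trials: pd.DataFrame, plan: SplitPlan) -> tuple[pd.Series, pd.Series]:
    """Per-participant accuracy on each half of a split plan.

    Returns two Series indexed by participant_id, in the same (sorted) order.
    """
    sub = _task_primary(trials, plan.task)
    halves = []
    for label in ("A", "B"):
        ids = plan.half(label)
        acc = (
            sub[sub["item_id"].isin(ids)]
            .groupby("participant_id", sort=True)["correct"]
            .mean()
        )
        halves.append(acc)
    a, b = halves
    if not a.index.equals(b.index):
        raise PhysepError(f"participants differ between halves of task {plan.task}")
    return a, b


@dataclass(frozen=True)
class SplitHalfResult:
    """Correlation between two independent halves, with permutation p.

    ``n_units`` is the number of paired observations correlated
    (participants for a trial split, items for a participant split).
    ``corrected_r`` is the Spearman-Brown projection to full length —
    reported alongside, never instead of, the raw half-length ``r``.
    """

    r: float
    p_perm: float
    n_units: int
    half_a: pd.Series
    half_b: pd.Series
    corrected_r: float
    plan: SplitPlan | None = None


def spearman_brown(r: float) -> float:
    """Predicted full-length reliability from a half-length correlation r.

    ``2r / (1 + r)``; undefined at r = -1.
    """
    if r == -1.0:
        raise UndefinedCorrelationError("Spearman-Brown correction undefined at r = -1")
    if not -1.0 <= r <= 1.0:
        raise UndefinedCorrelationError(f"correlation must be in [-1, 1], got {r}")
    return 2.0 * r / (1.0 + r)


def split_half_participants(
    trials: pd.DataFrame, task: str, seed=None, n_iter_perm: int = 10_000
) -> SplitHalfResult:
    """Trial-split reliability: correlate half accuracies across participants."""
    from .inference import permutation_test

    ss = as_seed_sequence(seed)
    split_ss, perm_ss = ss.spawn(2)
    plan = stratified_split(trials, task, seed=split_ss)
    a, b = half_accuracies(trials, plan)
    perm = permutation_test(a.to_numpy(), b.to_numpy(), n_iter=n_iter_perm, seed=perm_ss)
    return SplitHalfResult(
        r=perm.observed_stat,
        p_perm=perm.p_two_tailed,
        n_units=len(a),
        half_a=a,
        half_b=b,
        corrected_r=spearman_brown(perm.observed_stat),
        plan=plan,
    )


def split_half_items(
    trials: pd.DataFrame, task: str, seed=None, n_iter_perm: int = 10_000
) -> SplitHalfResult:
    """Participant-split reliability: correlate per-item accuracy across groups.

    Participants are halved at random without stratification; each group
    must contain at least 2 participants and the task at least 3 items.
    """
    from .inference import permutation_test

    sub = _task_primary(trials, task)
    pids = np.sort(sub["participant_id"].unique())
    if len(pids) < 4:
        raise PhysepError("need at least 4 participants (2 per group) for an item split")
    if sub["item_id"].nunique() < 3:
        raise PhysepError("need at least 3 items for an item-level split half")

    ss = as_seed_sequence(seed)
    split_ss, perm_ss = ss.spawn(2)
    rng = np.random.default_rng(split_ss)
    rng.shuffle(pids)
    g1, g2 = pids[: len(pids) // 2], pids[len(pids) // 2 :]

    acc1 = sub[sub["participant_id"].isin(g1)].groupby("item_id", sort=True)["correct"].mean()
    acc2 = sub[sub["participant_id"].isin(g2)].groupby("item_id", sort=True)["correct"].mean()
    perm = permutation_test(acc1.to_numpy(), acc2.to_numpy(), n_iter=n_iter_perm, seed=perm_ss)
    return SplitHalfResult(
        r=perm.observed_stat,
        p_perm=perm.p_two_tailed,
        n_units=len(acc1),
        half_a=acc1,
        half_b=acc2,
        corrected_r=spearman_brown(perm.observed_stat),
        plan=None,
    )


def average_split_half_r(
    trials: pd.DataFrame, task: str, seed=None, n_plans: int = 1
) -> float:
    """Mean split-half correlation over ``n_plans`` independent split plans."""
    from .inference import pearson_r

    ss = as_seed_sequence(seed)
    rs = []
    for child in ss.spawn(n_plans):
        plan = stratified_split(trials, task, seed=child)
        a, b = half_accuracies(trials, plan)
        rs.append(pearson_r(a.to_numpy(), b.to_numpy()))
    return float(np.mean(rs))
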