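"""End-to-end orchestration: simulate/load -> screen -> score -> reliability
-> task intercorrelations -> model comparison -> residual separability.

The pipeline produces a JSON-serialisable report mirroring the sequence of
an individual-differences analysis: cohort bookkeeping, per-task accuracy
summaries and split-half reliabilities, the full 5x5 task intercorrelation
matrix with permutation p values, AIC/F comparisons of one- versus
two-predictor models within the spatial and working-memory domains, and the
residual split-half separability test of the towers task.

All randomness flows from a single master seed, split into per-stage child
streams, so the whole report is reproducible from the seed recorded inside
it.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import inference, reliability, scoring
from .cohort import (
    TRIAL_COLUMNS,
    TASKS,
    CohortConfig,
    draw_abilities,
    scheduled_units,
    simulate_trials,
)
from .errors import BookkeepingError, TrialTableError

log = logging.getLogger("physep")


def retained_n(completers: int, exclusions: Iterable[int]) -> int:
    """Participants remaining after subtracting every exclusion category."""
    exclusions = list(exclusions)
    if completers < 0 or any(e < 0 for e in exclusions):
        raise BookkeepingError("counts must be non-negative")
    remaining = completers - sum(exclusions)
    if remaining < 0:
        raise BookkeepingError(
            f"exclusions ({sum(exclusions)}) exceed completers ({completers})"
        )
    return remaining


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trial table CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str, "stratum": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialTableError(f"trial table is missing column(s): {sorted(missing)}")
    df = df[list(TRIAL_COLUMNS)]

    unknown = set(df["task"]) - set(TASKS)
    if unknown:
        raise TrialTableError(f"unknown task label(s): {sorted(unknown)}")
    bad_kind = set(df["unit_kind"]) - {"primary", "secondary"}
    if bad_kind:
        raise TrialTableError(f"unknown unit_kind value(s): {sorted(bad_kind)}")
    if not df["correct"].isin((0, 1)).all():
        raise TrialTableError("column 'correct' must be binary (0/1)")
    dup = df.duplicated(subset=["participant_id", "task", "item_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TrialTableError(
            f"duplicate unit: participant {row['participant_id']} task {row['task']} "
            f"item {row['item_id']}"
        )
    return df


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def run_pipeline(source, seed: int = 0, n_perm: int = 10_000) -> dict:
    """Run the full analysis chain and return the report as a dict.

    Parameters
    ----------
    source
        A :class:`CohortConfig` (a cohort is simulated with a seed derived
        from ``seed``), a trial-table DataFrame, or a path to a trial-table
        CSV.
    seed
        Master seed; per-stage streams are spawned from it.
    n_perm
        Permutation iterations for every significance test.
    """
    master = np.random.SeedSequence(seed)
    (
        sim_ss,
        rel_ss,
        item_ss,
        corr_ss,
        resid_ss,
    ) = master.spawn(5)

    config_json = None
    if isinstance(source, CohortConfig):
        sim_seed = int(sim_ss.generate_state(1)[0] % (2**31))
        config = source.model_copy(update={"seed": sim_seed})
        config_json = config.model_dump(mode="json")
        log.info("stage=simulate n=%d seed=%d", config.n_participants, sim_seed)
        trials = simulate_trials(draw_abilities(config), config)
        expected = scheduled_units(config)
    else:
        trials = source if isinstance(source, pd.DataFrame) else read_trial_table(source)
        expected = None
        log.info("stage=load n_rows=%d", len(trials))

    n_input = trials["participant_id"].nunique()

    log.info("stage=screen k_sd=5")
    screen = scoring.screen_participants(trials)
    retained = scoring.apply_screen(trials, screen)

    log.info("stage=score")
    scores = scoring.score_primary(retained, expected_units=expected)
    scores = scores.sort_values("participant_id").reset_index(drop=True)
    tasks = [t for t in TASKS if t in scores.columns]

    accuracy_summary = {
        task: {
            "mean": float(scores[task].mean()),
            "sd": float(scores[task].std(ddof=1)),
            "min": float(scores[task].min()),
            "max": float(scores[task].max()),
            "chance": scoring.chance_level(task),
        }
        for task in tasks
    }

    log.info("stage=reliability n_perm=%d", n_perm)
    rel_children = rel_ss.spawn(len(tasks))
    rel_block = {}
    for task, child in zip(tasks, rel_children):
        res = reliability.split_half_participants(retained, task, seed=child, n_iter_perm=n_perm)
        rel_block[task] = {
            "r": res.r,
            "p_perm": res.p_perm,
            "spearman_brown": res.corrected_r,
            "n_units": res.n_units,
        }

    item_block = {}
    if "towers" in tasks:
        res = reliability.split_half_items(retained, "towers", seed=item_ss, n_iter_perm=n_perm)
        item_block["towers"] = {
            "r": res.r,
            "p_perm": res.p_perm,
            "spearman_brown": res.corrected_r,
            "n_units": res.n_units,
        }

    log.info("stage=correlations")
    pairs = list(combinations(tasks, 2))
    extra = [
        ("towers", pred)
        for pred in ("combined_spatial", "combined_wm")
        if "towers" in tasks and pred in scores.columns
    ]
    corr_children = corr_ss.spawn(len(pairs) + len(extra))
    corr_block = {}
    for (a, b), child in zip(pairs + extra, corr_children):
        perm = inference.permutation_test(
            scores[a].to_numpy(), scores[b].to_numpy(), n_iter=n_perm, seed=child
        )
        corr_block[f"{a}~{b}"] = {"r": perm.observed_stat, "p_perm": perm.p_two_tailed}

    log.info("stage=model_comparison")
    model_block = {}
    if "towers" in tasks:
        y = scores["towers"].to_numpy()
        domains = {
            "spatial": ("paper_folding", "mental_rotation"),
            "working_memory": ("wm_verbal", "wm_spatial"),
        }
        for domain, (first, second) in domains.items():
            if first not in scores.columns or second not in scores.columns:
                continue
            red = inference.ols_fit(y, scores[[first]], names=(first,))
            full = inference.ols_fit(y, scores[[first, second]], names=(first, second))
            cmp_ = inference.nested_f_test(red, full)
            model_block[domain] = {
                "reduced_predictors": [first],
                "full_predictors": [first, second],
                "aic_reduced": cmp_.aic_reduced,
                "aic_full": cmp_.aic_full,
                "evidence_ratio": cmp_.evidence_ratio,
                "favored": cmp_.favored,
                "f": cmp_.f_stat,
                "df": [cmp_.df_num, cmp_.df_den],
                "p": cmp_.p_value,
            }

    resid_block = None
    if "towers" in tasks and "combined_spatial" in scores.columns and "combined_wm" in scores.columns:
        log.info("stage=residual_separability")
        res = inference.residual_separability(
            retained, scores, seed=resid_ss, n_iter_perm=n_perm
        )
        resid_block = {
            "r_resid": res.r_resid,
            "p_perm": res.p_perm,
            "n_participants": res.n_participants,
            "coefficients_half_a": res.fit_a.coefficients.tolist(),
            "coefficients_half_b": res.fit_b.coefficients.tolist(),
            "predictors": ["combined_spatial", "combined_wm"],
        }

    return {
        "seed": seed,
        "n_perm": n_perm,
        "config": config_json,
        "cohort": {
            "n_input": int(n_input),
            "n_excluded_screen": len(screen.excluded_ids),
            "excluded_ids": list(screen.excluded_ids),
            "screen_thresholds": screen.thresholds,
            "n_retained": int(scores.shape[0]),
        },
        "accuracy_summary": accuracy_summary,
        "reliability": rel_block,
        "item_reliability": item_block,
        "correlations": corr_block,
        "model_comparisons": model_block,
        "residual_separability": resid_block,
    }


def render_report(report: dict) -> str:
    """Human-readable text summary of a pipeline report."""
    lines = []
    cohort = report["cohort"]
    lines.append(
        f"Cohort: {cohort['n_input']} participants in, "
        f"{cohort['n_excluded_screen']} excluded by the secondary screen, "
        f"{cohort['n_retained']} retained."
    )
    lines.append("")
    lines.append("Task accuracy (mean +/- SD, chance):")
    for task, s in report["accuracy_summary"].items():
        lines.append(
            f"  {task:16s} {s['mean']:.3f} +/- {s['sd']:.3f}  (chance {s['chance']:.4g})"
        )
    lines.append("")
    lines.append("Split-half reliability (trial split; Spearman-Brown in brackets):")
    for task, r in report["reliability"].items():
        lines.append(
            f"  {task:16s} r = {r['r']:+.3f} [{r['spearman_brown']:+.3f}], "
            f"p_perm = {r['p_perm']:.4g}"
        )
    if report["item_reliability"]:
        lines.append("")
        for task, r in report["item_reliability"].items():
            lines.append(
                f"Item-level split-half ({task}): r = {r['r']:+.3f}, "
                f"p_perm = {r['p_perm']:.4g} across {r['n_units']} items"
            )
    lines.append("")
    lines.append("Task intercorrelations (permutation p):")
    for pair, c in report["correlations"].items():
        lines.append(f"  {pair:36s} r = {c['r']:+.3f}, p = {c['p_perm']:.4g}")
    if report["model_comparisons"]:
        lines.append("")
        lines.append("Nested model comparisons (predicting towers accuracy):")
        for domain, m in report["model_comparisons"].items():
            lines.append(
                f"  {domain}: AIC {m['aic_reduced']:.2f} (1 predictor) vs "
                f"{m['aic_full']:.2f} (2 predictors); evidence ratio "
                f"{m['evidence_ratio']:.1f} favoring the {m['favored']} model; "
                f"F({m['df'][0]},{m['df'][1]}) = {m['f']:.2f}, p = {m['p']:.3g}"
            )
    if report["residual_separability"]:
        r = report["residual_separability"]
        lines.append("")
        lines.append(
            f"Residual separability: r_resid = {r['r_resid']:+.3f}, "
            f"p_perm = {r['p_perm']:.4g} "
            f"(n = {r['n_participants']}; towers residuals after regressing out "
            "combined spatial and working-memory scores)"
        )
    return "\n".join(lines) + "\n"
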