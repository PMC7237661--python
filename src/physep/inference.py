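"""Statistical core: Pearson correlation with permutation-null inference,
OLS fits with a Gaussian-profile AIC, nested-model comparison, and the
residual split-half separability procedure.

Significance everywhere is non-parametric: the null distribution of a
statistic is generated by shuffling the participant correspondence of one
variable (10,000 iterations by default) and the two-tailed p value is the
proportion of null statistics strictly larger in absolute value than the
observed one.

The headline procedure, :func:`residual_separability`, asks whether a task
measures an ability the other tasks do not: split the towers trials into two
balanced halves, regress each half's per-participant accuracy on the
combined spatial and working-memory scores (computed once from the full
data of the other four tasks), and correlate the two residual vectors.
Because the halves share no trials, binomial measurement noise is
independent between them, and any reliable residual correlation reflects
systematic variance not captured by the predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    AICUndefinedError,
    NonNestedModelsError,
    PhysepError,
    UndefinedCorrelationError,
)
from .utils import as_seed_sequence

_RSS_TOL = 1e-12


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation, with degenerate inputs rejected.

    Raises :class:`UndefinedCorrelationError` for vectors shorter than 3,
    unequal lengths, or zero variance in either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic with its shuffled-label null distribution."""

    observed_stat: float
    null_stats: np.ndarray
    p_two_tailed: float
    n_iter: int
    seed: int | None


def permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] = pearson_r,
    n_iter: int = 10_000,
    seed=None,
    smoothed: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test by shuffling y's participant labels.

    On each iteration y is randomly re-ordered against x and the statistic
    recomputed; p is the proportion of null values strictly larger in
    absolute value than the observed one (set ``smoothed=True`` for the
    add-one estimator ``(count + 1) / (n_iter + 1)`` instead).

    The default statistic is :func:`pearson_r`, for which a vectorised path
    is used; any other deterministic ``statistic(x, y)`` is supported via a
    Python loop.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_iter < 1:
        raise PhysepError("n_iter must be >= 1")
    observed = statistic(x, y)

    ss = as_seed_sequence(seed)
    rng = np.random.default_rng(ss)
    n = len(y)
    if statistic is pearson_r:
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        perm = np.argsort(rng.random((n_iter, n)), axis=1)
        null = zy[perm] @ zx / n
    else:
        null = np.empty(n_iter)
        for i in range(n_iter):
            null[i] = statistic(x, y[rng.permutation(n)])

    count = int(np.sum(np.abs(null) > abs(observed)))
    p = (count + 1) / (n_iter + 1) if smoothed else count / n_iter
    return PermutationResult(
        observed_stat=float(observed),
        null_stats=null,
        p_two_tailed=float(p),
        n_iter=n_iter,
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )


@dataclass(frozen=True)
class LinearFit:
    """Ordinary-least-squares solution with the pieces model comparison needs.

    ``k`` counts estimated mean-model coefficients (intercept included);
    the AIC additionally counts the error-variance parameter:
    ``AIC = n * ln(RSS / n) + 2 * (k + 1)``, the Gaussian profile-likelihood
    form with constants dropped.  Only AIC *differences* matter downstream.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    rss: float
    n: int
    k: int
    names: tuple[str, ...] = ()

    @property
    def aic(self) -> float:
        if self.rss <= _RSS_TOL:
            raise AICUndefinedError(
                "AIC undefined: residual sum of squares is zero (saturated fit)"
            )
        return self.n * float(np.log(self.rss / self.n)) + 2.0 * (self.k + 1)


def ols_fit(
    y: Sequence[float],
    X: Sequence[Sequence[float]] | np.ndarray | pd.DataFrame,
    include_intercept: bool = True,
    names: Sequence[str] | None = None,
) -> LinearFit:
    """Fit y on the columns of X by ordinary least squares.

    ``X`` is an (n, p) regressor array (a 1-D vector is treated as a single
    regressor).  Raises on rank-deficient designs and on n <= k.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    names = tuple(names)
    design = sm.add_constant(X, has_constant="raise") if include_intercept else X
    if include_intercept:
        names = ("intercept",) + names
    k = design.shape[1]
    if n <= k:
        raise PhysepError(f"need more observations ({n}) than coefficients ({k})")
    if np.linalg.matrix_rank(design) < k:
        raise PhysepError("design matrix is rank deficient")

    res = sm.OLS(y, design).fit()
    return LinearFit(
        coefficients=np.asarray(res.params, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        rss=float(res.ssr),
        n=n,
        k=k,
        names=names,
    )


@dataclass(frozen=True)
class EvidenceRatio:
    """Relative likelihood ``exp(|dAIC| / 2)`` in favor of the lower-AIC model."""

    ratio: float
    favored: str  # "a", "b", or "tie"


def evidence_ratio(aic_a: float, aic_b: float) -> EvidenceRatio:
    """Akaike evidence ratio between two models given their AICs."""
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise PhysepError("AIC values must be finite")
    ratio = float(np.exp(abs(aic_a - aic_b) / 2.0))
    if aic_a < aic_b:
        favored = "a"
    elif aic_b < aic_a:
        favored = "b"
    else:
        favored = "tie"
    return EvidenceRatio(ratio=ratio, favored=favored)


@dataclass(frozen=True)
class ModelComparison:
    """Nested-model F test plus AIC evidence ratio for the same pair."""

    aic_reduced: float
    aic_full: float
    evidence_ratio: float
    favored: str  # "reduced" or "full" (or "tie")
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def nested_f_test(reduced: LinearFit, full: LinearFit) -> ModelComparison:
    """F test for the extra coefficients of ``full`` over ``reduced``.

    ``F = ((RSS_r - RSS_f) / dk) / (RSS_f / (n - k_f))`` on
    ``(dk, n - k_f)`` degrees of freedom.
    """
    if reduced.n != full.n:
        raise NonNestedModelsError("fits are on different numbers of observations")
    if full.k <= reduced.k:
        raise NonNestedModelsError("the full model must estimate more coefficients")
    if reduced.names and full.names and not set(reduced.names) <= set(full.names):
        raise NonNestedModelsError(
            f"reduced regressors {reduced.names} are not a subset of {full.names}"
        )
    if full.rss > reduced.rss + 1e-9 * max(1.0, reduced.rss):
        raise NonNestedModelsError("full-model RSS exceeds reduced-model RSS; models not nested")

    dk = full.k - reduced.k
    df_den = full.n - full.k
    rss_f = full.rss
    f_stat = max(0.0, (reduced.rss - rss_f) / dk) / (rss_f / df_den)
    p = float(stats.f.sf(f_stat, dk, df_den))

    er = evidence_ratio(reduced.aic, full.aic)
    favored = {"a": "reduced", "b": "full", "tie": "tie"}[er.favored]
    return ModelComparison(
        aic_reduced=reduced.aic,
        aic_full=full.aic,
        evidence_ratio=er.ratio,
        favored=favored,
        f_stat=float(f_stat),
        df_num=dk,
        df_den=df_den,
        p_value=p,
    )


@dataclass(frozen=True)
class ResidualReliabilityResult:
    """Residual split-half correlation and its permutation inference."""

    r_resid: float
    p_perm: float
    fit_a: LinearFit
    fit_b: LinearFit
    plan: "SplitPlan"  # noqa: F821 - forward ref; see physep.reliability
    n_participants: int
    permutation: PermutationResult = field(repr=False, default=None)


def residual_separability(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    seed=None,
    n_iter_perm: int = 10_000,
    task: str = "towers",
) -> ResidualReliabilityResult:
    """Split-half test for task variance unexplained by the other measures.

    Steps: (1) split the task's trials into stratum-balanced halves;
    (2) compute each participant's accuracy on each half; (3) regress each
    half on ``combined_spatial`` and ``combined_wm`` from ``scores`` (full
    data of the other four tasks, computed once); (4) correlate the two
    residual vectors; (5) permutation p by shuffling the participant
    correspondence between the residual vectors.
    """
    from .reliability import half_accuracies, stratified_split

    for col in ("combined_spatial", "combined_wm"):
        if col not in scores:
            raise PhysepError(f"scores table lacks required predictor column {col!r}")

    ss = as_seed_sequence(seed)
    split_ss, perm_ss = ss.spawn(2)

    scores = scores.sort_values("participant_id").reset_index(drop=True)
    trials = trials[trials["participant_id"].isin(scores["participant_id"])]
    plan = stratified_split(trials, task, seed=split_ss)
    acc_a, acc_b = half_accuracies(trials, plan)
    acc_a = acc_a.reindex(scores["participant_id"]).to_numpy()
    acc_b = acc_b.reindex(scores["participant_id"]).to_numpy()
    if np.isnan(acc_a).any() or np.isnan(acc_b).any():
        raise PhysepError("some scored participants have no trials in one half")

    X = scores[["combined_spatial", "combined_wm"]]
    fit_a = ols_fit(acc_a, X)
    fit_b = ols_fit(acc_b, X)
    perm = permutation_test(
        fit_a.residuals, fit_b.residuals, n_iter=n_iter_perm, seed=perm_ss
    )
    return ResidualReliabilityResult(
        r_resid=perm.observed_stat,
        p_perm=perm.p_two_tailed,
        fit_a=fit_a,
        fit_b=fit_b,
        plan=plan,
        n_participants=len(scores),
        permutation=perm,
    )
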