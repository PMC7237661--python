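# Methods

## The analysis problem

Given trial-level accuracy from a five-task battery — unstable-towers
physical prediction, paper folding, mental rotation, and spatial and verbal
complex span — the pipeline asks three questions in sequence: (1) are the
measures reliable enough to carry individual differences (split-half
reliability)? (2) how do the tasks intercorrelate, and within a domain does
a second task add predictive information about towers performance (AIC /
nested-F model comparison)? (3) is there reliable towers variance left after
regressing out the combined spatial and working-memory scores (residual
split-half separability)?

## Generative model for synthetic cohorts

Each participant i has latent abilities (s_i, w_i) drawn from a bivariate
normal with configurable SDs and correlation ρ, plus an independent
physics-unique factor u_i ~ N(0, σ_u²). Task true scores are linear:
θ_task = l_s·s + l_w·w + l_u·u, with l_u ≠ 0 permitted only for the towers
task. A scoring unit j is answered correctly with probability

    P_ij = c_task + (1 − c_task) · logistic(θ_task,i − b_j),

the three-parameter-logistic response function. This is the simplest family
that produces the features the analysis depends on: per-task guessing floors
set by the response format, graded above-floor performance, and
heterogeneous item difficulty (b_j ~ N(m_task, sd_task), drawn once per
cohort, which is what makes item-level split-half correlations high).
Working-memory trials shift b linearly in set size (slope 0.35 per item,
centered at 5.5) so longer spans are harder; trial correctness is modeled
directly at the span-trial level because the scoring rule is exact-set
(all-or-none), not per-element. The two selections of a mental-rotation item
are conditionally independent given θ — the "select exactly two options"
constraint lives in the schedule, not the response model.

Secondary judgements (132 symmetry, 132 lexical) are Bernoulli at a stable
per-participant accuracy ~ N(0.93, 0.03) clipped to [0, 1]; designated
outlier participants can be forced to a low accuracy to exercise the screen.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| n_participants | 100 | standard battery cohort size |
| schedule | 48 towers (12 strata of 4: six block counts × two sides), 20 paper folding, 48 MR selections, 24 span trials per WM task (4 × set sizes 3–8) | the battery's design |
| chance floors | 0.5, 0.2, 0.5, 2⁻¹², 2⁻¹² | analytic per response format |
| latent_corr ρ | 0.3 | modest spatial–WM association |
| loadings | towers (s 0.6, u 0.6); spatial 0.9 on s; WM 1.1 on w | see below |
| item difficulty mean / SD | −0.33/1, 0/1, −0.4/1, −0.5/0.5 (×2 WM) | accuracies between chance and ceiling |
| secondary accuracy | mean 0.93, SD 0.03 | high but variable compliance |
| seed | 0 | all randomness flows from one seed |

Loadings and difficulties are illustrative, not fitted — no per-task
accuracy distributions exist to calibrate against beyond the towers task.
They were chosen once so that the default cohort lands near the published
towers operating point (simulated mean accuracy ≈ 0.78, SD ≈ 0.10) and
reproduces the qualitative intercorrelation pattern: spatial tasks correlate
with towers and each other; the span tasks correlate strongly with each
other, weakly with spatial, and near zero with towers. With the default
u-loading of 0.6 latent-SD the residual split-half correlation comes out
near 0.45 at n = 100 — the regime of interest.

What the generator deliberately does **not** emulate: response times, trial
order and practice effects, participant dropout or comprehension failures
(the screen only sees secondary-task accuracy), within-item dependencies in
mental rotation, and per-element recall dynamics in the span tasks. Passing
recovery tests therefore shows the *analysis chain* is correct and
calibrated under the stated measurement model, not that real data satisfy
that model.

## Scoring and screening choices

* Accuracy = correct units / scheduled units; missing scheduled units are an
  error naming the participant and task, never silently renormalized.
* Combined predictors are plain arithmetic means of the two task accuracies
  in each domain.
* Screening thresholds (mean − k·SD, k = 5, sample SD) are computed once on
  the full cohort, per secondary measure, and a participant is excluded if
  below threshold on **either** measure (the OR rule is the conservative
  reading for data quality). A measure with zero spread excludes no one.
  Single-pass screening makes the operation idempotent by construction.

## Statistical machinery

* **Split plans.** Items are shuffled within each stratum and dealt into
  halves; strata differ by at most one item between halves (exactly equal
  for the battery's even strata). The towers split stratifies jointly on
  block-count × outcome side (strata of 4). One plan is drawn per analysis
  call; `average_split_half_r` averages over plans when a stabler point
  estimate is wanted. Item-level splits halve participants without
  stratification.
* **Permutation p.** Two-tailed, strict inequality: p = #(|null| > |obs|) /
  n_iter, so ties do not count against the observed value; an add-one
  smoothed option exists but is off by default. Shuffling one vector's
  participant labels is equivalent to shuffling the correspondence between
  the paired measurements.
* **AIC.** Gaussian profile form n·ln(RSS/n) + 2(k+1), counting the error
  variance as a parameter. Constants cancel in ΔAIC, which is all the
  evidence ratio exp(|ΔAIC|/2) uses. A saturated fit (RSS = 0) raises rather
  than reporting −∞.
* **Nested F.** F = ((RSS_r − RSS_f)/Δk) / (RSS_f/(n − k_f)) on
  (Δk, n − k_f) degrees of freedom — at n = 100 with two predictors this is
  (1, 97).
* **Residual separability.** The spatial/WM predictors enter both half-fits
  as *full-data* combined scores: only the towers trials are split, so the
  predictors cannot be half-specific. Residuals inherit independence of
  measurement noise from the disjoint trial halves; the permutation null
  shuffles the correspondence between the two residual vectors.
* **Degenerate inputs** (constant vectors, rank-deficient designs, singleton
  strata) raise typed errors; no NaN sentinels.

## Numerical and design notes

* All randomness descends from integer seeds through `numpy` SeedSequence
  spawning; the pipeline records the derived simulation seed in its report,
  so any report is exactly reproducible from its own provenance block.
* Trial tables are validated on read (column set, task labels, binary
  outcomes, duplicate units) before any statistic is computed.
* OLS is delegated to statsmodels; tests verify coefficients and RSS against
  direct normal-equation solutions and residual orthogonality to the design.

## Validation strategy and problem sizes

The test suite validates the chain at three levels, with sizes chosen to
keep the full run to a few minutes:

1. **Exact oracles** — chance levels against exhaustive enumeration (all
   2¹² response subsets; all 6 option pairs), permutation p against all 120
   pairings at n = 5, OLS against normal equations, evidence ratios against
   the printed-AIC arithmetic.
2. **Calibration** — type-I error of the permutation correlation test at
   α = .05 over 500 null simulations (n = 200, 2,000 iterations each);
   simulated split-half r against the analytic half-test reliability
   var(true half score) / var(observed half score) obtained by quadrature
   over the latent ability (within ±0.03 at 2,000 participants), plus
   monotonicity of expected r in true-score variance.
3. **Parameter recovery** — the residual-separability procedure over
   replicate cohorts: with the default unique loading (0.6 latent-SD,
   n = 100, 48 towers trials) it is significant in ≥ 90% of 100 replicates;
   with zero unique loading and predictor item counts scaled ×20 (so the
   combined predictors are nearly noise-free and the residuals are pure
   binomial noise) its false-positive rate over 200 replicates stays inside
   the 99% binomial band around 5%.

## Known limitations

* With realistic (finite) predictor item counts, the combined spatial score
  measures s with error, so under a *true* null some correlated spatial
  variance survives regression in both towers halves and the residual test
  is anticonservative — an attenuation property of any residualization
  approach, which is why the null-calibration check uses near-noise-free
  predictors. Interpreting a small residual correlation on real data
  requires the predictors' reliabilities to be high.
* Power at the recovery margin is steep: at a unique loading of 0.5
  latent-SD (rather than the default 0.6) the significance rate in the same
  design drops to roughly the mid-80s percent.
* The 3PL model treats guessing as a floor mixture; formats where errors are
  systematic rather than random (e.g., near-miss tower predictions) are not
  distinguished.
* Spearman–Brown values are reported alongside raw split-half correlations,
  never substituted for them.
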