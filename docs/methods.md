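# Methods

## Problem and model

`covproj` quantifies how much of the association pattern between a single
outcome *y* (e.g. HOMA-IR, the homeostatic model assessment of insulin
resistance) and a multicollinear explanatory block **X** (e.g. 26
NMR-derived lipoprotein features) is carried by covariates — including
covariate groups that are themselves strongly multicollinear (three
adiposity measures) or exactly linearly dependent (23 physical-activity
intensity bins that sum to the daily total) — and produces the *net*
association pattern after those covariate subspaces are projected out.

The building blocks:

1. **PLS1 regression.** NIPALS with X-deflation: for component *a*,
   `w_a ∝ X_a' y`, `t_a = X_a w_a`, `p_a = X_a' t_a / (t_a' t_a)`,
   `q_a = y' t_a / (t_a' t_a)`, `X_{a+1} = X_a − t_a p_a'`. The regression
   vector is `b = W (P'W)⁻¹ q` (triangular solve; `P'W` is unit upper
   triangular). For one response every mainstream PLS variant yields the
   same `b`; NIPALS is used for transparency. y is not deflated.

2. **Component count by Monte-Carlo resampling.** Repeated random
   half-splits (default 1000 repetitions, 50% holdout, no stratification).
   Per repetition the median squared holdout error is recorded for the
   mean-only model (A = 0) and A = 1..A_max; the curve
   `RMedSEP[A] = sqrt(median over repetitions)` is minimized, and the
   selected A is the largest value at or below the minimum whose every
   incremental component *clearly* improves prediction (next section).

3. **Target projection (TP).** A validated PLS model is condensed to one
   predictive component: `w_tp = b/‖b‖`, `t_tp = X w_tp`,
   `p_tp = X' t_tp/(t_tp' t_tp)`. The TP score carries all the predictive
   information of the model (`t_tp‖b‖ = X b` exactly), which is what makes
   a single score usable as a stand-in for a whole covariate block.

4. **Covariate projection (CP).** The covariates, the outcome and the
   explanatory block are collected in one centered augmented matrix and
   deflated by one rank-one step per covariate: the step score is the
   covariate's current residual column (or, for a multivariate group, the
   standardized TP score of a PLS model of the current residual outcome on
   the group's current residual block), the loading is
   `p = E' t/(t' t)`, and `E ← E − t p'`. Each step zeroes its covariate
   column exactly and residualizes every other column on it — identical to
   least-squares residualization, but performed on outcome, explanatory
   variables and remaining covariates simultaneously, so the per-column
   sums of squares removed by each step form a complete variance partition
   (the variance-plot data). Sequential CP over an orthogonal covariate
   basis equals the Moore–Penrose adjustment `M − Z Z⁻ M`.

5. **Selectivity ratio (SR) and VIP.** For the net model,
   `SR_i = ‖t_tp p_i‖² / ‖e_i‖²` (TP-explained over TP-residual sum of
   squares of variable *i*); the exported signed variant attaches
   `sign(p_tp,i)` so SR plots show direction. VIP is the standard
   weight-based importance with mean(VIP²) = 1.

## Component-selection rule

The resampling literature phrases the step criterion as "the median
prediction error must be significantly lower than for the model with one
component less". Two operationalizations are implemented and recorded in
every `ValidationCurve`:

* **`percentile-overlap` (default).** The extra component must improve the
  per-repetition median squared error in at least 75% of repetitions
  (`improvement_quantile = 0.25`). This is a materiality criterion whose
  stringency does not depend on the number of repetitions.
* **`wilcoxon`.** A paired one-sided signed-rank test at `alpha` (default
  0.05) on the per-repetition errors.

The default is the percentile rule because Monte-Carlo repetitions resample
the *same* cohort: they are not independent observations, so the nominal
level of a paired test is not interpretable and its real false-positive
rate grows with the number of repetitions. Empirically (null cohorts whose
outcome is unrelated to the explanatory block, or related only through a
fully removed confounder), the Wilcoxon rule at 0.05 certifies dataset-level
chance correlations — components explaining well under 2% of the outcome —
in roughly a quarter of cohorts, while a strict 95%-of-repetitions rule
conversely rejects genuine signals of ~10–20% explained variance. The 75%
materiality threshold keeps null selections at or below the ~5% level while
detecting every planted signal in the recovery designs. The quantile, the
alternative rule, `alpha`, repetitions and holdout fraction are all exposed
(`ValidationConfig`, CLI flags).

## Pretreatment

All variables except those explicitly exempted (age, the 0/1 sex indicator)
are log-transformed, then every variable is mean-centered and scaled to
unit sample variance (`ddof = 1`); TP scores used in CP are standardized
the same way (projection residuals are invariant to the score's scaling, so
this affects only the variance bookkeeping). Every "% of variance" figure
in the package is a ratio of column sums of squares, so the variance
divisor cancels.

Zeros before the log: variables containing values below the configured
offset (default 1/1440 — one minute as a fraction of a day, aimed at
minutes-per-day activity bins) receive that offset additively. The offset
applies to all sub-threshold values, not only exact zeros, because values
below recording resolution are measurement artifacts; without the floor a
single subnormal value can dominate an autoscaled log column. The offset is
recorded in `PreprocessState` and replayable exactly.

## Percentages reported by the pipeline

Remaining variance after adjustment and the explained variance of the net
model are both expressed as percentages of the *original* (pretreated,
unadjusted) sums of squares, so numbers are comparable across adjustment
scenarios; consequently `r2_outcome_pct = explained fraction of the net
outcome × remaining outcome fraction` exactly. Each scenario re-derives its
covariate TP scores from scratch in its own group order (scenarios are
independent runs). Sequential CP is order-dependent when covariates
correlate; attribution is first-come (default order: age, sex, adiposity,
PA), matching the variance-plot construction.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure of a pediatric
metabolic cohort (defaults = study-shaped conditions, chosen once):

* n = 841 samples; 26 positive-valued explanatory variables generated as
  `exp(latent loadings + covariate loadings + Gaussian noise)` on 2 latent
  factors, so the log-transform path is genuinely exercised;
* a 3-variable lognormal adiposity block with pairwise log-scale
  correlation 0.8 around one adiposity latent;
* a 23-bin PA spectrum drawn per subject from a Dirichlet whose
  concentration profile decays with intensity and is tilted along a PA
  latent (tilt 3.5), scaled to exactly 840 min/day — rows sum to the
  constant exactly, so the centered block has rank ≤ 22 and the linearly
  dependent covariate path is genuinely exercised. The tilt strength was
  set so the block carries its latent at a strength comparable to the
  reported target-projection summaries of real accelerometry (TP explaining
  roughly a third of the block's variance);
* an adiposity–PA latent correlation of −0.5, the magnitude implied by the
  reported ~24% of the adiposity target component explained by the PA
  spectrum (inverse adiposity / moderate-to-vigorous activity relation);
* a binary sex indicator, age uniform within a 1-year window, and a
  lognormal outcome loading on the latent factors and the covariate
  latents (defaults: β_latent = (0.5, 0.3), β_adiposity = 0.6,
  β_PA = −0.15, noise s.d. 0.5 on the log outcome).

What the generator does **not** emulate: real lipoprotein inter-feature
correlation structure beyond a low-rank factor model, measurement error in
HOMA-IR components, wear-time variation in accelerometry (daily total is
exactly constant), or non-lognormal tails. Passing recovery tests therefore
demonstrates correctness of the projection machinery and the validation
logic under the assumed structure, not performance on any particular real
cohort.

Two named experiment designs are built on the generator:

* **Pure confounding** (`pure_confounding_config`): no direct
  outcome–explanatory effect; the association exists only through the
  adiposity confounder, whose block measures its latent with high
  reliability (pairwise correlation 0.95) and which is uncoupled from the
  PA latent. After full adjustment the net model should select A = 0. The
  high reliability is essential to the design, not a convenience: a
  rank-one TP projection can only remove confounding that the covariate
  block actually measures, so with noisier covariate blocks a
  residual-confounding leak (classical measurement-error attenuation)
  remains and *is* detected at large n. This is a real limitation of any
  residualization-based adjustment and is deliberately not hidden by the
  package.
* **No confounding** (`no_confounding_config`): a genuine direct effect
  with covariates unrelated to the explanatory block; adjustment must leave
  the SR sign pattern intact.

## Numerical choices

* A residual column counts as "zeroed" when its SS drops below 1e−12 of its
  original SS; the projected column is set to exact zeros (it is
  mathematically zero).
* SR for a variable with (numerically) zero TP residual is capped at the
  sentinel 1e12 rather than emitting infinities.
* `b` is recovered from the triangular system `(P'W) c = q`, never by a
  general inverse.
* Degenerate inputs (zero-variance columns, zero regression vector,
  component counts beyond the predictive rank) raise typed errors rather
  than producing NaNs.
* All randomness flows from explicit integer seeds; per-model seeds are
  derived from the run seed and a stable model label (CRC32), so adding a
  model to a pipeline does not shift the seeds of the others.

## Problem sizes used by the test-suite and acceptance runs

Cohort-level checks run at n = 600–2000 with 80–200 Monte-Carlo repetitions;
the acceptance script uses the full study-shaped cohort (n = 841) with 1000
repetitions for the scenario pipeline and 100 repetitions across 40 seeds
for the null-rate probe. These sizes reproduce the qualitative regime of the
full protocol (the selection rule is repetition-count-stable by design)
while keeping a complete run in the tens of seconds.

## Known limitations

* Residual confounding: see the pure-confounding design above. The
  residual-covariate check (refitting the net model with the adjusted
  covariate columns appended) is the diagnostic for it.
* Sequential CP attributes shared covariate variance to the earliest group
  in the configured order; the order is a modelling decision, not a result.
* Half-split resampling validates against the cohort at hand; it cannot
  detect chance correlation at the whole-dataset level (the materiality
  rule mitigates, but external validation is the only cure).
* The study-table loader (`covproj.study`) matches the published
  supplementary spreadsheet's variable set; the spreadsheet itself is not
  redistributed and must be supplied by the user at `data/table_s1.xlsx`.
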