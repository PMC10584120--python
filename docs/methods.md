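# Methods

This note documents the models the package implements, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Starvation-survival model

Cumulative larval mortality under starvation is modelled as

    Pm(t) = 1 / (1 + (t / t50)^s),        t >= 0,  t50 > 0,  s < 0,

the CDF of a log-logistic death-time distribution with median `t50` (the
LT50, in days) and unitless slope `s` (more negative = steeper die-off).
`Pm(0) = 0` by the limit convention and `Pm(t50) = 0.5` exactly.

**Observation model.**  Trials are scored daily, so a death observed on
day `d` is interval-censored in `(d-1, d]`; larvae alive past the horizon
(49 days = 7 weeks by default) are right-censored.  The default likelihood
is therefore the interval-censored multinomial one: each death contributes
`log[Pm(d) − Pm(d−1)]` and each survivor `log[1 − Pm(49)]`.  Within a
treatment cell larvae are treated as i.i.d., so the per-cell daily death
counts (plus the censored count) are a sufficient statistic and the
likelihood is evaluated on that aggregate.  A per-insert-day
cumulative-binomial pseudo-likelihood (each day's cumulative dead out of
the initial 20 as an independent binomial draw) is available behind
`likelihood_mode="daily-binomial"` for comparison with analyses phrased
that way; its daily terms are not independent, so it is not the default.

**Factor structures.**  `t50` and `s` may each be constant, vary by embryo
treatment (E), larval treatment (L), additively (E+L), or freely per cell
(E#L).  Parameterization is dummy coding with the ambient level as
reference, on `log t50` (keeping `t50 > 0` unconstrained) and on `s`
directly; E#L uses one free parameter per cell.  Parameter counts are
1/3/3/5/9 per structure, so the ten-model candidate set has
K = 2, 4, 4, 6, 10, 4, 4, 6, 10 and 18.

**Fitting.**  Negative log-likelihood is minimized with L-BFGS-B from a
deterministic start (`log t50` = overall empirical median death day,
`s = −3`), tolerance 1e-8, with up to five seed-deterministic jittered
restarts on failure, followed by a Nelder–Mead polish (cheap, and it makes
the nested-model log-likelihood ordering robust on flat ridges).  A fitted
`s >= 0` triggers a validity warning; an all-censored cell is an error when
the model needs that cell's own `t50` (it is unidentifiable there).

**Model selection.**  `AICc = −2 lnL + 2K + 2K(K+1)/(n−K−1)` with `n` the
number of larvae under the interval likelihood (900 at design scale) and
the number of insert-day records under the daily-binomial mode; the
effective-n convention is recorded in the fit metadata.  Δ-AICc, relative
likelihoods `exp(−Δ/2)` and Akaike weights are reported, with models at
Δ < 2 flagged as an equal-support top set.  Because the original raw data
are not deposited, absolute AICc values are not reproducible; the package
validates selection behaviour by simulation at design scale instead
(see `opilio.recovery`).

## Synthetic-data generators

The generators produce inputs with the statistical structure the analyses
assume, at the study's scale; their defaults are the study conditions.

* **Survival** — continuous log-logistic death times by inversion,
  binned to days and censored at 49; 3×3 cells × 5 inserts × 20 larvae.
  Larvae are i.i.d. within a cell: the generator has no insert-level
  random effect by default (the study design does not quantify
  inter-insert overdispersion), so recovery results quantify sampling
  error only, not extra-binomial noise.
* **Morphometrics** — multivariate-normal vectors around per-treatment
  mean vectors (defaults: the published year-1 treatment means for CW,
  LSL, DSL, RDL, RSL, PL), truncated at zero by resampling rather than
  clipping so means stay unbiased; 15 specimens per treatment.  The
  default measurement SD of 0.12 mm is a realistic optical-measurement
  spread for millimetre-scale zoeae; the covariance is diagonal by
  default, so generated data lack the allometric correlation structure of
  real larvae — tests passing on these data say nothing about
  correlated-measurement behaviour beyond what the covariance argument is
  given.
* **Clutch outcomes** — Poisson totals around
  `mean_fecundity / (1 − p_nonviable − p_unhatched)` split multinomially,
  so viable counts average the requested fecundity.  Poisson is a
  one-parameter convenience; any count law with the right mean would do.
* **Water series** — daily (temperature, pH) probe rows with Gaussian
  noise and one weekly (DIC, TA) bottle row per started week, where the
  noise-free TA comes from the carbonate solver at the target conditions,
  making a zero-noise series solver-consistent by construction.

All generators are bit-reproducible under a fixed seed.

## Permutation multivariate statistics

Measurements are z-scored (n−1 denominator) before distance-based tests;
SIMPER runs on raw values.  Distances are Euclidean.

* **PERMANOVA** uses the Gower-centred matrix `G = −(1/2) J D² J` and
  sequential hat-matrix projections, so term sums of squares are
  `tr(ΔH G)` and each pseudo-F uses the residual mean square.  One or two
  crossed factors are supported; the study's female-nested embryo analysis
  is approximated by permutation *strata* (permutations restricted within
  a blocking label) rather than a full nested partitioning — a documented
  scope bound, not asserted equivalent to nested software conventions.
  With a single variable the pseudo-F equals the classical one-way F.
* **PERMDISP** embeds samples by principal coordinates (negative
  eigenvalue axes subtract in squared distance, the usual sign
  correction), computes distances to group centroids and F-tests them.
  The null permutes group labels and recomputes the distances each time;
  the cheaper permute-the-residuals scheme is available
  (`scheme="residuals"`) but is measurably anti-conservative at small
  group sizes, which is why it is not the default.
* **ANOSIM** ranks all pairwise distances with midranks for ties;
  `R = (mean between − mean within) / (M/2)`, `M = n(n−1)/2`, so
  `R ∈ [−1, 1]` with 1 at complete separation.
* **SIMPER** attributes to each variable its squared coordinate difference
  share of the squared Euclidean distance, averaged over all between-group
  pairs and normalised to sum to 100% (an absolute-difference mode exists
  behind a flag; the convention differs between software packages).  The
  percent-difference summary is `100 (mean_A − mean_B)/mean_A`, negative
  when the second group is larger.

P-values use the add-one convention `p = (b+1)/(m+1)` with `m = 9999`
permutations by default; for ≤ 8 samples `exhaustive=True` enumerates all
relabellings and returns the exact fraction.

## Univariate framework

Sums of squares are sequential (Type I) computed by least-squares
projection (rank-aware, so nested dummy blocks that overlap treatment
dummies are handled correctly); on balanced designs this coincides with
Type III, and balance is reported.  The nested ANOVA tests treatment over
the nested-unit-within-treatment mean square — the defensible reading when
units (females) are the replicates — while crossed terms use the residual.
Levene's test centres at the group mean (classic variant; median-centring
available), Anderson–Darling uses the estimated-parameters case, and the
gatekeeping rule is: Levene p ≥ α → judge the ANOVA at α = 0.05; Levene
p < α → declare the term significant only if its p-value is below the
Levene p-value.  Tukey HSD uses the studentized range (Tukey–Kramer for
unbalanced groups) with a compact letter display built over mean-sorted
groups from maximal runs of mutually non-different groups.

## Carbonate system

Constants: K1/K2 Lueker et al. (2000, total scale), K0 Weiss (1974) with
the Weiss fugacity correction (so pCO₂, not just fCO₂, is reported), KB
Dickson (1990b), KW Millero (1995), KS Dickson (1990a, free scale), KF
Perez & Fraga (1987), Ksp Mucci (1983), total boron Lee et al. (2010),
sulfate/fluoride/calcium proportional to salinity.  Surface pressure;
nutrient alkalinity assumed zero (unmeasured in such experiments).

From (pH_free, DIC): pH is converted free → total
(`pH_T = pH_F − log10(1 + S_T/K_S)`; ~0.04 units at 2 °C, ~0.11 at 25 °C),
speciation is closed-form, TA is assembled from carbonate + borate + water
+ free-proton + bisulfate + HF terms, and Ω = [Ca²⁺][CO₃²⁻]/Ksp.  From
(TA, DIC): Brent root-finding on total-scale pH in [3, 11] (the TA
residual is monotone in [H⁺], so bracketing converges whenever a root
exists), then as above; the round trip recovers pH to < 1e-6.  Salinity is
rarely reported in tank studies; the default is 32 PSU (coastal Gulf of
Alaska surface range), configurable and echoed in every output.
Validation is against the published tank tables, whose derived columns
were computed by an independent solver from the same measured pairs: all
nine treatment rows reproduce within the printed ±1 SD.

## Reproduction metrics

Pure bookkeeping: PAY = 100·yolk/egg areas; hatch counts from
`batch mass / pooled mean larval mass` (calibration batches pooled by
total mass over total count) or from mean subsample concentration × total
volume; counts round half-up at the final step only.  Hatching success,
% non-viable and % unhatched share the total-embryo denominator and so
partition 100% exactly.

## Problem sizes and determinism

The simulation studies in the acceptance checks use the design scale
(900 larvae per experiment): 100 replicates for parameter recovery per
year and 25 for the ten-model selection study — enough for median
estimates to stabilise well inside the tolerances being checked.  Null
calibration of the permutation tests uses 2000 simulated datasets of 12
samples with 99 permutations each.  Every stochastic path takes an
explicit seed; replicate seeds are spawned from a single `SeedSequence`
and kept below 2³¹.

## Limitations

* No mixed-effects/REML alternatives, no frailty or insert-level random
  effects in the survival likelihood, no Bayesian fitting.
* PERMANOVA nesting is approximated by permutation strata; full nested
  pseudo-F partitioning is out of scope.
* Non-Euclidean dissimilarities (e.g. Bray–Curtis), nMDS ordination and
  plotting are out of scope.
* The carbonate solver omits pressure corrections and nutrient
  alkalinity, and propagates no constant uncertainties.
* Published absolute fit statistics (log-likelihoods, AICc values) of the
  original experiment cannot be reproduced without its raw data; the
  package validates by simulation recovery instead.
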