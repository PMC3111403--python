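# Methods

## Dose-response model

The four-parameter logistic (4PL), in the "log(inhibitor) vs. response —
variable slope" convention:

    y(d) = bottom + (top − bottom) / (1 + 10^(h · (log10 ED50 − log10 d)))

with parameters `(bottom, top, log10_ed50, hillslope)`. Responses are in %
of vehicle control (≈100 untreated); inhibition curves therefore decrease
with dose and carry a negative hillslope `h`. The model is invariant under
swapping the asymptotes while negating `h`, so fits are canonicalised to
`top > bottom` (the covariance is transformed along with the parameters).
Dose 0 is evaluated as the analytic limit (`top` for `h < 0`) and excluded
from log-dose initialisation.

**"Percent effect"** is defined as the percentage of the fitted span
`top − bottom` suppressed, so 50% effect corresponds exactly to the ED50
and inversion has the closed form

    log10 d = log10 ED50 − log10(e / (1 − e)) / h,    e = effect/100,

which round-trips with the forward model to machine precision. Effects at
or beyond the asymptotes (≤ 0 or ≥ 100) are domain errors: the sigmoid
never attains them.

**Estimation.** Unweighted nonlinear least squares
(Levenberg–Marquardt, cost tolerance 1e-10), fitting replicate wells as
individual points (larger residual degrees of freedom than averaging
replicates first; the alternative changes the CIs, not the estimates, for
balanced designs). The warm start is deterministic: `top`/`bottom` from
the data extremes, `log10_ed50` by linear interpolation of per-dose means
to the half-span crossing, `h` from the slope of logit-transformed
responses. Covariance is `s² (JᵀJ)⁻¹` at the optimum; confidence intervals
are Wald intervals with Student-t quantiles on `n − 4` degrees of freedom.
Profile-likelihood intervals are not implemented. Zero response span, or
optimizer non-convergence, raises an explicit fit failure carrying the
optimizer diagnostics. Zero or negative responses are kept (no clipping);
weights are uniform.

## Equal-potency fixed-ratio design

Given monotherapy ED50s, mixture dose fractions are proportional to them:
`f_a = ED50_a / (ED50_a + ED50_b)`. At a total dose equal to the mean of
the ED50s each component then sits at half its own equi-effective dose, so
each drug contributes 50% of the combination's potency. A display ratio
rounds each ED50 to the nearest multiple of 5 μM with half-to-even ties
(52.5 → 50); this reproduces four of the five published reference ratios.
The fifth (ED50 63.8 printed as 60) does not follow nearest-5 rounding
under any tie rule; rather than guess the original rounding, the package
documents the discrepancy and all downstream arithmetic uses the exact
fractions — the rounded ratio is only ever a label. The "working ratio"
(e.g. 60:40 → 3:2) is the display ratio reduced to smallest integers.

## Loewe additivity and the theoretical additive curve

For a mixture of fixed composition `(f_a, f_b)` the Loewe-additive total
dose at percent effect `x` solves

    f_a Z / Dx_a + f_b Z / Dx_b = 1   ⇒   Z_add(x) = 1 / (f_a/Dx_a + f_b/Dx_b)

with `Dx_*` the equi-effective monotherapy doses from the inverted 4PL
fits. With equal-potency fractions this reduces at 50% effect to
`Z_add(50) = (ED50_a + ED50_b)/2` (verified symbolically in the test
suite). The construction is evaluated on a 1–99% effect grid in 1% steps —
dense enough for a stable refit while staying clear of the asymptote
singularities — converted to response values, and refit with a 4PL. The
additive isobole of two dissimilar sigmoids is not exactly 4PL; the refit's
maximum absolute residual is recorded so that departure is visible.

**Response scale of the additive curve.** The published workflow overlays
the additive and mixture curves on one axis but does not state the additive
curve's asymptotes; the package uses the mean of the two monotherapy
tops/bottoms by default, with a switch (`asymptotes="a" | "b"`) for either
drug's scale.

**Uncertainty propagation.** The constructed additive points are noiseless,
so the refit's own residual covariance is vanishingly small and would
drastically understate the additive curve's real uncertainty — which stems
from the monotherapy fits. The refit covariance therefore adds a
delta-method term `J C Jᵀ`, where `C` is the block covariance of the two
monotherapy fits and `J` (the sensitivity of the refit parameters to the 8
monotherapy parameters) is obtained by one-sided finite differences through
the construction. Without this term, comparing the actual mixture fit
against a pseudo-exact additive curve flags spurious differences in roughly
a quarter of Loewe-additive simulations; with it, the flag rate matches the
nominal level.

## Combination Index and the synergy verdict

    CI(x) = d1 / Dx_1 + d2 / Dx_2,    CI < 1 synergy, CI > 1 antagonism,

evaluated by default at the actual mixture's ED50 (`d1, d2` from the exact
fractions, never the rounded display ratio). CI is linear in `(d1, d2)` and
equals 1 identically on decompositions of the additive dose — a
self-consistency oracle tested across the whole effect grid.

Because CI is a positive ratio-like quantity, its uncertainty is handled on
the log scale: the delta-method variance propagates the three log10(ED50)
variances (mixture and both monotherapies),

    Var(log CI) ≈ (ln 10)² [ v_mix + (w₁² v_a + w₂² v_b) / CI² ],
    w_i = dᵢ/Dx_i,

and the interval is exponentiated. In simulation the linear-scale interval
miscovered badly (≈16% of truly additive mixtures called synergistic at a
nominal 5%); the log-scale interval is near-nominal (~1%).

**Verdict logic.** A mixture is called *synergistic* when the CI interval
falls entirely below 1, or the 95% CIs for log10(ED50) of the actual and
additive fits fail to overlap with the actual curve more potent, or the
hillslope CIs fail to overlap with the actual slope shallower (a shallower
mixture slope widens the dose span where the mixture outperforms the
additive expectation — the pattern in the motivating data, where the
additive slope was −7.6 (95% CI −10.2, −5.1) against an observed −1.9
(−2.8, −1.0)). Mirror-image evidence gives *subadditive/antagonistic*;
otherwise *additive*. The CI interval driving the verdict is two-sided 90%
(`verdict_alpha=0.10`), i.e. each directional call is a 5% test — sized so
that at most a few percent of truly additive mixtures are miscalled — while
the reported parameter-comparison flags always use conventional 95%
intervals. A bare point estimate (CI marginally below 1) never triggers a
synergy call: with noisy data half of all additive mixtures sit below 1 by
chance.

No extra-sum-of-squares F test is performed; the comparison is
parameter-wise, as in the original confidence-interval workflow.

## Synthetic data generators

All generators draw every random number from one explicit integer seed and
are bit-reproducible.

**Monotherapy** (`simulate_monotherapy`): exact 4PL responses plus
additive Gaussian noise on the %-control scale (plate-reader-like;
heteroscedastic noise is out of scope). Defaults emulate a 24 h
proliferation screen: bottom 0, top 100, hillslope −2, noise SD 5% of
control, 6 replicate wells at 8 log-spaced doses spanning 1–100 μM.

**Combination** (`simulate_combination`): a τ-Loewe interaction surface.
At total dose Z the noiseless effect `e` solves
`f_a Z/Dx_a(e) + f_b Z/Dx_b(e) = τ` (monotone bisection), so the mixture's
ground-truth Combination Index is exactly τ at every effect level: τ = 1 is
Loewe additivity (the generated curve coincides with the additive
construction to numerical precision — a cross-module consistency oracle),
τ < 1 synergy, τ > 1 antagonism. Doses outside the achievable effect range
clamp to the asymptotes with a warning. The default total-dose ladder
(8 log-spaced doses, 5–250 μM) brackets the additive reference curve of
the default drug pair (additive ED50 ≈ 51.5 μM) with margin on both sides,
so mixtures with τ between 0.25 and 2 still traverse most of their dynamic
range; a ladder truncated at 100 μM would cap an antagonistic (τ = 1.5)
mixture at ~63% effect and leave its potency shift statistically
unidentifiable.

**Microarray tables** (`simulate_feature_tables`): a shared multi-
feature-per-gene universe (feature counts uniform in a configurable range);
null features draw log2 ratios from N(0, 0.2); planted responders carry
their stated direction and magnitude (≥ 2-fold) in all three replicates
with a small upward jitter so they never dip below threshold; an optional
contradiction rate plants one consistently opposing feature on planted
genes with ≥ 2 features. P values come from a deterministic monotone map
`P = 10^(−4·|log2 ratio|)` (a 2-fold change maps to 1e-4, typical null
noise to ~0.16) because the proprietary error model that produced the
original P values is not re-derived — only its downstream filtering logic
is reproduced. The generator returns a ground-truth ledger of expected
significant and contradicted genes per treatment.

**What passing simulations do and do not show.** The generators emulate the
*structure* of plate-reader and two-channel-style array data, not their
full pathology: no plate effects, no heteroscedastic or correlated noise,
no dye bias, no missing features, and P values that are a deterministic
function of effect size. Recovery results therefore validate the estimators
and the filtering logic under the stated noise model, not robustness to
real-world artefacts.

## Transcript filtering

Thresholds are inclusive exactly as printed: a feature responds when
`ratio ≥ 2` (or `≤ 0.5`) *and* `P ≤ 0.01`; ratio 1.999 or P 0.0101 does
not. A feature survives only when it responds in the same direction in all
three replicates; its fold change and P are then averaged across
replicates. "Contradictory" means disagreement among features that
*themselves survive* the three-replicate filter — sub-threshold features of
the same gene never veto it (the candidate lists that feed the original
workflow had already excluded them). The representative feature per gene is
the one with the smallest mean P, ties broken lexicographically by feature
id for determinism. Down-regulation is displayed as signed fold change
−1/ratio (ratio 0.135 → −7.4-fold) so magnitudes are always ≥ 1; matrix
cells store log2 of the mean ratio. The fill-in path averages ratios and P
values across replicates first, then selects the per-gene lowest-mean-P
feature, mirroring the original spreadsheet workflow's order of operations.
Both feature-level and gene-level responder counts are exposed, since
"transcripts" in the original count is ambiguous between the two.

The whole implementation is regression-tested against a deliberately naive
nested-loop oracle on randomized tables salted with exact-boundary values.

## Numerical choices and degenerate inputs

- Optimizer: `scipy.optimize.least_squares` (LM), ftol 1e-10, xtol/gtol
  1e-12; covariance by pseudo-inverse if `JᵀJ` is singular.
- Effect-grid construction requires ≥ 5 valid points; datasets require
  ≥ 4 distinct nonzero doses and ≥ 5 observations.
- τ-Loewe bisection: Brent's method on the effect fraction in
  (1e-12, 1 − 1e-12) at machine-precision tolerances.
- Fractions must sum to 1 within 1e-12; component doses sum to the total
  exactly by construction (`dose_b = total − dose_a`).
- All-flat responses, non-positive ratios, mismatched replicate universes,
  ≠ 3 replicates, and duplicate feature ids are rejected with specific
  errors rather than propagated as NaNs.

## Problem sizes

Simulation-based checks use 100–200 seeded runs of 48-observation datasets
(6 replicates × 8 doses) per condition, and 50 randomized feature tables of
up to 100 features for the filter oracle — sizes at which the Monte Carlo
summaries (medians, coverage and classification rates) are stable while
the full suite runs in well under a minute.

## Known limitations

- Two-drug fixed-ratio designs only; no Bliss/HSA/ZIP or response-surface
  models, and no >2-component mixtures.
- Wald intervals throughout; profile likelihood and bootstrap are not
  implemented, so intervals can misbehave when the ED50 sits near the edge
  of the dose ladder.
- The additive curve's covariance propagation linearises the construction;
  very steep or near-degenerate monotherapy fits may strain it.
- The verdict's power to detect mild antagonism (τ = 1.5) under the default
  noisy conditions is ≈80% — a property of the information in 48-point
  curves at 5% noise, not of the estimator.
- P values in the array generator are a stylised stand-in; no
  multiple-testing correction is applied anywhere, matching the original
  workflow.
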