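# Methods

This note documents the statistical model, the synthetic-data conditions,
and the numerical and design choices behind `fact8d`.

## Descriptive system and scoring

The FACT-8D describes health by eight dimensions (pain, fatigue, nausea,
sleep, work, support, sadness, worry), each at five levels (1 "Not at all"
… 5 "Very much"), a space of 5⁸ = 390,625 states. Nine FACT-G items
(scored 0–4) determine the state: direct items map level = score + 1;
the positively framed sleep/work/support items are reverse-scored
(level = (4 − score) + 1); support uses the *maximum* of its two items
(best available support from family or friends). Missing items raise an
error — no imputation rule is defined, and scoring incomplete responses is
out of scope.

Utility is additive: u = 1 + Σ decrement(dimension, level), with level 1
contributing 0. Consequently the maximum utility is 1 (full health) and
the minimum is the all-level-5 score. Decrements are reported to 3
decimals (full precision retained internally).

The bundled `uk_valueset_synthetic.csv` is a synthetic stand-in for a
published UK value-set table (which lives in journal supplementary
material). It is constrained to the published anchor facts — fatigue
level-3 decrement −0.047, worry level-3 decrement −0.002, worst-state
utility −0.402, pain and nausea the largest decrements, within-dimension
monotonicity, a worry 2–3 merged pair — and is clearly labelled synthetic;
its remaining entries are plausible interpolations, not estimates.

## DCE design

The design class is the published construction: 800 paired choice sets in
which exactly 5 of 9 attributes (8 dimensions + duration) differ, obtained
by adding four *generators* to a 200-run initial design (50-run orthogonal
array of strength 2 in 5-level columns × 4 durations). Each generator is a
length-9 offset vector with exactly 4 zeros, acting by modular addition on
0-based level codes (mod 5) and on the index of the ordered duration list
(1, 2, 5, 10) (mod 4). The zero pattern places two attributes at 1 zero
and seven at 2 zeros across the four generators, giving the overlap
pattern of 200 sets for two attributes and 400 for seven.

The original study's specific orthogonal array and generators are not
published, so the package constructs its own instance of the same class:

- **Orthogonal array.** A difference scheme D(10,10;5) over Z₅ (every
  pair of distinct columns' difference vector hits each residue exactly
  twice) was found by randomized search and frozen into `design.py`;
  developing it over Z₅ yields OA(50, 5¹⁰) of strength 2, of which the
  first 8 columns are used. The balance and strength-2 properties are
  re-validated on every construction, so a corrupted fixture fails loudly.
- **Generators.** A seeded random search draws feasible zero patterns and
  uniform nonzero offsets, scoring each candidate set of four generators
  by null-prior D-efficiency — det(M)^(1/33) of the average per-set Fisher
  information M = ¼·mean(Δx Δxᵀ) at β = 0, where Δx is the within-set
  feature difference. The default search (100 candidates) is cheap because
  the information matrix is 33 × 33. This reproduces the stated
  construction class, not the undisclosed instance.

Blocking: the 800 sets are permuted per 50-respondent rotation and cut
into 50 blocks of 16, so blocks partition the design within a rotation;
each respondent's A/B presentation side is randomized per set. All
randomization flows from a single seed.

## Estimation

With two alternatives per choice set the conditional logit reduces to a
no-intercept binary logit on within-set feature differences: P(choose A) =
logistic(Δxᵀθ), θ = (α, β). The log-likelihood is globally concave;
`ConditionalLogitQALY` maximizes it by Newton–Raphson with analytic
gradient and Hessian. Convergence requires max |gradient| < 1e-6;
step-halving guards ascent with an accept tolerance scaled by |loglik|
(absolute tolerances below the rounding noise of a ~10⁴-magnitude
log-likelihood cause spurious stalls). Separation — a column whose sign
perfectly predicts the choice — is detected and warned about before
fitting; fits that cannot converge raise with diagnostics rather than
returning garbage.

Respondent weights enter as probability weights multiplying each
respondent's log-likelihood contributions. The covariance is always the
respondent-clustered sandwich H⁻¹(Σ_c g_c g_cᵀ)H⁻¹ with observed
information H, per-cluster score sums g_c, and a finite-sample factor
G/(G−1); with weights of 1 the weighted fit is bit-for-bit identical to
the unweighted one. Pseudo-R² is McFadden's against the equal-share null
LL₀ = −(Σw)·log 2 (the published analyses name only "pseudo R²"; other
software may apply different cluster corrections, so exact SE replication
across packages is not claimed). Significance in QC summaries means
two-sided robust p < 0.05.

## Preference weights and monotonicity

Weights are w = β̂/α̂ with delta-method variance
Var(w) = Var(β)/α² + β²Var(α)/α⁴ − 2βCov(α, β)/α³ on the clustered
covariance. The ratio is refused when α̂ ≤ 0 or α̂/SE(α̂) < 2, since the
QALY anchor is then undefined.

The constrained model ("Model 2") iteratively detects within-dimension
adjacent level groups whose coefficients are disordered (a less severe
level with the larger decrement), merges each disordered pair into one
shared dummy, and refits, until all dimensions are monotone. By default
all disorders found in a pass are merged before refitting; a
one-at-a-time strategy is available (`merge_all_per_pass=False`) — the
merge order is genuinely underdetermined and the default favors fewer
refits. Merging never crosses the level-1 reference; a dimension may in
principle collapse to a single 2–5 group (flagged, allowed). The change in
pseudo-R² between Models 1 and 2 is reported.

## Raking

Variables are raked only when some category's sample share deviates from
the population marginal by ≥ 2.0 percentage points. IPF cyclically
rescales weights to match each selected variable's weighted shares;
convergence is max marginal discrepancy < 1e-6 within 50 cycles
(ipfweight-like defaults). Respondents missing any selected variable are
pinned to weight 1 and excluded from fitting; converged weights are
normalized to sum to the number of raked respondents. No trimming by
default. Shipped population targets are the printed UK census marginals;
printed percentages are rounded (some variables total 99.9–100.1%), so
the loader renormalizes each variable to sum to 1. Variance inflation
from weighting is summarized as the mean percentage increase in Model 1
coefficient SEs, weighted vs. unweighted.

## Synthetic cohorts

The generator emulates the study conditions: 2054 completers by default,
each allocated 16 choice sets from the 800, choosing by U = αt + β′Xt + ε
with i.i.d. Gumbel ε (scale fixed at 1 for logit identification; signal
strength lives in the coefficient magnitudes). Defaults:

- **α = 0.4 per life-year**, with β = α × the example value-set
  decrements (so pain and nausea carry the largest decrements and the
  implied true value set equals the bundled table). This calibration
  makes the Model 1 pseudo-R² on a simulated cohort ≈ 0.13, typical of
  published DCE health-state valuations; it was fixed once, by that
  realism argument alone.
- **Demographics** are drawn i.i.d. from the study sample's printed
  composition, so education (+23.5 points at the highest level), country
  of birth, marital status and household ownership deviate from the
  census marginals just as in the study and trigger raking; sex and age
  match (quota variables). About 13/2054 respondents have the four
  non-quota variables missing.
- **Completion times** are lognormal with a 13-minute median and an
  IQR of roughly 9–19 minutes; they feed only the QC decile analysis.
- **Pathology injections** are stylized test fixtures, not behavioural
  claims: straight-liners always take a presented side; "fast random"
  respondents choose uniformly and get times in the fastest tail.

What simulated cohorts do *not* emulate: taste heterogeneity between
respondents (except where tests construct it deliberately), panel
attrition and quota screening, item-level FACT-G response processes, and
any dependence of preferences on demographics. Passing recovery tests
therefore demonstrates the estimator's correctness under the stated
random-utility model, not robustness to real-world misspecification.

## Validation scales

The test suite runs at the study's scale where the claim depends on it:
parameter-recovery coverage uses 800 replicates of 2000 respondents × 16
tasks (replicates sized so the binomial noise of an estimated coverage,
sd ≈ 0.8 points, is small against the 92–98% acceptance band), and the
delta-method/bootstrap comparison uses a 500-replicate respondent-cluster
bootstrap on one such cohort. Smaller cohorts
(300–600 respondents) back the qualitative checks (QC decile patterns,
clustered-vs-naive SEs, merge behaviour under tied truth). The per-decile
QC fit requires a decile to contain comfortably more choice sets than the
33 parameters; smaller deciles are reported but skipped.

## Known limitations

- The design search optimizes D-efficiency only under a null prior;
  Bayesian-efficient designs with informative priors are out of scope.
- The published UK coefficient table cannot be verified beyond its
  printed anchor values; the bundled table is synthetic (see above).
- Mixed logit / latent-class extensions, weight trimming, replicate-
  weight variance estimation and cross-country comparisons are
  deliberately not implemented.
- The worst-state check tolerates ±0.005 because it is unstated whether
  the published −0.402 sums rounded or full-precision decrements.
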