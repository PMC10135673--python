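# Methods

## Trait allocation

Fuzzy coding grades how strongly a taxon expresses each trait within a
grouping feature on an integer 0–5 scale. For a coded taxon the allocation
coefficients are the normalised scores `c_t = a_t / Σ a_t`; a coded taxon
whose scores are all zero contributes nothing to that feature, which is
deliberately distinct from an *uncoded* taxon (no fuzzy information), whose
count is split `1/T` over the `T` traits it is recorded to possess. A count
`n` is allocated as `round(n · c_t)` per trait and summed over taxa per
site.

Rounding is to the nearest whole number with ties away from zero,
centralised in one swappable function (`round_half_away`). Rounding happens
per taxon *before* summation across taxa — the order the allocation
procedure describes. The per-taxon totals therefore conserve the count up
to `T/2` (exactly when every share is integral).

Unknown taxa abort the matrix build by default; a lenient flag skips them
and reports the skipped names. Traits that are zero at more than a
configurable fraction of sites (default 0.9) are flagged excluded —
preserving their data — with an explicit exclude-list override for
reproducing a fixed exclusion set; response models consume only retained
traits while diversity metrics use the full matrix (configurable
separation, since the appropriate choice depends on why a trait is sparse).

## Diversity metrics

`H = −Σ p_i ln p_i`, `D₁ = 1 − Σ p_i²`, `D₂ = 1/Σ p_i²`, richness `S`
(traits with nonzero allocated abundance), `J = H/ln S`. Natural logarithms
are used for both `H` and `J` so that `J = 1` exactly at perfect evenness;
`0·ln 0 = 0`; `J` at `S = 1` and every metric on an all-zero site are NaN
(sites are retained and flagged, never dropped or zero-filled). The
implementation is cross-checked in the tests against scikit-bio's alpha
diversity functions and an independent scalar evaluation.

## Response models

Single-predictor fits of each response against each environmental variable,
after centring the predictor at its sample mean (reduces linear/quadratic
collinearity; the centring constant is stored so curves are reported on the
original scale — predictions are invariant to centring, only coefficients
change).

Counts: negative-binomial GLM, log link, variance `µ + µ²/k`. Maximum
likelihood alternates IRLS for the coefficients at fixed `k` with a bounded
scalar maximisation of the profile likelihood over `log k`,
`k ∈ [10⁻³, 10⁶]` (boundary hits flagged); convergence when the relative
log-likelihood change falls below 1e-8, at most 100 outer iterations. The
fitter reproduces statsmodels' `NegativeBinomial` optimum to ~1e-4 and R
MASS `glm.nb` likelihood ratios to ~1e-9 (test-suite cross-checks); it is
implemented directly because the segmented iteration and the Monte-Carlo
validation suites need thousands of fits per run. Diversity metrics:
Gaussian ML via closed-form least squares (NaN responses dropped per fit).

Model selection is backward elimination: quadratic fitted first, its term
tested by a likelihood-ratio χ²(1) test at α = 0.05, then the linear term
likewise; lower-order terms are always retained under a significant
higher-order term. LR tests were chosen over Wald for small-sample
stability; the selection trace (terms, statistics, p-values, decisions) is
stored on every fit.

Diagnostics: deviance residuals vs fitted values, with the NB residuals
matching the standard `sign(y−µ)·√(deviance)` definition (verified against
R residuals to 1e-8). No automatic pass/fail is applied.

## Tipping points

The broken-line model `y = α + β₁x` before ψ and
`y = (α − β₂ψ) + (β₁ + β₂)x` after is estimated by Muggeo-style iterative
linearisation: refit with the hinge `U = (x−ψ)⁺` and correction
`V = −1(x>ψ)`, update `ψ ← ψ + γ̂/β̂₂`, step-halving back into the data
range, until `|Δψ| < 10⁻⁶·range(x)` (max 50 iterations). Because the
profile likelihood is kinked at the data points, the fixed point can cycle
among neighbouring kinks; a revisit in the iterate history is resolved by a
coarse-scan-plus-bounded-search profile maximisation over the cycle's span,
and every converged estimate gets the same local polish over the
surrounding few data points. This makes the estimator agree with an
exhaustive 1000-point profile-likelihood grid search on all tested
instances of both families. `SE(ψ)` comes from the delta method on `γ/β₂`
using the working-fit covariance; the reported (α, β₁, β₂) come from a
final hinge-only refit at ψ̂, so the two segments meet at ψ̂ exactly. The
NB dispersion is re-estimated at every iteration by default (switchable to
the null fit's value).

Existence of a breakpoint cannot be tested by the usual asymptotics (ψ
vanishes under the null of β₂ = 0), so a statistic is maximised over K
interior candidate quantiles of x (default K = 10) and referred to the
Davies (1987) bound, two-sided union form
`p = 2·(tail(M) + V·e^(−M²/2)/√(8π))` with `M` the largest absolute
statistic and `V` the total variation of the statistic sequence. Gaussian
responses use the Wald t of the hinge coefficient per candidate (Student-t
tail); count responses use the Rao score statistic for adding the hinge to
the null NB fit, dispersion held at the null estimate (normal tail). Both
tests hold their nominal 5% size within Monte-Carlo error (5.1% and 5.3%
at 1000 null replicates, n = 80).

The reported tipping point follows the published selection rule: segmented
fits are started from the interior deciles of x (between the 5th and 95th
percentiles), and among converged fits the estimate *closest to the
existence test's best candidate* is chosen (ties: higher log-likelihood,
then smaller ψ). Note this is intentionally not the global maximum-likelihood
estimate; the oracle-equivalence test therefore checks the ML-selected
multi-start fit, while the pipeline reports the rule-selected one. Estimates
with fewer than 5 observations on one side carry a warning but are never
suppressed, and a non-significant test never suppresses the estimate — the
verdict flag is simply false.

## Synthetic surveys

The generator emulates an ~80-site tropical stream survey. Environmental
variables are scaled Beta draws chosen to match the survey's summary
statistics: velocity `1.5·Beta(1, 4)` m/s (mean ≈ 0.3), turbidity
`34.7·Beta(0.8, 6)` NTU and elevation `2 + 1073·Beta(0.8, 4.5)` m a.s.l.,
the latter two right-skewed so the median sits well below the mean, as in
the field data's summaries. Only range and skew are matched — the true
field distributions are unknown, and no spatial structure, stream-network
topology or seasonality is modelled, so passing recovery tests demonstrates
correctness of the estimators under the stated model, not robustness to
real-data violations of it.

Counts are generated at the *trait* level — where the ground truth
(log-mean form, coefficients, dispersion `k`, breakpoint ψ) must live —
from NB draws with `var = µ + µ²/k`, and then disaggregated into taxon
counts: mixed-affinity taxa absorb random shares whose rounded allocations
are subtracted from the targets, and single-trait specialist taxa carry the
exact remainders. Re-allocating the output therefore reproduces the input
trait counts exactly, which is how the allocation stage is validated
end-to-end. Polynomial log-means apply to the predictor centred at its
sample mean (the scale models are fitted on); broken-line parameters apply
to the original scale so ψ is in predictor units.

The bundled default scenario has 80 sites, 30 families (8 feeding
specialists plus mixed profiles over all five grouping features, one
taxon/feature pair left uncoded to exercise equal coding), dispersion
k = 2 throughout (moderate overdispersion typical of macroinvertebrate
counts), and known responses: a velocity slope of 1.2 (scraper), a
mid-elevation quadratic peak (deposit feeder), a declining turbidity slope
(filter feeder), a flat control (predator), a near-absent trait for the
sparsity filter (absorber), and one true turbidity breakpoint at 5 NTU
(piercer: log-mean +0.35/NTU before, −0.20/NTU after). The breakpoint
effect size was fixed at design time by a power calculation so that the
score test detects it with high probability at n = 80; the validation suite
then measures detection (≈100%), aggregate slope recovery and ψ recovery
over 200 replicates.

## Pipeline

Listwise deletion of sites missing any predictor happens once, up front;
every removed or annotated site appears in a report, and sites present only
in the environmental table are kept as zero-count communities. Each stage
reads/writes plain CSV keyed by `site_id`; `run_pipeline` writes a manifest
with a config hash and an SHA-256 checksum per output, and identical
config + seed reproduce identical files. Plots are optional artifacts that
nothing downstream reads.

## Validation suite sizes

Calibration tests use 1000 null replicates at n = 80; the
backward-elimination calibration uses n = 500 per replicate, where the
χ²(1) reference for the LR statistic is accurate; oracle-equivalence uses
20 instances per family at n = 70 against a 1000-point grid; pipeline
recovery uses 200 replicates of the 80-site default scenario.

## Known limitations

- The LR χ² reference is asymptotic: at n = 80 with k = 2 the spurious
  quadratic retention rate is ≈ 7.8% rather than 5% (the identical rate is
  obtained from R MASS `glm.nb` on the same data — a property of the test
  at that sample size, not of the implementation).
- NB deviance residuals have a negative mean on strongly skewed data
  (≈ −0.27 at k = 2, µ ≈ 4.5, matching R); the residual plot is a
  diagnostic, not a calibrated statistic.
- Single predictor, single breakpoint, no zero-inflation, no interactions —
  matching the modelling scope of the analysis the package implements.
- The Davies bound is an upper bound; with strongly dependent candidate
  statistics it can be mildly conservative.
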