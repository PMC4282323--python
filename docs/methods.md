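# Methods

## Model

A two-stage drop-the-loser trial with k experimental arms.  Stage-1 effect
estimates are X_i ~ N(μ_i, σ₁²), independent across arms with a common,
*known* standard error σ₁ (the package never estimates σ₁ or σ₂ from raw
data; they are user-supplied design constants).  The arm with the largest
X_i is selected — ties, which have probability zero under the continuous
model, are broken toward the lowest index for determinism — and re-tested
on an independent stage-2 population, giving Y_s ~ N(μ_s, σ₂²).  No stage-2
data exist for dropped arms, and the control arm is out of scope: a control
mean, estimated without selection, can simply be subtracted from any
estimate here.

The estimand is μ_s, the true mean of whichever arm was selected.  Before
the trial it is a random variable — a mixture of μ_1 … μ_k over the
selection event — so bias and MSE are defined against the realized μ_s of
each replicate.

### Meta-analytic view

All shrinkage estimators except Carreras–Brannath operate on a
reformulation in which each arm is one "study": the non-selected arms
contribute (X_i, W_i = σ₁²) and the selected arm contributes the
precision-weighted combination X̃_s with W_s = σ̃² = (1/σ₁² + 1/σ₂²)⁻¹.
With a hierarchical prior μ_i ~ N(μ, τ²) this is exactly the
unequal-variance random-effects meta-analysis model, which is why the
machinery in `meta_core` (generalised Q, Paule–Mandel, DerSimonian–Laird,
profile likelihood) applies verbatim.

## Estimators

Formulas are in the README table.  Points that required a decision:

- **UMVCUE.**  Derived by Rao–Blackwellization: conditional on the
  combined estimate Z, the stage-1 winner X_s is N(Z, η²) with
  η = σ₁²/√(σ₁²+σ₂²), truncated below at the runner-up X_r; taking the
  conditional expectation of the (conditionally unbiased) stage-2 estimate
  yields Z − (σ₂²/√(σ₁²+σ₂²))·φ(v)/Φ(v) with v = (Z−X_r)/η.  The Mills
  ratio φ/Φ is evaluated in log space (`norm.logpdf − norm.logcdf`), which
  is stable to arbitrarily negative v, so no separate asymptotic branch is
  needed.  Conditional unbiasedness is verified by Monte Carlo in the test
  suite, including unequal stage variances.
- **Plus-rule everywhere.**  Each C-type factor is truncated at 0 before
  use.  It is stated for the equal-variance Lindley factor, but the
  Carter–Rolph factors can also go negative and a negative factor is never
  meaningful shrinkage; truncation is known to reduce MSE further.
- **Zero stage-1 dispersion** (all X_i equal) makes the Lindley and
  proportional-prior factors 1 − ∞; they are defined as C⁺ = 0, i.e. full
  shrinkage to the (then common) grand mean.
- **Grand means.**  `cr_standard` shrinks toward the inverse-(W_i+τ̂²)
  weighted (random-effects) mean; `cr_proportional` toward the
  inverse-W_i (fixed-effects) mean, which its prior implies;
  `direct` toward the weighted-mean MLE at the fitted τ², so all
  heterogeneity fits report the fixed-effects mean whenever τ̂² = 0.
- **Small k.**  The (k−3) factors make shrinkage estimators meaningful only
  for k ≥ 4.  The `small_k_fix` design flag replaces (k−3) by (k−2),
  crudely extending them to k = 3; it is off by default.  k ≤ 2 with a
  shrinkage method raises.
- **Limited translation.**  The corridor half-width is one naive SE — the
  usual practical choice — exposed as `lt_width` but deliberately not
  tuned; width tuning interacts with the selection mechanism and is left
  out of scope.
- **Direct plug-in without plus-rule.**  Its posterior weight
  τ̂²/(W_s+τ̂²) is intrinsically in [0,1].

## Numerical choices

- Paule–Mandel: Q(τ²) is monotone non-increasing, so the root of
  Q(τ²) = k−1 is bracketed by doubling an initial upper bound
  10·max(var(x̃), max W) (up to 60 doublings, then an error with
  diagnostics) and solved by Brent's method; truncated at 0 when
  Q(0) ≤ k−1.  The returned root satisfies the Q-equation to 1e-8 or
  better.
- Profile likelihood ℓ(τ²) = −½Σ[log(W_i+τ²) + (X̃_i−μ̂(τ²))²/(W_i+τ²)]
  with μ̂(τ²) the inverse-(W+τ²) weighted mean profiled out.  Maximized by
  bounded scalar minimization (tolerance 1e-8 on τ²) with an expanding
  upper bound; a boundary maximizer at 0 is snapped exactly when ℓ(0) is
  at least as large.  A joint maximization in (μ, τ²) would differ only
  through the profiling of μ, which is exact here (normal likelihood,
  closed-form μ̂), so a single strategy suffices.
- The simulation engine evaluates all estimators vectorized across
  replicates: Paule–Mandel by 80 steps of vectorized bisection, the
  profile maximizer by a 48-point bracketing grid (quadratically spaced
  toward 0, where the maximizer usually lies) refined by 60 golden-section
  steps.  A test asserts replicate-by-replicate agreement with the scalar
  API (1e-9; 1e-6 for the optimizer-based direct plug-in).

## Simulation study

`run_table1` crosses four true-mean scenarios — I: μ_i ~ N(0, τ²=1) redrawn
each replicate; II: all 0; III: one arm at δ=1; IV: one arm at δ=1.5 —
with four (σ₁, σ₂) levels, default (1,1), (2,1) plus two configurable
extras, 50000 replicates per cell.  Reported quantities are bias and √MSE
scaled by the naive SE σ̃, each with a Monte-Carlo standard error (delta
method for √MSE).  `sweep` varies δ, τ² or k one at a time and also
reports E[μ_s], the strength of the selection effect.  Every cell draws
from its own generator seeded from (master seed, cell index), so cells are
independently reproducible.

Under scenario II the MLE's scaled bias has a closed form,
σ̃·m_k/σ₁, with m_k = E[max of k standard normals] computed by numerical
integration (m₆ ≈ 1.26721; scaled bias ≈ 0.896 at k=6, σ₁=σ₂=1); the
simulator is required to agree within 3 Monte-Carlo SEs, which anchors the
whole error-accounting pipeline, and the acceptance script reproduces the
published table cells (e.g. MLE scaled bias 0.89 and √MSE 1.23, UMVCUE
√MSE 1.27, direct plug-in √MSE 0.65 in the all-null unit-variance cell).

### What the generator does and does not emulate

The generator reproduces the idealized model exactly: known variances,
normal estimates, a common σ₁, independence across arms and stages, and
max-selection.  Real trials violate most of these — variances are
estimated, arms share a control group (inducing correlation), selection
may use safety or futility criteria, and outcomes may be non-normal — so
passing tests certify correctness *within* the model, not robustness to
these departures.  In particular, if a supplied trial's continued arm is
not the stage-1 maximum, the reader accepts it with a warning but every
bias-correction guarantee is void.

## Known limitations

- Unequal per-arm stage-1 variances are not supported (the common-σ₁
  assumption is structural to the Lindley factor).
- No confidence or credible intervals; point estimation only.
- Estimating τ² from k ≈ 6 "studies" is intrinsically noisy; the direct
  plug-in inherits this fully (it collapses to the fixed-effects mean
  whenever τ̂² = 0), which is why it is simultaneously the best method
  when the selected mean is near the grand mean and the worst when it is
  an outlier.
- Multi-stage selection and correlated arms via a shared control are out
  of scope.
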