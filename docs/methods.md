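# Methods

## Model

For `n` individuals measured in up to `t` contexts (tissues, phenotypes)
with `c` covariates fit within each context, mclmm fits

    y = X β + u + e,     u ~ N(0, σg² K),     e ~ N(0, σe² I)

where `y` stacks the `N = Σᵢ tᵢ` observed responses, `X` (N × tc) fits an
intercept and every covariate effect separately within each context, and
`K` is the binary indicator with `K_{ij} = 1` exactly when observations
`i` and `j` come from the same individual.  This models within-individual
covariance only: two measurements of the same person share the random
effect `u`, measurements of different people are independent.  There is no
across-individual (kinship) or within-context random effect; mclmm is
restricted to this indicator `K` and is not a general-purpose LMM.

Writing `δ = σe²/σg²` and `H = K + δI`, the profile likelihood in `δ`
uses the GLS estimator `β̂ = (XᵀH⁻¹X)⁻¹XᵀH⁻¹y` and
`σ̂g² = R/N` (ML) or `R/(N − tc)` (REML), with
`R = (y − Xβ̂)ᵀH⁻¹(y − Xβ̂)`.

## Fast likelihood evaluation (arbitrary missingness)

`H` is block diagonal, one block `1_{tᵢ} + δI` per individual, so its
spectrum is known without any eigendecomposition:

* `log|H| = (N − n) log δ + Σᵢ log(tᵢ + δ)`;
* each block inverts in closed form (Sherman–Morrison):
  `(1_{tᵢ} + δI)⁻¹ = (1/δ)(I − 1/(tᵢ+δ)·11ᵀ)`.

Substituting gives `XᵀH⁻¹X = (1/δ)(E − D(δ))` where `E = XᵀX` is
δ-independent and `D(δ)` is a `1/(t_g+δ)`-weighted sum over *groups* —
the ≤ t sets of individuals sharing the same observed-context count
`t_g` — of precomputed rank-one accumulations `Σ v_ind v_indᵀ` with
`v_ind` the per-individual column sums of `X`.  The quadratic-form pieces
`a = yᵀH⁻¹y` and `b = XᵀH⁻¹y` decompose the same way.  (Grouping by
count alone suffices: `v_ind` is zero outside the individual's observed
contexts, so the restriction to individuals observing both contexts of an
entry is enforced by the zeros.)

All group sums are accumulated in one O(n) pass (`GroupIndex`).  Each
likelihood evaluation then costs `O(groups·(tc)² + (tc)³)`: form
`XᵀH⁻¹X`, Cholesky-factor it (`log|XᵀH⁻¹X| = Σ 2 log Lᵢᵢ`, needed for
REML), and compute `R = a − bᵀ(XᵀH⁻¹X)⁻¹b` through triangular solves.
The objectives maximized are, up to positive affine transformation
(δ-independent constants and the global ½ are dropped),

    ML:    −N log R − log|H|
    REML:  (tc − N) log R − log|H| − log|XᵀH⁻¹X|

## Optimization

The objective is maximized over `log δ ∈ [log 1e−5, log 1e5]` (the
conventional search range for variance-ratio profiling).  Because
unimodality of the profile is not guaranteed, a 64-point log-spaced grid
scan first brackets the best basin; bounded Brent refinement then polishes
to an absolute tolerance of 1e−8 on `log δ`, which leaves downstream
`β̂`/SEs stable past 1e−6.  If an endpoint beats the refined interior
point the endpoint is taken and the fit is flagged `boundary`.  A profile
that is numerically flat (relative range < 1e−9 across the grid — e.g.
every individual observed exactly once, so `K = I` and only
`σg²(1 + δ)` is identified) is reported as a boundary fit at `δ_max`,
i.e. the `σg² → 0` resolution of the ambiguity.

## Exact closed form for complete data

With no missing responses (`N = nt`, all `tᵢ = t`), sorting rows by
context factorizes `H = (1_t + δI) ⊗ Iₙ` and `X = I_t ⊗ X_dense`
(up to the fixed column permutation between context-major and our
context-fastest layout).  Kronecker algebra then gives:

* `β̂ = (I_t ⊗ (X_denseᵀX_dense)⁻¹X_denseᵀ) y` — per-context OLS,
  independent of δ;
* `(XᵀH⁻¹X)⁻¹ = (1_t + δI_t) ⊗ (X_denseᵀX_dense)⁻¹` (in context-major
  column order), so the coefficient covariance never requires a tc × tc
  inverse and the per-context estimates of one covariate have pairwise
  correlation exactly `1/(1 + δ)`;
* with OLS residuals `s`, `u = Σ s²` and `v = −Σᵢ(Σ_contexts s_ind)²`,
  the residual quadratic form is `R(δ) = u/δ + v/(δ(t+δ))` and both the
  ML and REML profile derivatives vanish at

      δ̂ = (−t·u − v)/(u + v).

The solver verifies by a second-difference check that this stationary
point is a local maximum (falling back to the iterative solver in the
pathological alternative).  A non-positive root — which occurs whenever
the within-individual residual correlation is weak, since variance
components cannot be negative — is resolved by clamping to `δ_max = 1e5`
(σ̂g² ≈ 0) with the boundary flag set; roots outside `[1e−5, 1e5]` clamp
to the nearer bound.  Total cost is `O(c³ + nc² + tcn)` with no
iteration.

## Inference and meta-analysis

Standard errors of `β̂` are square roots of the diagonal of
`σ̂g²(XᵀH⁻¹X)⁻¹`; per-coefficient tests are Wald z against the normal
(no small-sample t correction).  For an association scan, the `t`
per-context estimates of the tested covariate are combined by the
Lin–Sullivan generalized fixed-effects estimator: with
`Ω = diag(se)·corr·diag(se)`,

    β_meta = (1ᵀΩ⁻¹β̂)/(1ᵀΩ⁻¹1),    se_meta = (1ᵀΩ⁻¹1)^{−1/2},

which reduces to classical inverse-variance fixed-effects meta-analysis
when the correlation is the identity, and two-sided normal p-values.
Correlation matrices that drift indefinite through floating-point noise
are repaired by flooring eigenvalues at 1e−8 and re-normalizing the
diagonal.  A writer emits the per-context beta/SE table (with `NA NA`
pairs for unobserved contexts) and companion correlation matrices in the
format external meta-analysis tools (e.g. random-effects RE2
implementations) consume; those models themselves are out of scope here.

## Dense reference implementation

`mclmm.oracle` builds the explicit N × N `H`, evaluates the exact
likelihoods with all constants, and maximizes by grid search with GLS
profiling.  It exists to validate the fast solvers on small instances
(capped at N = 2,000) and is deliberately written by direct inversion for
transparency, not speed.

## Synthetic data

The generator reproduces three study designs:

* **Genotypes** — dosages as the sum of two Bernoulli(MAF) haplotypes;
  default MAF 0.3.
* **Null multi-context responses** — `y ~ N(0, σg²K + σe²I)`, sampled
  per individual as a shared `N(0, σg²)` effect plus independent
  `N(0, σe²)` noise (exactly the block covariance `σg²·1 + σe²·I`,
  never materializing an N × N matrix; a test verifies equivalence to a
  naive full-block multivariate-normal draw).  The null-calibration
  design uses equal component *standard deviations* of 0.5, i.e.
  variances 0.25 each and intraclass correlation 0.5 — the notation
  `σg = σe = 0.5` is read as SDs since the covariance is written in
  terms of σ².
* **Effects** — `y[ind, r] = β_r · dosage_ind + e`.  Non-null effect
  vectors are drawn either unstructured (`N(0, 0.01 I)`) or structured
  (`N(0, w U_k)`, `w = |N(0,1)|` drawn per gene–SNP pair, `U_k` picked
  uniformly from a supplied family).  Data-driven tissue-sharing
  covariance matrices are external artifacts; the built-in synthetic
  family (identity, equicorrelation at ρ = 0.5 and 0.9, rank-one plus
  diagonal ridge, all normalized to unit average variance) preserves the
  structured/unstructured contrast while keeping the package
  self-contained.  Users can supply their own `U_k` set.
* **Missingness** — each (individual, context) pair retained
  independently with the sampling rate (default design: rate 0.5 at
  `σg² = 0.4`, `σe² = 0.2`); individuals left empty are dropped, and a
  context left empty has one observation restored so the design stays
  valid.

What the generator does *not* emulate: real expression data's
non-normality, mean/variance relationships, batch and expression-factor
structure, LD between variants, or across-individual relatedness.
Passing tests therefore demonstrate correctness of the estimator and
calibration under the model's own assumptions, not robustness to their
violation.

## Validation experiments and problem sizes

The experiment scripts run at desk scale, preserving each design's
parameters while reducing replicate counts:

* **Null calibration** — 20,000 null gene–SNP pairs at n = 200
  individuals × 5 contexts, complete data; the empirical fraction of
  meta-analysis p-values below 0.05 is compared to 0.05 plus three
  binomial standard errors (≈ 0.0546).
* **Variance recovery with missingness** — 200 replicates at n = 500,
  t = 8, sampling rate 0.5; mean REML σ̂g² and σ̂e² against 0.4 and 0.2
  within three Monte-Carlo SEs.
* **Complete-data SD recovery** — 200 replicates at n = 500, t = 5 with
  both SDs 0.5; the square root of the mean σ̂g² against 0.5.
* **Solver equivalence** — 100 random small masked instances against the
  dense grid-search reference (δ̂ to grid resolution, β̂ to 1e−6);
  50 complete instances for closed-form vs iterative agreement; and a
  randomized identity suite checking every refactoring formula against
  dense linear algebra below 1e−9.

## Numerical choices and edge cases

* Cholesky failure of `XᵀH⁻¹X` raises a collinearity error (e.g. a
  context with fewer observations than covariates, or a variant identical
  to an existing covariate); the scan command isolates such variants and
  continues.
* A residual quadratic form below `1e−10 · a` raises a degenerate-fit
  error (saturated design, `N = tc`).
* Covariates must be complete per individual even where responses are
  missing; responses are the only place missingness is modeled.
* Reported log-likelihoods omit δ-independent constants; compare
  differences, not absolute values.
* All generators take either an integer seed or a NumPy `Generator`;
  every simulation is reproducible from its scenario seed.

## Known limitations

* Only the indicator `K` is supported — no arbitrary PSD kinship, no
  multiple variance components.
* Meta-analysis is fixed-effects only; heterogeneity-aware models must be
  run externally on the exported files.
* Wald/normal inference may be anti-conservative for very small n; the
  calibration experiment covers n = 200, not tiny samples.
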