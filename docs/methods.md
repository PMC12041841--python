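# Methods

`scmanova` implements a MANOVA-type homogeneity test for *semicontinuous*
data — nonnegative measurements with a probability mass at exactly zero —
that remains usable when the dimension `p` exceeds the sample size `n`.
This note records the model, the estimators, the numerical policies, and the
design choices made where the design was genuinely open, together with what
the simulation-based checks do and do not establish.

## Model

Observations fall into `K` groups of sizes `n_1, …, n_K` (`n = Σ n_k`).
Each observation is a vector `X_i ∈ [0, ∞)^p`; zeros encode absence.  Two
coupled components describe the data:

* **Presence pattern.**  `Y_i = 1(X_i > 0)` follows an *exchangeable*
  multivariate Bernoulli law per group: every configuration `a ∈ {0,1}^p`
  with the same number of presences `s = Σ_j a_j` has the same probability
  `π_k(s)`.  This reduces `K(2^p − 1)` Bernoulli parameters to `K(p + 1)`
  (with one normalization per group): `Σ_s C(p, s) π_k(s) = 1`.
* **Positive part.**  Conditionally on the pattern, the logs of the present
  components follow the corresponding marginal of `N_p(μ_k, Σ)`, with a
  single covariance matrix `Σ` shared by all groups (homoskedasticity).

The hypothesis under test is full homogeneity:
`H0: π_1(s) = … = π_K(s)` for all `s` and `μ_1 = … = μ_K`.

## Penalized closed-form estimation

Writing `V_i` for the support of observation `i` and `x̃` for log-values,
the estimators are:

* `π̂_k(s) = [s!(p−s)!/p!] · #{i in group k with |V_i| = s} / n_k`
  (configuration probability, i.e. the frequency of support size `s`
  divided by the number of configurations of that size);
* `μ̂_jk` = mean of `x̃_ij` over observations in group `k` with `j`
  present;
* `Σ̂_λ` = entry-wise ratio: numerator `Σ_i (x̃_i − μ̂)(x̃_i − μ̂)^T`
  accumulated only over co-observed pairs, with `Λ = diag(λ)` added once;
  denominator the matrix of co-presence counts `d_{j1 j2} = Σ_i Y_ij1 Y_ij2`.

The ridge-like `Λ` loads only the diagonal and makes `Σ̂_λ` positive
definite for large enough `λ` even when `p > n`.  With complete data,
`Σ̂_λ = S + Λ/n` (the classical ML covariance at `λ = 0`).

Two properties of `Σ̂_λ` deserve explicit statement:

* **Exactness regime.**  For complete data (and for a single variable under
  arbitrary masking) the closed forms globally maximize the ridge-penalized
  log-likelihood `ℓ − tr(ΛΣ^{-1})/2`; the objective is concave in the
  natural parameter and the stationarity condition gives `Σ̂ = S + Λ/n`
  exactly.  The test suite verifies this against an independent numerical
  optimizer.
* **Available-case behaviour.**  With heterogeneous presence patterns the
  entry-wise ratio is an *available-case* estimator: it is not the exact
  maximizer of the observed-data likelihood (which has no closed form and
  would require EM), and a numerical optimizer can attain a slightly higher
  penalized likelihood.  This is a deliberate trade: the closed form is
  direct, fast enough to re-estimate inside every permutation, and feeds a
  permutation test whose validity does not depend on the estimator being an
  exact MLE.  A regression test pins this behaviour.

Columns are pre-filtered so that every retained pair of variables is
co-observed in at least one row (pooled over groups): otherwise an entry of
the denominator would be zero.  The filter removes columns greedily,
most-absent first (largest index on ties, making the result independent of
row order), and also drops columns with no presences.  The retained
dimension is reported as `p*`.  A column with presences pooled but none in
one group is *kept*: its group mean is unidentified but never enters any
likelihood term (no support set of that group contains it), and removing it
would make the null and alternative models live on different variable sets.

All-zero rows are retained; they contribute `log π(0)` to the Bernoulli
part and nothing to the Gaussian part.  NaN input is rejected outright —
a missing value is not a structural zero, and silently coercing it would
corrupt the Bernoulli component.  Natural logarithms are used throughout.

## Penalty selection

Let `B = √d A √d` (entry-wise) with `A` the unpenalized ratio estimator and
`d` the vector of presence counts.  Then

    Σ̂_λ = D^{1/2} (B + λI) D^{1/2},   D = diag(1/d_j),

so `Σ̂_λ` and `B + λI` are congruent and share inertia: the feasible set
`Φ = {λ : Σ̂_λ ≻ 0}` is the ray `λ > −eigmin(B)` (up to the relative
tolerance below), and one symmetric eigendecomposition of `B` screens every
scalar candidate.  Positive definiteness is declared when the smallest
eigenvalue of `B + λI` exceeds `1e-10` times the largest (a scale-free
criterion; the congruence preserves the sign pattern exactly, so this
differs from a tolerance on `Σ̂_λ` itself only through the conditioning of
`D`, which is benign here).

Within `Φ`, `λ` is chosen by minimizing the information criterion

    M(λ) = −2 ℓ(θ̂_λ) + [log(n) + log(p*)/2] · Σ_i tr( (Σ̂_λ)_{V_i}^{-1} ),

with `ℓ` the *unpenalized* log-likelihood at the penalized estimates and
the per-observation trace of the inverse covariance (the trace of the
Fisher information of the mean parameters) as the complexity measure.  The
same criterion with pooled estimates selects `λ̂_0` under the null.

Numerically the criterion is minimized in two stages: a scan over a
scale-aware candidate grid (`{0}` plus 25 log-spaced points spanning
`10^-3`–`10^2` times the mean unpenalized variance diagonal `d̄`; ties go to
the smaller candidate), then golden-section refinement between the
bracketing candidates, with the positive-definiteness boundary as the lower
edge (interval tolerance `1e-9` relative).  The refinement is not a luxury:
inside the permutation test the penalty is re-selected on every permuted
dataset, and a penalty restricted to a coarse grid jumps between candidates
across permutations, injecting selection noise into the statistic that
visibly destroys power (in the zero-probability-shift study cell below,
grid-only selection gives a rejection rate of ~0.15 where the refined
selection gives ~0.52).  Per presence pattern, one eigendecomposition of
the congruent submatrix makes the criterion O(|V|) per candidate, so the
refinement costs microseconds.

Two selection behaviours worth knowing:

* For complete data the criterion has a closed-form interior optimum
  `λ̂/n = log(n) + log(p)/2`, independent of the data (plug
  `Σ̂ = S + (λ/n) I` into `M` and differentiate).  The selected penalty
  therefore *grows* with `n` — shrinkage on the estimator scale
  `λ̂/n` tends to the complexity weight, not to zero.  The test suite uses
  this closed form as an oracle for the whole selection machinery.
* In the `p > n` regime the criterion balances fit against the trace
  complexity and lands well inside the feasible ray, far from the
  positive-definiteness boundary.

Cross-validation is not implemented (the criterion is the recommended,
much faster route).

## Test statistic and permutation scheme

    D = −2 [ ℓ0(π̂0, μ̂0, Σ̂0_{λ̂0}) − ℓ(π̂, μ̂, Σ̂_{λ̂}) ],

unpenalized log-likelihoods at penalized estimates.  With complete data and
`λ = λ0 = 0` this is the classical Gaussian MANOVA likelihood-ratio
statistic (verified to `1e-8` against the scatter-matrix formula).  Because
`λ̂ ≠ λ̂0` in general, `D` can be slightly negative; the permutation
calibration makes this harmless.  A `penalized_ratio` switch differences
the penalized log-likelihoods instead, for sensitivity analysis.

The null distribution comes from label permutations: group labels are
shuffled uniformly at random (group sizes preserved), and the pipeline is
re-run per permutation.  By default the alternative penalty is re-selected
on each permuted dataset, so the permutation distribution absorbs the
variability of the data-driven penalty choice; the null-model estimates are
label-invariant, hence `λ̂0` and `ℓ0` are computed once and re-selecting
them per permutation would be a no-op.  `reselect=False` reuses the
observed `λ̂` for speed.

P-values: the default `add_one` convention `(1 + #{D_b ≥ D_obs})/(B + 1)`
guarantees validity at any finite `B`; `strict` reports the plain
proportion `#{D_b ≥ D_obs}/B`.  Ties count as at-least-as-extreme in both
modes — almost surely equivalent to counting strictly larger statistics for
continuous data, and the only convention that behaves sensibly (p = 1) on
degenerate data where every permutation reproduces the observed fit.  A
relative `1e-7` tie tolerance absorbs floating-point noise from the
continuous penalty selection; it can only enlarge the p-value.
Permutations with no feasible penalty (not observed in practice) would be
dropped and counted.

The permutation loop is compiled (numba).  Per labeling, the group means,
the entry-wise ratio matrix and one eigendecomposition per unique presence
pattern are recomputed; patterns and co-presence denominators are
label-invariant and prepared once.  The plain-numpy estimation path and the
compiled kernel are verified against each other in the test suite.

## Scenario simulator

One study cell fixes `(K, n_k, p, ρ, c1, c2, π_1)`.  Log-abundances are
`N_p(μ_k, Σ)` with `Σ = (1−ρ) I + ρ 11^T` (compound symmetry, unit
variances), `μ_jk = c1 (k−1)/(K−1)` (group 1 centred); presences are
independent Bernoulli draws with zero probability
`π_jk = π_1 + c2 (k−1)/(K−1)` (valid only below 1), independent of the
Gaussian draw; the observation is `exp(Z) ∘ Y`.  Masking a complete
Gaussian vector yields exactly the model's conditional law by
marginalization, and independence of presences is the minimal mechanism
consistent with specifying marginal zero probabilities only.  For `ρ ≥ 0`
the compound-symmetric draw uses the shared-factor construction
`√(1−ρ) ε + √ρ g 1` (exact); the valid negative range uses a Cholesky
factor.

`c1 = c2 = 0` puts every cell under the null, so the rejection rate
estimates the observed level; otherwise it estimates power.  Replicates
draw seeds from a spawned `SeedSequence` tree: the same master seed
reproduces a rejection rate bit for bit, and replicates are independent.

What the generator does *not* emulate: dependence between presence and
abundance (real omics zeros are often abundance-correlated), group-specific
covariances, non-lognormal positive parts, and technical batch structure.
Passing the simulation checks therefore establishes calibration and power
under the model's own assumptions, not robustness to their violation.

## Study sizes used by the checks

The published study used 1000 replicates × 1000 permutations per cell —
hours of CPU per cell.  The package's acceptance checks re-run eight cells
at `p = 50` with `R = 200` replicates × `B = 199` permutations (a desk
scale chosen so the whole grid runs in minutes with the compiled kernel)
and compare rejection rates within 3 binomial Monte-Carlo standard errors
`√(r(1−r)/R)`.  At this scale six of the eight cells reproduce the
published values; the two mean-shift cells sit at the band edge in opposite
directions (K=2 slightly below, K=4 slightly above), a residual gap
consistent with implementation details of the original software that the
published formulas do not pin down.

## Known limitations

* `π̂_k(s)` underflows double precision when `C(p, s)` exceeds ~1e300
  (`p ≳ 1000`); the regime targeted here (`p` up to a few hundred) is safe.
* The exchangeability reduction is an assumption, not a fitted choice; no
  goodness-of-fit check for it is provided.
* The statistic compares exactly two nested models; ordered alternatives,
  contrasts, or per-variable follow-ups are out of scope.
* Group-specific covariance matrices are not supported.
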