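# Methods

## Model

The package fits multi-trait linear mixed models of the form
`y = Xb + Wp + Zu + e`.  Random effects are organized in *groups*: each
group `k` is a set of correlated trait-columns (for example, the five
columns direct-bw / direct-ww / direct-pwg / maternal-bw / maternal-ww of a
growth model) sharing one relationship structure `K_k`, with
`Var(k) = θ_k ⊗ K_k`.  Supported structures are the pedigree numerator
relationship matrix `A`, the single-step matrix `H`, and `I` (e.g. maternal
permanent environment).  Residuals follow `R0 ⊗ I` with per-record
missingness: each record contributes only the observed sub-block of `R0`,
inverted per missingness pattern.

Structural zeros are first-class: any off-diagonal entry of a `θ_k` or of
`R0` can be masked, in which case it is excluded from the free-parameter
vector and held exactly at zero through every update.  The free parameters
are the unmasked lower-triangle entries (vech) of each `θ_k` and of `R0`.

## Relationship machinery

* Inbreeding `F` is computed by the Meuwissen–Luo recursion; the
  Mendelian-sampling variance fraction is `φ_i = 0.5 − 0.25(F_s + F_d)`
  with both parents known, `0.75 − 0.25 F_known` with one, and 1 otherwise.
  `A⁻¹` follows Henderson's rules with `d_i = φ_i`; `log|A| = Σ log φ_i`.
* Indirect products `A v` use Colleau's decomposition
  `A = (I−P)⁻¹ D (I−P)⁻ᵀ`; `A22` is assembled column-wise this way and
  factorized densely (desk scale).  A second backend computes
  `A22⁻¹x₂ = B22 x₂ − B21 B11⁻¹ B12 x₂` from sparse blocks `B` of `A⁻¹`
  with `B11` LU-factorized once; the two backends are cross-checked in the
  operator's self test and in the suite.
* `G_raw = MM′/(2Σp_i q_i)` with dosages centered by twice the observed
  allele frequency (VanRaden method 1); monomorphic loci are dropped at
  load time.  The J-factor variance `v = n⁻²1′(A22 − G_raw)1` aligns the
  genomic and pedigree base populations; it is computed from the
  *pre-blending* matrix, since the adjustment targets the base mean of the
  marker-based matrix.  On small simulated marker panels `v` can come out
  slightly negative by sampling noise; it is then clipped to zero with a
  logged warning (the adjustment is a mean alignment, not a variance
  inflation, so a negative value has no interpretation).
* Blending with the residual polygenic fraction α defaults to the
  variance-consistent form `G = (1−α)(G_raw + v·11′) + α·A22`, which is
  exactly the covariance the breeding-value sampler realizes, so the `G`
  used inside `H⁻¹` and the `G` implied by the simulation agree by
  construction.  A `blend = "sqrt"` configuration flag switches to
  `√(1−α)/√α` weights; the sampler weights adapt so sampler and matrix stay
  consistent under either convention.
* `H⁻¹` is never formed: `x′H⁻¹y = x′A⁻¹y + x₂′G⁻¹y₂ − x₂′A22⁻¹y₂`.  The
  genomic backend is the dense inverse of the blended `G` or, with APY
  enabled, the sparse inverse implied by the core/non-core split
  (`P_nc = G_nc G_cc⁻¹`, `Ψ = diag(G_nn − P_nc G_cn)`), with core animals
  selected uniformly at random under a dedicated seed.
  `log|H| = log|A| − log|A22| + log|G|`.

## Breeding-value simulation

`u ~ N(0, θ ⊗ H)` is sampled without forming `H`:

1. gene-drop `a_i = 0.5(a_s + a_d) + L x̃ √φ_i` down the pedigree
   (`LL′ = θ`), vectorized over pedigree depth levels and over a batch axis;
2. marker effects `g_i = L x̃ (2Σpq)^{−1/2}` per locus and one J-factor draw
   `μ = L x̃ √v` per trait-column;
3. genotyped animals: `u₂ = √(1−α)(1μ + Mg) + √α a₂` and
   `δ = √(1−α)(1μ + Mg) + (√α − 1) a₂`;
4. non-genotyped animals: `u₁ = A12 A22⁻¹ δ + a₁`, computed by default
   through the sparse identity `A12A22⁻¹ = −(B11)⁻¹B12` (blocks of `A⁻¹`),
   with a dense `A12`/`A22`-solve backend retained for cross-checks.

Under APY, steps 3–4 use only the core marker rows; non-core animals get
`u_n = P_nc u_c + ψ` with `ψ_i = L x̃ √Ψ_ii`, and with the full genotyped
set as core the APY path reproduces the plain path bit-for-bit on the same
random stream.  Phenotypes are `ỹ = Σ_k Z_k k̃ + ẽ` with pattern-restricted
residual draws; fixed effects contribute zero to `ỹ` but stay in the fitted
model, which leaves the REML error contrasts unaffected.

Randomness is addressed, not consumed in order: every draw site is keyed by
`(base_seed, sample_index, site_name, round_key)` through SeedSequence +
Philox, so draws are reproducible regardless of evaluation order and, with
`reuse_sequence = true` (default), every REML round consumes the identical
standard-normal sequence — round-to-round variation in the traces then
comes only from `θ`, which is what makes CV(logL) a usable convergence
statistic.  The Cholesky factor of `θ_k` is recomputed each round; the
underlying normals are not redrawn.

## Trace estimation and REML updates

Per round: solve the data MME by PCG (block-diagonal preconditioner over
(level × trait) blocks, zero fixed-effect pivots pseudo-inverted; tolerance
1e-10), compute `S_k = Û′K⁻¹Û` and residual cross-products, then for each of
`s` samples simulate, solve at the relaxed tolerance 1e-6 (cold-started:
warm-starting sample solves bought nothing in our experiments), and
accumulate the primary estimators

* `T̂_k = q_k θ_k − s⁻¹ Σ û~′K⁻¹û~`
* `TRW = n R0 ∘ (obs pattern) − s⁻¹ Σ ê~′ê~` per missingness pattern,
  where `TRW` estimates the per-record sums of `QC⁻¹Q′` blocks.

Centered variants (differences `k̃ − k̂̃` and `ẽ − ê~`) are available behind
`mc.variant = "centered"`; the primary forms are the default because the
centered ones need more samples for the same accuracy.  The residual
estimator treats the weighting between simulated residual vectors as the
identity (plain dot products over shared observed records): residuals are
i.i.d. given `R`, and the estimator is verified unbiased against the dense
oracle under exactly this reading.

Updates:

* EM: `θ_k ← (T_k + S_k)/q_k`; residual `R0_ij ← (ê_i′ê_j + TRW_ij)/n_ij`.
  The residual rule is exact EM for complete records and the standard
  per-pair convention under missingness.  Updates that leave the parameter
  space (possible under MC noise) are projected to the nearest SPD matrix
  with a logged warning, masks re-applied.
* Gradient of −2ℓ: `D_k = q_kθ_k⁻¹ − θ_k⁻¹(T_k+S_k)θ_k⁻¹` for groups and a
  pattern-stratified residual expression; off-diagonal vech entries carry a
  factor 2 (symmetric-perturbation convention), matching central finite
  differences of the exact −2ℓ to ~1e-7 relative in the suite.
* AI: `AI[p,q] = f_p′P f_q` with `f_p = (∂V/∂θ_p)Py`, evaluated as
  `f_p′R⁻¹f_q − (Q′R⁻¹f_p)′C⁻¹(Q′R⁻¹f_q)` — one linear solve per free
  parameter.  The update is `vech(θ)⁺ = vech(θ) − AI⁻¹∇`; if it leaves the
  parameter space the AI matrix is blended with the complete-data (EM)
  information `q_k D′(θ⁻¹⊗θ⁻¹)D` at escalating weights
  {0.1, 0.3, 0.5, 0.9, 1.0}, falling back to the pure EM update.  The
  blending schedule is this package's choice; reference software does not
  publish one.
* Standard errors: `SE = sqrt(diag(2·AI⁻¹))` at the optimum — the factor 2
  because AI tracks −2ℓ curvature — validated against the closed-form
  asymptotic variances of balanced one-way REML.

The restricted log-likelihood is computed exactly from factorizations:
`−2ℓ = log|C| + log|R| + Σ_k (q_k log|θ_k| + t_k log|K_k|) + y′Py`, with
`log|H|` from the three-term identity.  This assumes a full-rank fixed-effect
parameterization (class effects with levels taken from observed records
satisfy it).  At desk scale a dense Cholesky of `C` is affordable and is
reused within a round for the AI solves; this is an implementation
convenience of the benchmark-capable code path, not part of the MC method —
at production scale one would substitute a stochastic log-likelihood
approximation and per-parameter PCG solves, and the `ai_matrix` contract
accepts any solver callback.

Convergence uses two thresholds: `Δθ < t1 = 1e-12` (max relative parameter
change) or `CV(−2ℓ) < t2 = 1e-4` over the last five rounds — the CV
criterion exists because MC noise keeps `Δθ` from reaching t1.  Defaults:
starting values 1.0 (variances) and 0.1 (covariances), 30 MC samples,
at most 100 rounds.  For exact-trace runs that must resolve the optimum to
high precision (e.g. comparisons against closed forms), set `t2 = 0` so the
loop runs to the `Δθ` criterion; EM's linear convergence otherwise stops at
the CV plateau first.

## Synthetic data

The generator emulates a beef-cattle growth evaluation at desk scale:
discrete generations with random mating, founder allele frequencies
Uniform(0.05, 0.95) with gene-dropped biallelic loci, a genotyped subset
(youngest animals by default, as in routine evaluations), records for all
non-founders with per-trait Bernoulli missingness, and contemporary groups
formed as generation × random block.  The default model is the three-trait
template (bw/ww/pwg; direct + maternal genetic with one shared relationship
structure; maternal permanent environment for ww; residual covariances with
pwg and most direct–maternal pairs masked to zero; α = 0.05) with true
(co)variances at realistic magnitudes for such a model (e.g. direct bw
variance 24.9, ww residual variance 1443.6).  Default sizes
(60 founders, 4 generations, 30 matings × 4 offspring, 400 loci, 25%
genotyped) keep every downstream computation dense-checkable; tests override
them per fixture.

True breeding values are gene-dropped from the *pedigree* covariance by
default, which keeps truth generation independent of the single-step
machinery under test; note that exact ss-GREML fitted with `K = H` is then
deliberately mis-specified relative to the truth and recovers attenuated
genetic variances — recovery experiments therefore use
`truth_structure = "h"`, which routes the truth through the ssGBLUP sampler
so the fitted covariance is correct.  What the generator does **not**
emulate: linkage disequilibrium and QTL architecture (loci are independent
and effect-free; `G` carries only realized-relationship information),
selection (mating is random), overlapping generations, heterogeneous
residual variances.  Passing tests therefore demonstrate the correctness of
the estimation machinery under the stated model, not robustness to the ways
real cattle data violate it.

## Numerical choices

* PCG preconditioner: per-level trait-block diagonal of `C` (exact
  inversion of each small block); fixed-effect rank deficiency is handled by
  pseudo-inverting zero pivots, REML being invariant to the fixed-effect
  parameterization.
* Dense reference paths refuse beyond 5,000 equations.
* `Δθ` denominators carry ε = 1e-10; SPD projections floor eigenvalues at
  1e-8 of the largest.
* Empirical-covariance tests compare every matrix entry to its target at 3
  Monte Carlo standard errors; over thousands of entries the 3σ rule itself
  implies ~1% exceedances, so the tests require ≥99% of entries within 3 SE
  and no entry beyond 5 SE, rather than pretending a strict elementwise 3 SE
  bound is attainable.
* Test and acceptance problem sizes (about 300 animals for trace accuracy,
  2,000 for the exact-vs-MC comparison, 20 replicates for recovery) were
  chosen so each check resolves its question at desk scale.

## Known limitations

* All matrices live in memory; there is no out-of-core "iteration on data"
  storage, and the exact benchmark is limited by the dense guard.
* Metafounders, multiple J-factors, and heterogeneous marker weights are
  out of scope (the sampler's marker step is the hook where weights would
  enter).
* The stochastic log-likelihood approximation used by large-scale
  implementations is not implemented; exact logL plays that role here, so
  CV(logL) is noise-free in both trace modes.
* Phantom dam levels are supported only for identity-structured maternal
  groups; records with unknown dams are dropped (logged) under genetic
  maternal models.
* The EM residual update under missingness is the field-standard per-pair
  rule, whose fixed point can differ marginally from the REML optimum;
  AI-REML uses the exact pattern-stratified gradient and is unaffected.
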