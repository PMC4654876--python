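# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of the package. Nothing
here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The pipeline treats a quantitative trait measured once per animal in a
paternal half-sib cohort. Analysis proceeds in three stages.

**1. Adjustment and variance components.** The trait is modelled as

    y = X b + W c + u + e

where X holds breed type, gender and production system (reference-coded,
first level alphabetically as reference) plus linear covariates — age at
slaughter (days), days from slaughter to lipid extraction, diet metabolic
energy, and for muscle traits the marbling score as a proxy for
intramuscular fat; W is the incidence matrix of contemporary groups
(feedlot location × year), c ~ N(0, I σ²_cg), u ~ N(0, G σ²_a) with G the
VanRaden method-1 genomic relationship matrix, and e ~ N(0, I σ²_e).
Variance components are estimated by average-information REML.
Heritability is reported as h² = σ²_a / (σ²_a + σ²_cg + σ²_e) by default;
whether the contemporary-group variance belongs in the denominator is a
modelling choice, so `REMLResults.heritability(include_cg=False)` exposes
the alternative. The SE of ĥ² comes from the delta method applied to the
inverse average-information matrix. Adjusted phenotypes are
y* = y − X b̂ − W ĉ (fixed-effect GLS solutions and contemporary-group
BLUPs removed; genetic and residual parts retained).

Animals with missing covariates are dropped with a warning rather than
mean-imputed; with a complete synthetic generator this path only triggers
on user-supplied data.

**2. Association.** y* is regressed on all SNPs jointly under the BayesCπ
mixture prior. Conditionals per Gibbs iteration:

1. μ from its normal full conditional (flat prior);
2. for each SNP j in ascending map order, the inclusion indicator γ_j from
   its Bernoulli conditional — the marginal likelihood ratio of inclusion
   is computed in log space — and, if γ_j = 1, the effect a_j from its
   normal conditional;
3. σ²_a from a scaled inverse chi-square with df v_a + m (m = number of
   included SNPs) and scale combining S²_a and Σ a_j²;
4. σ²_e likewise with df v_e + n;
5. π from Beta(M − m + 1, m + 1), the full conditional under a uniform
   prior.

Hyper-parameters: v_a = 4, v_e = 10;
S²_a = σ̂²_u (v_a − 2) / [v_a (1 − π) Σ 2p_j(1−p_j)] and
S²_e = σ̂²_0 (v_e − 2)/v_e, where σ̂²_u and σ̂²_0 are the REML additive and
residual variances from stage 1. Because the S²_a formula references π while
π itself is sampled, the scale is frozen at the initial π (default 0.9) —
the scale must exist before sampling starts, and re-scaling per iteration
would change the stated prior. Initialisation: a = 0, π = 0.9, σ²_a = S²_a,
σ²_e = σ̂²_0, μ = mean(y*). The per-SNP association statistic is the PPI
(post-burn-in mean of γ_j); the reported allele substitution effect is the
unconditional posterior mean (zero draws included). A fixed-π mode
(plain BayesC) exists mainly so that π = 0 with fixed variances can be
checked against the closed-form ridge posterior.

Genome-wise significance uses phenotype permutation: y* shuffled, genotypes
intact, one sampler run per permutation, the maxima of PPI sorted ascending
(stable sort; ties keep their order) and the ceil((1 − α)·n_perm)-th value
taken as threshold — rank 950 of 1000 at α = 0.05. The percent of genetic
variance explained by a significant SNP is reported as
100·2p(1−p)a²/σ̂²_u using the unconditional posterior-mean effect; this
formula is the conventional single-locus variance under Hardy-Weinberg and
is flagged as a reconstruction in the output metadata since no unique
definition exists for correlated loci.

**3. Prediction.** Animals are split into k = 10 folds by whole sire
families (greedy largest-first packing into the smallest fold, then a
repair pass that moves families to restore breed coverage; deterministic
given the seed). GBLUP solves y* = 1μ + Za + e with validation records
absent, via two algebraically equivalent routes that are cross-checked in
the tests: the mixed-model equations over all animals, and the kernel form
â_v = G_vt (G_tt + λI)⁻¹ (y*_t − 1μ̂) with λ = σ²_e/σ²_a. The intercept μ̂
in the kernel route is the GLS estimate (1'V⁻¹1)⁻¹1'V⁻¹y* rather than the
arithmetic training mean: the two routes then agree to machine precision,
whereas a plain mean leaves an O(1/n) discrepancy. PBLUP substitutes the
pedigree A matrix. BayesCπ GEBVs are Σ_j x_ij â_j with effects estimated
on the training fold only. Variance components and h² are re-used from the
full-data REML fit (per-fold re-estimation would change the question being
asked — how well do fixed components predict — and the full-data components
are what a breeding program would carry forward). Realized accuracy is
r(EBV, y*)/√ĥ² per fold, aggregated as mean ± sd/√k; the slope of y* on
EBV measures bias. Folds with degenerate (zero-variance) predictions are
flagged NaN rather than given a number — with a one-generation, dam-less
pedigree, PBLUP on sire-disjoint folds is exactly information-free and
reports as such.

## The synthetic generator

The generator emulates the cohort structure this analysis assumes, not
bovine genome biology:

- **Genotypes / LD.** A pool of founder haplotypes (default 60) is drawn
  per LD block (default 10 SNPs, never spanning chromosomes) from a
  first-order Markov chain along SNPs: each allele copies its left
  neighbour with probability `ld_decay` (default 0.8), else is a fresh
  Bernoulli draw at that SNP's frequency (uniform in `allele_freq_range`).
  Gametes copy whole blocks from the pool, so dosage correlation decays
  geometrically within a block and is zero across blocks. This exercises
  correlation pruning and the smearing of PPI across a QTL's block; it is
  not a coalescent model and has no recombination map.
- **Pedigree.** Each offspring receives one gamete from its sire (one of
  the sire's two block-haplotypes per block) and one fresh population
  gamete; dams are unrecorded, matching a thin one-generation pedigree.
  Families are as equal-sized as possible (n/n_sires).
- **Trait.** phenotype = intercept (10.0) + fixed effects + TBV +
  contemporary group + residual. Fixed-effect magnitudes default to
  0.25–1.0 phenotypic SD — large enough that adjustment matters, not
  dominant. Contemporary groups: 8 levels (2 locations × 4 years) assigned
  uniformly. TBV = centred-dosage × effects over the chosen QTL: each of
  `n_large_qtl` QTL gets an equal share of
  `large_qtl_var_fraction` × σ²_a (effect sized against its sample dosage
  variance, random sign), and the polygenic effects (iid normal over
  `n_poly_qtl` SNPs, default min(200, M/4)) are rescaled so the polygenic
  variance is exactly the remainder. The residual vector is likewise
  rescaled exactly, so realized h² differs from the target only through
  the 8-draw contemporary-group variance.
- **What passing tests do not show.** Real data have genotyping error,
  population stratification confounded with breed, selection, multi-breed
  LD heterogeneity and covariates correlated with genetics; none are
  simulated. Recovery results here validate the estimators under their own
  assumptions, not robustness to these violations.

## Numerics

- **AI-REML** runs on the eigenbasis of G + 1e-6·I (the ridge is needed
  because VanRaden G has zero row sums, hence is singular). In that basis
  the covariance is diagonal plus a rank-q contemporary-group term, handled
  by the Woodbury identity, so an iteration costs O(n q²) after a single
  O(n³) eigendecomposition. Updates: AI (Newton) direction with
  step-halving, falling back to the EM-REML update
  σ²_i ← σ²_i + σ⁴_i (y'P V_i P y − tr(P V_i))/q_i, which cannot leave the
  parameter space; accepted steps never decrease the restricted
  log-likelihood, and variances are floored at 1e-8·var(y) (boundary
  projection). Convergence: |Δ logL| < 1e-6 or max |Δθ| < 1e-8; failure
  raises a convergence error carrying the last estimates. A near-singular
  AI matrix (e.g. G = I, where σ²_a and σ²_e are jointly unidentifiable)
  triggers an identifiability warning and reports the boundary solution.
- **Gibbs kernel** (numba): residuals are maintained incrementally
  (y − 1μ − Xa updated per accepted effect change) so a full sweep is
  O(nM), with a full recomputation every 2000 iterations against float
  drift; the inclusion log-odds are clipped at ±35 before
  exponentiation. Chains are bit-reproducible given (seed, chain length,
  update order); the SNP update order is ascending map order by default
  with a randomised-order option.
- **Correlation pruning** compares each candidate against the previous 50
  retained SNPs on the same chromosome (the window and the keep-first rule
  are choices; genome-wide all-pairs pruning would be O(M²) and the scope
  of the original filter is not observable from its description). MAF
  exactly at the 0.05 boundary is kept ("less than" removed).
- **HWE** uses the 1-df chi-square goodness-of-fit test; monomorphic SNPs
  return p = 1. An exact test would differ at tiny expected counts, but
  those SNPs are removed by the MAF filter first.
- **Imputation** draws Binomial(2, p̂_j) per missing call — allele
  frequencies are preserved in expectation and the operation is seeded; at
  the sub-percent missingness this pipeline expects after filtering, LD
  information would change almost nothing.
- Permutation analyses derive one chain seed per permutation from a single
  seed stream; the pipeline derives per-stage seeds from the global seed by
  hashing stage names, so partial re-runs reproduce full runs.

## Validation studies and problem sizes

`bovigen.validation` packages the simulation studies run by the acceptance
script and tests (sizes chosen to complete in minutes on one CPU):

- heritability recovery: 10 cohorts at n = 1500, M = 2000, h² = 0.5, fitted
  with the matched (marbling-included) adjustment model;
- PPI contrast: 5 cohorts at n = 1000, M = 2000 with one QTL carrying 25%
  of genetic variance, chains of 2000 (burn-in 500); "null" SNPs are those
  in LD blocks containing no simulated QTL — SNPs in LD with real small
  QTL are not null and are excluded from that summary;
- genome-wise type-I error: 100 pure-noise replicates × 50 permutations at
  n = 200, M = 100, chains of 500 (burn-in 100);
- accuracy comparison: 5 cohorts per architecture at n = 600, M = 600,
  5 sire-family folds, chains of 2000 (burn-in 400); "large-QTL" = two QTL
  sharing 50% of genetic variance, "polygenic" = 300 small QTL;
- oracle agreements and GRM invariants at n = 200–2000.

## Limitations

Single-trait only (no genetic correlations between tissues or traits); no
multi-generation inbreeding; no single-step (H-matrix) evaluation; no
reference-panel imputation or phasing; the permutation threshold at
production scale (1000 × 45 000-iteration chains) is cluster-scale work —
the package exposes the same code path at reduced scale and leaves the
production sizes as configuration defaults.
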