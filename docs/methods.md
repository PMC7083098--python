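# Methods

## Model

For species *s*, the trait vector of fish *i* on its *j*-th trial is

    y_ij = X_ij β + u_i + e_ij,    u_i ~ N(0, ID_s),   e_ij ~ N(0, R_s)

with four traits (tracklength TL, activity Act, area covered AC,
time-in-middle TIM). Fixed effects per trait are an intercept, a categorical
*repeat* effect (one level per cumulative trial number, controlling
habituation) and a linear *within-group order* slope (controlling netting
stress and cue build-up as a group of tank-mates is assayed in sequence).
`ID` is the among-individual covariance matrix — the quantity of interest —
and `R` the residual (within-individual) covariance, both unstructured.
Assumptions: Gaussian individual and residual deviations, individual effects
constant across trials (no individual-by-repeat interaction), homogeneous
`R` across repeats, and independence across individuals.

### Estimation

Restricted maximum likelihood. Because every individual with *n* trials has
marginal covariance `V = I_n ⊗ R + J_n ⊗ ID` (trial-major layout), the
restricted log-likelihood and its analytic gradient are evaluated per
trial-count group with dense algebra only in the `nT × nT` block; fixed
effects are profiled out by GLS. Optimization is L-BFGS-B on Cholesky-type
factors: `ID = LL'` with free entries, so boundary (singular) solutions are
admissible, and `R = L_R L_R'` with exponential diagonal, so `R` stays
positive definite. Symmetry and (semi)definiteness therefore hold by
construction. Convergence: relative objective change below 1e-11 or
projected-gradient norm below 1e-7, at most 1000 iterations; non-convergence
is reported on the fit, never silently accepted. Starting values are
moment-based (between- minus scaled within-individual covariance of
individual means, eigenvalue-floored).

The univariate repeatability fits are the one-trait case of the same
engine (verified against statsmodels MixedLM to ~1e-5 and against the
balanced-ANOVA closed form). The reduced model of the 6-df covariance test
constrains `ID` to be diagonal while `R` stays unstructured — the published
description fixes only the ID covariances at zero, so the residual
covariances are left free. The pairwise equality test fits an 8-trait
blocked model; with no cross-species covariance and disjoint individuals the
unconstrained likelihood separates into the two species' fits, while the
constrained fit shares one `ID` (10 parameters) across species with
species-specific `R` and fixed effects, giving the 10-df LRT.

### Tests and intervals

- Significance of `V_I` uses the boundary LRT referred to a 50:50 mixture of
  a point mass at zero and chi-square(1): `p = 0.5·P(χ²₁ > stat)`, `p = 0.5`
  at `stat = 0`.
- The 6-df and 10-df LRTs use ordinary chi-square references; p-values
  across the 21 species pairs are nominal — no multiplicity correction, as
  the comparisons are non-independent by design.
- Parametric bootstrap: each draw simulates a complete dataset from the
  fitted model on the original design and refits; the refitted `ID` matrices
  form the ensemble. Default 200 draws at desk scale (5000 at paper scale);
  failed refits are excluded and counted. CIs are 2.5/97.5 percentile bands;
  for pairwise statistics, draw *i* of one species is paired with draw *i*
  of the other (ensembles are independent across species).

## Comparison statistics

- `Δ = |tr(ID₁) − tr(ID₂)|`; its CI is the percentile band of the *signed*
  trace difference, so "CI excluding zero" is the significance reading.
- `θ = arccos |v₁·v₂|` in degrees for unit leading eigenvectors, folded into
  [0°, 90°] because eigenvector sign is arbitrary. Eigenvectors with
  near-tied eigenvalues (gap < 1e-8) are flagged as directionally unstable.
  Bootstrap draws are matched by eigenvalue rank; no re-matching of axes
  across draws is attempted, so CIs for θ can legitimately be very wide when
  λ₁ ≈ λ₂.
- Krzanowski `K = Σ eig(AᵀBBᵀA)` for `n × x` orthonormal bases of the
  leading eigenspaces, `x ≤ n/2` enforced; reported as dissimilarity
  `x − K`. Published loading vectors carry rounding, so they are
  renormalized, and for subspace work QR-orthogonalized keeping the printed
  directions.

## Phylogenetic signal

Patristic distances come from the species tree (dendropy); the association
with each behavioral dissimilarity table is Kendall tau-b over the 21
unordered pairs, vectorized in alphabetical species order (any shared order
gives the same tau). Tau-b's tie correction matters: the distance matrix has
only six distinct values. The nested bootstrap draws, per replicate, one
tree from the tree set and one `ID` per species from its ensemble, rebuilds
the dissimilarity table and recomputes tau; the CI is the percentile band
over replicates. The point estimate uses the designated point tree with the
point `ID` estimates — the bootstrap supplies only the CI. No permutation
p-values are computed.

The reference phylogeny is the unique ultrametric tree reproducing the
published substitutions-per-site distance matrix (leaf-pair distance equals
twice the MRCA depth); the test suite verifies the reproduction entrywise.
The tree-set generator jitters branch lengths multiplicatively
(log-normal, median 1, log-SD `jitter`, default 0.1) with fixed topology — a
deliberately minimal stand-in for posterior tree uncertainty.

## Canonical variate analysis

Each fish is reduced to its within-individual mean trait vector; axes solve
the generalized eigenproblem `B a = λ W a` with `W` the pooled within-species
covariance and `B` the scatter of species means, *unweighted* by sample size
(samples range from 26 to 831 fish, and no weighting was specified — the
unweighted convention avoids letting the guppy sample dominate the between
scatter). Scores are sphered (pooled within-species covariance identity);
confidence ellipses describe the 95% spread of the score distribution
(covariance scaled by the chi-square(2) quantile), not the mean's standard
error.

## Preprocessing

Fixed order: (1) TL (cm) → body lengths via `10·TL/SL` with the *species
mean* standard length in mm (using individual lengths would conflate
personality with within-species size variation); (2) TIM → √TIM;
(3) all traits centred and scaled to global SD units (SDU) using trial-level
statistics pooled over every observation of every species, so species mean
differences survive. Sample SD (n−1) throughout. Whether the original
standardization used trial-level or individual-mean-level SDs is not
recorded; trial-level is assumed and flagged here.

## Synthetic data

The generator draws from exactly the model above. Trait means, `ID` and `R`
are specified on the analysis scale (body lengths, %, %, √s), with the
seven default species configured so that:

- each species' `ID` reproduces the published eigenstructure — printed first
  two eigenvectors (orthonormalized) with their printed eigenvalues, the
  remaining variance (printed trace minus the leading two eigenvalues) split
  60:40 over the orthogonal complement;
- `R` gives each trait a low-to-moderate repeatability, as reported, with a
  mild uniform residual correlation of 0.25;
- species means sit within ~1 SDU of each other so the pooled SD is close to
  one by construction — the generator's scale *is* the analysis scale, and
  raw recorded units (cm, %, %, s) are produced by inverting the
  deterministic transforms. Re-standardizing a single simulated species
  rescales units by ~1/√(ID_tt+R_tt); single-species recovery tests
  therefore fit on the analysis-scale columns directly.
- sample sizes: 26–831 individuals per species summing to the study's 1479
  fish, 4–6 trials each; only the extremes were attributable to particular
  species, the rest are a plausible allocation. Groups of 8 tank-mates are
  assigned cyclically in individual order with within-group order 1..8 (the
  original assignment rule is unrecorded).

What the generator does *not* emulate: tracking noise, arena geometry and
tank-size effects, sex structure, percentage-trait boundary effects (Act/AC
are Gaussian, not bounded), and non-Gaussian residuals. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them. √TIM values are clipped at zero before
squaring into seconds; with default means (≈8√s vs SD ≤ ~1) clipping is a
≥8-sigma event and has no practical effect.

## Numerical choices and problem sizes

- LRT statistics are clipped at zero; a strongly negative statistic (full
  model below the reduced one) raises an error pointing at convergence
  order.
- The desk-scale test suite uses reduced problem sizes chosen to keep each
  statistical check meaningful: ID recovery at 500 fish × 5 trials with a
  60-draw bootstrap SE; LRT type-I calibration on 200 null replicates at
  50–60 fish × 4 trials (rejection count compared with the binomial 95% band
  around 5%); trace-CI coverage on 100 replicates of a two-trait model at
  50 fish × 4 trials with 100-draw ensembles (coverage compared with 95%
  allowing binomial noise and the known small-sample undercoverage of
  percentile intervals).
- One internal inconsistency of the published tables is handled explicitly:
  the printed θ for *D. rerio*–*P. reticulata* (73.1°) does not follow from
  the printed loadings of those two species (which give 53.1°) and appears
  to be a typographical duplicate; the reproduction tests assert the other
  20 pairs to 0.6° and document this one.

## Known limitations

- No Bayesian/MCMC estimation, no pedigree (additive-genetic) models, no
  factor-analytic or structural-equation decompositions of `ID`, no Flury
  hierarchy or random-skewers comparison, and no formal phylogenetic
  comparative models (seven species is too few); these are out of scope.
- Which tree (summary tree, posterior draw, or posterior-mean distances)
  produced the original point correlations is not recorded; the
  comparison-only workflow uses the distance-matrix-consistent fixture tree
  and treats the published 0.320 subspace correlation with a ±0.05 band
  rather than asserting intent.
- The original study reported unstable convergence for pair models involving
  *L. nigrofasciata* for unknown reasons; this implementation reports
  failures honestly (flagged fits, counted bootstrap exclusions) but does
  not attempt to emulate that behavior.
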