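# Methods

## The model and its assumptions

`nbgwas` treats a field of n inbred individuals on known planar positions.
Each biallelic marker is coded x ∈ {−1, +1} (reference → −1); heterozygous
calls are rejected rather than guessed at, because the neighbor covariate
x_i·x_j has no canonical extension to heterozygotes without a dominance
weight. The fitted model per marker k is

y = Wτ + β1 x_k + β2 X2_k + [β12 X12_k] + u + e,
u ~ N(0, σ1²K1 + σ2²K2), e ~ N(0, σe²I),

with W a fixed design (default: intercept; field analyses would add
covariates such as block or plant size). X2_k is the neighbor genotypic
identity: the mean over the L neighbors within reference scale s of the
product x_i x_j, bounded in [−1, 1], zero when identical and different
alleles balance. X12 = X1 ⊙ X2 is the asymmetric interaction covariate:
it lets neighbor similarity act on carriers of one allele only.

Neighborhoods are nested distance shells: j is in shell t of i iff
δ_{t−1} < d(i,j) ≤ δ_t with δ_0 = 0 (Euclidean distance, exact symmetry).
On a unit-spaced checkered lattice the thresholds δ_s = s·√2·(1+10⁻⁶) give
interior individuals L = 4 at s = 1 (diagonal nearest neighbors) and
L = 12 at s = 2. Edge individuals keep their true, smaller L; isolated
individuals get zero covariates and a logged warning instead of exclusion,
so n never changes.

Kinships: K1 = X1X1ᵀ/(q−1) rescaled entrywise to (k+1)/2, so entries read
as the shared-locus proportion with unit diagonal; K2 (and K12) are the
raw cross-product similarities of the neighbor (asymmetric) covariates.
The n×n orientation (individuals on rows) is used throughout.

## Collinearity and the conservative testing order

Self and neighbor covariates of the same marker are correlated, the more
so the lower the MAF and the broader the scale (at whole-field scale
X2_k = x_k·x̄, perfectly collinear). `collinearity_diagnostics` reports
the per-marker correlation. All inference is therefore ordered: the self
effect is tested against the K1-only null (exactly standard mixed-model
GWAS — the neighbor model is a superset that reduces to it at s = 0,
σ2² = 0), and the neighbor effect against the two-component model that
already contains the marker's self effect. Likewise partial PVE_nei is
tested by the LRT of the (K1+K2) model against the K1-only model, and the
reported genome-wide neighbor contribution is the net PVE_nei =
(partial self + partial nei) − single self, not the single PVE_nei, which
overstates it whenever K1 and K2 overlap.

## Variance-component estimation (AI-REML)

`reml_fit` maximizes the restricted likelihood over non-negative variance
components. Details the estimator needs but the model statement does not
fix: initialization at an equal split of the OLS residual variance;
average-information (quasi-Newton) steps with backtracking halving;
projection onto the non-negativity box with an active set — a component
at zero whose score is negative stays pinned until its score turns
positive, and components with zero information are pinned outright; an
EM-style multiplicative fixed-point update as fallback when no damped AI
step improves the likelihood; convergence when the restricted
log-likelihood moves by < 10⁻⁶, with a 100-iteration cap and an explicit
`converged` flag that propagates to downstream results. Likelihood-ratio
statistics for variance components are referred to plain χ²₁ (the
reporting convention adopted throughout); the 50:50 boundary-mixture
correction is available but off by default, making the default tests
conservative.

The genome scan is the plug-in (EMMAX-style) approximation: variance
components are estimated once on the no-marker model, the combined matrix
(σ̂1²K1 + σ̂2²K2)/σ̂e² is eigendecomposed once, and every marker model is a
weighted least-squares fit in the rotated basis with the overall residual
scale profiled by ML. Exact per-marker re-estimation exists behind a flag
for validation. A test column whose rotated design has condition number
> 10¹⁰ is flagged and reported with p = 1. Monomorphic markers and
constant neighbor covariates are likewise flagged with p = 1.

## Effective spatial scale

ΔPVE_nei(s) = partial PVE_nei(s) − partial PVE_nei(s−1), with the s = 0
value defined as 0 since no neighbor component exists there; ŝ = argmax
ΔPVE, ties to the smallest s. Under strong distance decay the profile
saturates at the first shell and ŝ = 1 — this reproduces robustly. Under
very weak decay the partial PVE keeps rising with s, but because
successive neighbor kinships are strongly mutually correlated
(element-wise R² ≈ 0.7 between s = 2 and s = 3 on a checkered lattice),
the first shell already absorbs a large share and the base increment at
s = 1 usually remains the largest; ŝ then still sits at 1–2 rather than
s_max. The estimator therefore discriminates "narrow" sharply but flags
"broad" only through a rising profile, not through ŝ itself — a known
limitation documented here rather than patched over.

## The phenotype simulator

The generator is deliberately richer than the fitted model. Genotypes are
Balding–Nichols draws: per-marker ancestral frequency uniform on
(maf_min, 1−maf_min), Beta-perturbed subpopulation frequencies with
variance set by F_ST, fully inbred ±1 individuals, markers redrawn until
the realized MAF respects the floor. Defaults (3 subpopulations,
F_ST = 0.1, maf_min = 0.1) give element-wise K1–K2 overlap below the
0.62–0.84 range reported for real A. thaliana panels — i.e. the synthetic
data are, if anything, easier to partition than real data, which is the
right direction for a conservative test bed. Individuals are placed
uniformly at random on the occupied cells of a (checkered) grid.

Causal markers (10/50/300 in the study grid) split 15% self+neighbor+
asymmetric, 15% self+neighbor, 35% self-only, 35% neighbor-only
(largest-remainder rounding, ties to the earlier class), with independent
±1 coefficients. Phenotypes follow

y_i = β1 x_i + (β2/L_w) Σ w(t,α) x_i x_j + β12 (x_i/L_w) Σ w(t,α) x_i x_j
      + u_i + e_i,

built from column-standardized genotypes, with exponential distance decay
w(t, α) = e^{−α(t−1)} over shells up to s_max = 3. The decayed covariate
is normalized by the decay-weighted neighbor count L_w = Σ_t w(t,α)L_t,
so it reduces to the plain cumulative-L covariate at α = 0 and converges
to the unweighted first-shell covariate as α → ∞ — the natural
generalization that keeps the covariate a weighted mean of products. The
fitting model always uses the unweighted covariate at a single scale;
this mis-specification is intentional and part of what the power study
measures.

Two design choices the model statement leaves open, resolved here:

- **The PVE ratio applies to effect classes, not only to the random
  part.** The triple PVE_self:PVE_nei:PVE_s×n scales the self, neighbor,
  and asymmetric blocks of both the major-effect (fixed) part and the
  polygenic background: each sub-block is normalized to unit realized
  variance and weighted by the square root of its ratio share. This makes
  the ratio mean what its name says — the relative contribution of each
  effect type to the phenotype — makes 1:0:0 a phenotype with no neighbor
  effects at all, and lets the ratio govern neighbor-detection power, all
  of which the method's expected behavior requires. With ±1 coefficients
  on raw covariates instead, the neighbor fixed signal would be a few
  percent of the self signal at any ratio, and the ratio could not move
  the neighbor AUC.
- **Two-block calibration.** Scalars a (fixed block) and b (random block)
  are set by alternating 1-D Brent root solves on the realized variance
  fractions, so that var(a·fixed)/var(y) = PVE_β and var(b·u)/var(y) =
  PVE_u exactly for the realized draws (cross-covariances included);
  calibration aborts with the achievable range if a target cannot be
  bracketed. y is then standardized to mean 0, variance 1; realized
  fractions and the per-class coefficient scales are stored with the
  truth so estimates can be mapped back to the generative scale (estimate
  × sd of the raw phenotype, divided by the genotype column sd).

What the generator does not emulate: linkage disequilibrium along the
chromosome (markers are independent given structure), dominance, shared
micro-environment beyond the lattice, and missing data. Power numbers on
synthetic data therefore say that the machinery extracts the signal its
model class can represent — not that real fields behave this way.

## Evaluation statistics

ROC/AUC from −log10(p) against the simulator's causal labels (midrank tie
handling, i.e. the Mann–Whitney statistic); sensitivity is the TPR at the
largest threshold with empirical FPR ≤ 0.05 (step-function convention, no
interpolation); MAE compares back-scaled coefficient estimates with
generative truth; PVE accuracy is the signed relative error of the total
PVE. Problem sizes for the bundled studies: n = 400, q = 1000, 10
replicates for calibration and power checks; n = 200, q = 300–500 for
structural and recovery checks; chosen as the smallest sizes at which the
regimes of interest (null AUC ≈ 0.5, strong-regime AUC > 0.9) are stable
across seeds.

## Forward Ising search

For a marker with coefficients (β1, β2) the population sum over a lattice
is Σy_i = β1Σx_i + 2β2Σ_pairs x_i x_j (each unordered first-shell pair
counted from both members; checkered grids pair the four diagonal
neighbors, full grids the four orthogonal ones). `anneal` runs Metropolis
single-spin-flip annealing from a uniform random start with geometric
cooling from T = 10 to T = 0.01 over n_iter sweeps (one proposed flip per
site per sweep; "iteration" = sweep, configurable) and returns the best
state visited. Allele counts are unconstrained (flip dynamics); β2 > 0
yields mixed optima, β2 < 0 clustered ones, β1 biases the allele balance.
Small lattices are verified against exhaustive enumeration.

## Reproducibility

Every stochastic stage takes a single integer seed and derives sub-seeds
by `numpy.random.SeedSequence` spawning, so identical seeds give
bit-identical phenotypes, scans, and CLI output files; each CLI result is
paired with a metadata JSON sufficient to re-run it.
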