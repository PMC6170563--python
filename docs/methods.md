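# Methods

This note records the models, conventions and numerical choices behind
`econetres`, in the order the pipeline applies them.

## Network resilience

A plant–animal mutualistic web is a binary incidence matrix `M` (n plants ×
m animals).  Before projection, weighted webs are binarized (an entry becomes
1 when its value exceeds a threshold, default 0: any observed interaction
counts) and zero rows/columns are pruned iteratively; an unobserved species
carries no network information and would put a zero in the inverse-degree
denominators below.

Each side is projected onto a weighted one-mode network by summing the
inverse degrees of shared partners:

    plant side:   A_ij = Σ_k M_ik M_jk / Σ_s M_sk
    animal side:  A_ij = Σ_k M_ki M_kj / Σ_s M_ks

Sharing more partners couples two plants (animals) more strongly; a
generalist shared partner contributes less to each pair.  The macroscopic
resilience parameter of the effective one-dimensional dynamics is

    β_eff = Σ_ij A_ij A_ji / Σ_ij A_ij

For the symmetric `A` built here this equals Σ A² / Σ A.  Useful closed
forms (used as test oracles): the complete bipartite web K_{n,m} has
plant-side β_eff = m/n and animal-side n/m; a single plant with m animals
has plant-side β_eff = m and animal-side 1/m.

Two conventions are exposed because the literature is not unanimous:

* `diagonal_policy` — the sums above run over all i, j including i = j
  (default `include`); `exclude` zeroes the diagonal after projection.  For
  constant `A` (complete webs) the ratio is unaffected.
* `variant` — the overlap-ratio form above (`ratio`, default) versus the
  weighted-degree estimator ⟨s_out s_in⟩/⟨s⟩ = (1ᵀA A 1)/(1ᵀA 1) of the
  originating resilience-reduction theory (`gao`).  They coincide only for
  special matrices, so both are computable.

## Climate-change velocity

Velocity at a site is the temporal climate gradient divided by the local
spatial gradient of the current climate surface:

* temporal gradient — |current − past| at the raster cell containing the
  site (past = Last Glacial Maximum conditions);
* spatial gradient — Horn's 8-neighbour third-order finite difference on
  the 3×3 window, in climate units per km.  East–west spacing is the
  haversine distance between adjacent cell centres at the cell's own
  latitude; north–south spacing is the constant meridian arc per cell.

The quotient is the km of displacement needed to track the climatic shift.
Numerical choices: a configurable `slope_floor` (default 1e-6 units/km)
bounds the division on flat surfaces and flags the result; edge cells error
by default (`reflect` padding optional); time normalization (dividing by the
~21 000-yr glacial–interglacial span) is off by default, since the velocity
is defined per climatic shift, not per year.

A caveat the tests respect: on a geographic lattice an east–west climate
gradient is not exactly planar in km space (meridians converge), so Horn's
estimator is machine-precision exact only for meridian-oriented planes;
oblique planes on a small equator-centred grid are recovered to ~1e-5
relative error.

## Spatial statistics

**Weights.** k-nearest-neighbour (default k = 4) by great-circle distance,
row-standardized, symmetrized as (W + Wᵀ)/2 wherever a symmetric operator is
required.  The neighbour definition is a modelling choice and is recorded in
every report's provenance block.

**Residual Moran test.** For OLS residuals e = (I − H)y, Moran's
I = (n/S0)·eᵀWe/eᵀe is a ratio of quadratic forms in the Gaussian errors.
The exact p-value P(I ≥ i0) is computed from the nonzero eigenvalues of
M((n/S0)W_s − i0·I)M (M the hat-complement) by Imhof's characteristic-
function inversion (adaptive quadrature, absolute tolerance 1e-9).  The
distribution is continuous, so null p-values are exactly uniform — the
calibration test checks precisely this.  Two cheaper methods are provided:
a moment-based normal approximation, and Freedman–Lane randomization
(permute the residuals, re-residualize them on X, recompute I).  The
re-residualization matters: naively shuffling residuals ignores the hat
matrix and disagrees with the exact test by up to ~0.04 at n = 40, while the
Freedman–Lane scheme agrees to <0.01.

**SEVM.** Moran eigenvector maps are the eigenvectors of the doubly-centred
weight matrix C W_s C; candidates are restricted to positive eigenvalues
with λ/λ_max ≥ 0.01 (numerical-noise cut).  The spatial filter is built by
forward selection: at each step the candidate that maximizes the exact
residual-Moran p-value of y on [X, filter] is added, subject to not
increasing the residual autocorrelation measured as |I − E0[I]|.  The
deviation is centred at the null expectation E0[I] (which is negative for
residual Moran's I) rather than at zero: centring at zero rejects filter
candidates that move I below zero toward its null value and stalls the
selection.  Selection stops when the residual test is non-significant
(p ≥ α = 0.05), the candidate pool or q_max is exhausted, or no candidate
improves; the selected basis is re-orthonormalized.  The stopping rule is
one-sided (positive autocorrelation), which is what SEVM targets.

## Regression protocol

Transforms: natural log for richness S, T_velocity, P_velocity and β_eff;
square root for P_ann; then every quantitative column, response included, is
standardized to mean 0, sd 1 (n−1 denominator).  The full model regresses
standardized log β_eff on nine candidate terms: S, elevation, T_mean,
T_seasonality, P_ann, P_seasonality, human footprint, T_velocity,
P_velocity.

Model selection fits all 2^9 = 512 subsets (intercept and any spatial filter
in every model — the filter selected on the full model is held fixed), ranks
them by AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1) with k counting intercept,
slopes, filter columns and the error variance, and forms Akaike weights.
The 95% confidence set is the smallest AICc-ordered prefix with cumulative
weight ≥ 0.95 (weights renormalized inside).  Averaging uses full
(zero-substitution) averaging — β̄_j = Σ w_m β_jm with β_jm = 0 where the
term is absent — with Burnham–Anderson unconditional standard errors
SE_j = Σ w_m √(var_jm + (β_jm − β̄_j)²) and two-sided normal z p-values.
Zero substitution is the conservative convention when averaged estimates
span models that omit the term; conditional averaging is not offered.
Richness is a free candidate, not a forced term.  Ties in AICc break toward
fewer terms, then lexicographically, making selection deterministic.

The OLS fits themselves use Gram-matrix linear algebra (one Gram
factorization per study, sub-matrix solves per subset) so that full
enumeration inside simulation loops stays cheap; the fits are cross-checked
against an independent generic least-squares routine in the test suite.
Subsets whose Gram condition number exceeds 1e12 are skipped with a warning.

The SEVM branch triggers when the exact Moran p-value of the full OLS
model's residuals is below 0.05 (configurable to test the best model, or
either).  Partial-residual ("added-variable") pairs for plotting residualize
both the focal term and the response on the other best-model terms (plus the
filter under SEVM), so their OLS slope equals the term's best-model
coefficient exactly (Frisch–Waugh–Lovell); this property is what makes
partial residuals the right choice for effect displays.

## Synthetic data

The generator emulates the statistical shape of a global mutualistic-network
compilation; it does not attempt ecological realism beyond that shape.

* **Sites** — uniform over a continental window (lat ±30°, lon ±60°);
  presets of 62 sites (pollination-scale) and 30 sites (seed-dispersal
  scale) mirror the two study sample sizes.
* **Covariates** — independent zero-mean Gaussian random fields with
  exponential covariance sill·exp(−d/range) + nugget·δ over great-circle
  distance (default range 1500 km, sill 1, nugget 0.05), drawn by Cholesky
  factorization.  Raw scales are chosen so the standard transforms recover
  the fields exactly (velocities are log-normal, precipitation is a squared
  linear field), keeping generated truth and fitted scale commensurable.
* **Networks** — binary webs with per-cell link probability equal to the
  target connectance (0.15–0.45), redrawn until no species is isolated;
  richness ranges 8–30 plants × 10–45 animals (6–25 × 6–30 for the
  seed-dispersal preset).
* **Response** — in `regression-recovery` mode, y = Xβ + spatially
  structured error (exponential GRF, default sill 0.5) + iid noise (default
  sd 0.4), with default true coefficients 0.4 on log-richness, 0.25 on human
  footprint, 0.2 on log-T_velocity — effect sizes of the order reported for
  such compilations, against total noise giving R² ≈ 0.5.  In `end-to-end`
  mode no response is drawn: animal richness is monotonically linked to a
  chosen covariate and β_eff computed from the generated webs carries the
  signal, which is why only the monotone-link contract (not an exact
  coefficient) is testable in that mode.

What passing tests on these data do **not** show: robustness to the
features of real compilations the generator omits — correlated covariates,
non-Gaussian responses, nestedness/modularity structure in the webs,
sampling-effort artefacts, and shared phylogenetic history.

## Problem sizes and calibration checks

Simulation-based checks use the sizes at which their statistical guarantees
are stated: 200 random webs (≤ 8×8) for the projection oracle; 500
replicates at n = 40 for exact-test uniformity (Kolmogorov–Smirnov at
α = 0.01) and 20 fixtures × 99 999 draws for exact-vs-permutation agreement;
200 seeds at n = 60 for post-filter de-autocorrelation (≥ 95% non-
significant); 200 seeds at n = 100 for averaged-coefficient recovery (±3
unconditional SE) and the full-model type-I rate (0.05 ± 0.02, computed with
iid errors, as OLS t-tests assume).  Recovery is assessed with the response
on its generated scale; standardizing the response (the pipeline default for
comparability of estimates) rescales coefficients by 1/sd(y) and would test
the convention, not the recovery.

## Known limitations

* The exact Moran test assumes Gaussian errors; for heavy-tailed responses
  the Freedman–Lane permutation method is the safer choice.
* Forward selection of eigenvectors is greedy; it can stop short of α on
  rare draws (flagged via `converged=False`) rather than search subsets.
* kNN weights on strongly clustered site sets can yield a disconnected
  neighbour graph (a warning, not an error); eigenvector filtering still
  operates but interpretability of single eigenvectors degrades.
* Velocities are per glacial–interglacial shift, not per year, unless time
  normalization is enabled; comparing against annualized velocities
  requires that option.
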