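# Methods

This note documents the statistical model behind `funfanova`, the numerical
choices made where the design was open, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Sample model and basis representation

Curves are modelled as elements of L²[a, b].  A paired (repeated-measures)
design observes the same n units under R = 2 conditions,
X_jr(t) = μ_r(t) + e_jr(t), with e_jr zero-mean random functions that may
be correlated across the two conditions within a unit.  An independent
design observes g groups of i.i.d. H-variate curve vectors with group mean
vector μ_i(t) and a common matrix covariance function.

Raw series are discretely observed, possibly with gaps.  Each series is
reconstructed by ordinary least squares on a clamped cubic B-spline basis
(order 4) with equally spaced interior knots; missing values are dropped
per curve and a curve is rejected only when fewer usable points remain than
basis functions.  There is no roughness penalty: smoothness is controlled
by the basis dimension alone.  The default dimension is p = 20, which for
few-week daily series retains local behaviour; p = 7 is the conservative
trend-only choice.  Raw time stamps are affinely mapped to [0, 1] per
condition window (using the window's global range so all units share one
normalized domain).  The tests are invariant to this common rescaling up to
a constant factor applied identically to both samples.

The Gram matrix W = (∫φ_k φ_l dt) is computed by Gauss–Legendre quadrature
on each inter-knot interval with 2×order nodes.  Products of two splines of
degree order−1 are piecewise polynomials of degree 2·order−2, so any node
count ≥ order already makes W exact up to rounding; the default is simply a
comfortable margin.

## Paired tests

With coefficient matrices A₁, A₂ (rows aligned by unit), mean difference
d̄ and per/cross-condition coefficient covariances Σ̂₁, Σ̂₂, Σ̂₁₂
(denominator n−1):

- Cₙ = n d̄′ W d̄ (exact, no grid),
- K̂(t,t) = φ(t)′(Σ̂₁ − Σ̂₁₂ − Σ̂₁₂′ + Σ̂₂)φ(t); the symmetrized cross term
  equals 2Σ̂₁₂ inside the quadratic form but keeps the matrix symmetric,
- Dₙ integrates n(φ′d̄)²/K̂ by composite Simpson on a uniform grid
  (default 1001 points), and Eₙ takes the maximum over the same grid — a
  lower bound on the true supremum; no continuous optimization is
  attempted.

K̂ is floored at 10⁻¹² of its grid maximum before division to avoid 0/0 at
isolated zeros; a grid on which K̂ vanishes everywhere (deterministically
identical paired differences) is an error.

**Permutation null.**  Each replicate flips, independently per unit with
probability ½, the roles of the two condition curves.  Because all three
statistics depend on the data only through the difference rows
D_j = a_j1 − a_j2, a swap is a sign flip of row j, and since sign flips
leave D′D unchanged, the whole replicate batch reduces to one matrix
product on the signed row means.  This makes the 1000-dataset Monte-Carlo
calibrations cheap without changing the statistic's definition (unit tests
verify the vectorized path against explicit row-swapping).  When 2ⁿ ≤ Δ
(the replicate budget, default Δ = 2000) all 2ⁿ swap patterns are
enumerated and the p-value is exact over that set.

**Ties.**  "Replicate ≥ observed" counts toward the p-value, the
conservative reading; an add-one correction (1+#)/(1+Δ) is available but
off by default.  A consequence worth knowing: the identity and the
all-units swap always reproduce the observed statistic, so with exhaustive
enumeration at n = 5 the smallest attainable p-value is 2/32 = 0.0625, not
1/32.  A strict ">" convention would instead allow 0; the conservative
choice is deliberate.  Replicates with a fully degenerate kernel (possible
for Dₙ/Eₙ under extreme configurations) are counted as exceedances and
reported via a warning counter.

## Multivariate functional PCA

Per-variable coefficient matrices are stacked into A (n × Σp_h) with the
block-diagonal Gram matrix W.  Centering uses the overall mean across all
groups (the score definition uses the overall μ(t), not group means).  The
eigen-problem Σ_A W bₘ′ = λₘ bₘ′ is solved through the symmetric form: with
the symmetric square root W^{1/2} (eigendecomposition, eigenvalues below
10⁻¹² of the maximum clipped to zero, pseudo-inverse for the back-map), the
spectrum of W^{1/2} Σ_A W^{1/2} gives λₘ and orthonormal uₘ; then
bₘ = uₘ W^{−1/2} and scores ξ = A_c W^{1/2} uₘ′.  Eigenvector signs are
fixed by making each uₘ's largest-magnitude entry positive, so score files
are reproducible.  The retained rank defaults to min(n−1, Σp_h).

Per-variable standardization (dividing each variable's centered
coefficient block by the square root of its integrated total variance
trace(Σ_h W_h)) is available but **off by default**: the pollutants of the
motivating application live on different µg/m³ scales, and whether to
equalize them is a modelling decision the package leaves to the user rather
than silently imposing.

q is selected as the smallest number of components whose cumulative
explained fraction reaches a threshold (default 0.99), with an explicit
override for analyses that fix q a priori.

## Score homogeneity tests

Two families are always computable from the leading q scores:

- **Per-component one-way ANOVA** with Bonferroni-corrected level α/q
  (Bonferroni chosen as the correction because it is assumption-free and
  exact under independence, which holds for Gaussian scores).  Under
  `test="anova"`/`"both"` the per-component p-values come from the
  permutation distribution of each F statistic; the family-level summary is
  the Bonferroni combination min(1, q·min_m p_m).
- **Spatial-rank multivariate Kruskal–Wallis**: spatial ranks
  R_i = n⁻¹ Σ_j (x_i−x_j)/‖x_i−x_j‖ (u(0)=0), scatter B = n⁻¹ Σ R_i R_i′,
  statistic Q = Σ_i n_i R̄_i′ B⁻¹ R̄_i, asymptotically χ² with q(g−1)
  degrees of freedom.  The outer-standardization form was chosen (the
  alternative inner-standardization variant is affine-invariant but needs
  iterative scatter estimation); the decision rule is the permutation null,
  so the asymptotic reference is informational only.

Label permutations are enumerated exhaustively whenever the number of
distinct arrangements n!/(n₁!…n_g!) does not exceed the replicate budget
(e.g. 10 for a 2-vs-3 split of five stations), giving exact permutation
p-values.  Normality is never auto-tested; both families are reported and
the user chooses.

**Degenerate geometry.**  When n ≤ q + 1 the spatial-rank statistic is
invariant under relabelling (with five units and q = 4 it equals n for
every arrangement), so the permutation test carries no information; the
package warns and suggests capping q at n − 2 or using the ANOVA family.
This is intrinsic to outer-standardized spatial ranks in dimension close to
the sample size, and is the practical reason the component-selection
threshold should not be pushed to 100% in tiny designs.

## Synthetic data generator

The generator draws X = μ + e + ε on a uniform grid of the unit interval:
e is a zero-mean Gaussian process with stationary exponential kernel
σ² exp(−|s−t|/ℓ) (defaults σ = 1, ℓ = 0.2) and ε is iid N(0, noise_sd²)
measurement noise (default 0.1).  The exponential kernel's non-smooth
sample paths are deliberately rough: a 20-dimensional cubic spline basis
smooths them imperfectly, so calibration runs exercise the reconstruction
error path rather than only the coefficient algebra.  Dependence across
conditions and across variables is separable — the joint covariance is the
Kronecker product of the temporal kernel with 2×2 / H×H correlation
matrices — which is PSD by construction; a 10⁻¹⁰-scale diagonal jitter
stabilizes the Cholesky factor.  An optional uniform missing-data rate
exercises the least-squares path.

The `airlike` preset mimics the motivating study's design: four
pollutant-scale variables (NO2, PM10, PM2.5, benzene), five stations split
two urban-traffic / three urban-background, two 39-day windows of daily
values, within-station cross-window correlation 0.5 and cross-pollutant
correlation 0.3, with smooth window-level mean functions on realistic µg/m³
scales (NO2 roughly halving in the second window, particulate matter
increasing, benzene diverging by station type).  What it does **not**
emulate: meteorology-driven chemistry, episodic long-range dust transport,
spatial correlation between stations, diurnal/weekly cycles within a
window, and non-Gaussian heavy tails.  Passing calibrations therefore
demonstrate correctness of the inferential machinery under the stated
Gaussian-process model, not robustness to every feature of real monitoring
data.

## Monte-Carlo calibration sizes

The calibration harness runs the full chain (simulate → smooth at p = 20 →
test) per dataset.  Reported studies use 1000 Monte-Carlo datasets with
Δ = 200 permutation replicates and a 201-point integration grid for the
null-size checks (n = 20 paired units, within-unit correlation 0.5), and
300 datasets per point of the shift-power curve — sizes chosen so binomial
standard errors (≤ 0.016 at rates near 0.5, ≤ 0.007 near 0.05) resolve the
questions asked of them.  Rejection is "p-value strictly below α", which
makes α = 0 reject nothing by construction.

## Numerical conventions collected

- Integration grid: uniform, composite Simpson, default 1001 points; the
  same grid serves Eₙ's maximum.
- Kernel floor: 10⁻¹² × grid maximum of K̂.
- Tie tolerance: a replicate counts as an exceedance when it is within
  10⁻⁹ (relative) of the observed statistic, absorbing last-ulp differences
  between the observed and batched computation paths.
- Gram/eigen clipping: eigenvalues below 10⁻¹² of the maximum are treated
  as zero; pseudo-inverses act on the retained spectrum only.
- RNG: every stochastic routine takes one seed (or NumPy Generator); study
  drivers derive per-cell seeds from a root SeedSequence, so reports are
  byte-identical under a fixed seed.

## Known limitations

- Only R = 2 conditions and one-way group designs are supported.
- Eₙ is a grid maximum, a lower bound on the continuous supremum.
- The ≥ tie convention bounds attainable p-values away from zero under
  exhaustive enumeration (2/2ⁿ for the paired design).
- No penalized smoothing, Fourier/wavelet bases, or irregular per-variable
  domains; per-variable domains are all normalized to [0, 1].
- The spatial-rank test degenerates when q ≥ n − 1 (see above).
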