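# Methods

## The two-stage procedure

`readsem` estimates relations between eight CHC broad cognitive abilities
(Gc, Gf, Gv, Ga, Gl, Gr, Gwm, Gs) and five narrow reading skills (PD, LD,
DS, RF, RC) from a long-format database of subtest-pair Pearson
correlations, each tied to the correlation matrix (sample) it was
extracted from. The unit of information is one correlation; the cluster
is one matrix, because all correlations from a matrix are computed on the
same examinees.

### Stage 1: three-level random-effects pooling

Correlations are Fisher-transformed, `z = artanh(r)`, with known sampling
variance `v = 1/(N − 3)`; records with `N < 4` are invalid. For one
construct pair, the model for correlation `i` in matrix `j` is

    z_ij = μ + u_j + e_ij + ε_ij
    u_j  ~ N(0, τ²_between)   (matrix-level heterogeneity / clustering)
    e_ij ~ N(0, τ²_within)    (correlation-level heterogeneity)
    ε_ij ~ N(0, v_ij)         (known sampling error)

Some software communities number these levels differently (sampling error
as level 1, correlation-level heterogeneity as level 2, cluster
heterogeneity as level 3); the code names the components
`tau2_between`/`tau2_within` with respect to matrices to avoid silent
misbinding.

μ, τ²_between and τ²_within are estimated by restricted maximum
likelihood. Each cluster's marginal covariance is a known diagonal plus a
compound-symmetric term, so the restricted likelihood is evaluated in
O(k) per cluster with rank-one (Woodbury) updates. The optimizer is
L-BFGS-B directly on (τ²_b, τ²_w) with lower bounds at zero — boundary
solutions are common and a log-scale parameterization cannot represent
them exactly — started from a method-of-moments split of the excess
dispersion plus seeded random restarts (4 by default). `SE(μ)` is the
inverse square root of the summed GLS weights at the solution; the 95%
interval `μ ± 1.96·SE` is back-transformed with `tanh`. With a single
correlation the pooled mean is that correlation and the variance
components are reported as zero with an explicit not-estimable flag.
The test suite checks the REML solution against an independent
brute-force oracle (dense per-cluster matrices, nested 2-D grid
refinement) to 1e−4 on small instances; note that instances in which
every cluster is a singleton identify only the sum τ²_b + τ²_w, so
oracle comparisons use instances with replicated clusters.

Heterogeneity per pair: Cochran's Q under fixed-effect inverse-variance
weights (`w = 1/v`), `df = k − 1`, p-value from χ²(df), and
`I² = max(0, (Q − df)/Q)`, clamped because the ratio is negative when
Q < df.

The pooled matrix sets the diagonal to 1 and uses, as the effective
sample size for Stage 2, the median of the per-pair total Ns; each
matrix's examinees are counted once per pair no matter how many subtest
pairs it contributes (the per-pair total is the sum over contributing
matrices of the matrix's largest per-record N). Pair-wise pooling does
not guarantee a positive semidefinite assembly; if the smallest
eigenvalue is negative the matrix is projected to the nearest correlation
matrix (Higham-style projection, via statsmodels' `corr_nearest`) and
flagged.

### Stage 2: RAM maximum likelihood

The structural model has one latent variable, g, with variance fixed at 1
for identification and free loadings on the eight broad abilities. The
broad abilities carry no residual covariances: their intercorrelations
flow solely through g, so the implied correlation between broads i and j
is λ_i·λ_j. Every broad ability predicts every reading skill (the
Gv → reading paths are removable as a model variant), and the reading
skills form the cascade PD → LD → DS → RF → RC with all forward edges.
Each observed variable has a free residual variance. With p = 13 observed
variables, the full model has 8 + 40 + 10 + 13 = 71 free parameters
(df = 20) and the Gv-removed variant 66 (df = 25); the Δdf = 5 contract
between the variants is what the nested comparison tests.

The implied covariance is `Σ(θ) = F(I − A)⁻¹S(I − A)⁻ᵀFᵀ`. The input
correlation matrix is treated as the covariance matrix of standardized
variables (means 0, SDs 1), fitted directly with the normal-theory
discrepancy

    F_ML(θ) = ln|Σ(θ)| − ln|S| + tr(S·Σ(θ)⁻¹) − p,

and `χ² = (N − 1)·F_min`. No correlation-specific χ² correction is
applied; with the alternative multiplier N instead of N − 1 the χ²
changes by under 0.1% at N ≈ 1764. Minimization is multi-start L-BFGS-B
(analytic gradient from the RAM derivatives; 4 seeded restarts plus a
tighter polishing pass) with residual variances bounded at zero — a
residual landing on the bound is flagged as a Heywood case — and all
parameters boxed in ±10 so the line search cannot overflow on the
non-positive-definite penalty plateau. Positive definiteness of Σ(θ) is
established by Cholesky factorization, not by the sign of the
determinant; an indefinite Σ has a positive determinant whenever it has
an even number of negative eigenvalues, and inverting a near-singular Σ
can silently produce a large negative discrepancy. Standard errors come
from the inverse expected information, `I_ij = (N−1)/2 ·
tr(Σ⁻¹Σ_iΣ⁻¹Σ_j)` (they are secondary; interpretation rests on effect
sizes).

Fit indices follow the standard definitions against the independence
baseline (all covariances zero, variances free, which for a correlation
input has the closed form `F_min = −ln|S|`): CFI with noncentrality
clamped at zero, TLI, `RMSEA = √(max(χ²−df,0)/(df·(N−1)))` (undefined at
df = 0 and reported as not applicable, as is TLI), and SRMR as the root
mean square residual over the lower triangle including the diagonal.

### Effect decomposition

For the acyclic standardized path matrix B, total effects are
`T = (I − B)⁻¹ − I` and indirect effects `T − B`, so total = direct +
indirect holds to machine precision. An exhaustive DFS path enumerator
serves as an independent oracle: the sum of coefficient products over all
directed paths equals the matrix-algebra total. The indirect effect of g
on each reading skill is `Σ_b λ_b · T[b → skill]` (g has no direct
reading paths). R² for an outcome is `β′Φβ` with Φ the model-implied
correlation matrix among its direct predictors (λ_iλ_j among broads,
recursive structural algebra for upstream reading skills); this equals
1 − residual variance of the standardized solution, which the tests check
across modules. Coefficients are banded by magnitude after half-up
rounding to two decimals: <0.05 negligible, 0.05–0.09 small, 0.10–0.24
moderate, >0.24 large.

### Reproducing published cells from rounded inputs

The reference standardized solution in `readsem.consensus` (loadings
0.70, 0.64, 0.56, 0.59, 0.56, 0.43, 0.59, 0.47; direct paths such as
Ga → PD = 0.29 and PD → LD = 0.55) is printed to two decimals, while the
published decomposition cells were computed from unrounded estimates.
Recomputation from the rounded inputs therefore reproduces most cells
exactly (LD R² = 0.59, PD → RC total = 0.28, RC R² = 0.54) but lands one
unit in the second decimal away on cells near a rounding boundary: the PD
R² recomputes to 0.3501 (published 0.34) and the indirect effect of g on
PD to 0.5066 (published 0.50). The package reports its own computed
values and does not adjust them toward the published ones. The published
prose also states the RC R² as 0.55 where the published table prints
0.54; the recomputed value is 0.5375 → 0.54.

## The synthetic-data generator

`synth.simulate_database` emulates the statistical structure of a
cross-battery subtest-correlation database; it makes no attempt to clone
any specific battery census. Defaults define the study conditions used
throughout the tests:

- population model: the reference loadings and paths above
  (`population_sigma` solves residual variances for unit totals and
  rejects inadmissible parameter sets);
- heterogeneity τ²_between = 0.02, τ²_within = 0.01 on the z scale —
  at the generator's typical per-matrix sample sizes this puts I² near
  0.90, matching the high heterogeneity (I² ≈ 0.88 on average) reported
  for cross-battery correlation pooling;
- per-matrix N log-uniform on [18, 2901], the range reported for such
  databases; construct coverage probability 0.5 with 1–3 subtests per
  covered construct, giving matrices on the order of 80 correlations;
- within-construct (same broad ability, different subtests) population
  correlation 0.65 — these pairs exercise Stage 1's diagonal buckets but
  never enter Stage 2, which fixes the diagonal at 1;
- small contamination rates (5% poor indicators, 3% clinical matrices,
  1% cross-version flags) so the inclusion filters have real work; the
  contaminated records carry the same generating values, so their removal
  is neutral to recovery.

`independent_z` mode draws each record's z independently around the
matrix-shifted population value — exactly the model Stage 1 assumes, with
no joint PSD constraint across pairs within a matrix (pair-wise pooling
never uses joint structure). `wishart` mode instead perturbs the
population matrix per matrix on the z scale, repairs it to the nearest
correlation matrix, and draws a genuine sample correlation matrix at N_j,
guaranteeing internally consistent (PSD) matrices; it exists to
stress-test PSD repair and costs realism in exchange (sampling error is
no longer exactly normal on the z scale). Matrices get deterministic
substreams spawned from the master seed, so enlarging `n_matrices`
extends rather than reshuffles a database.

What passing recovery tests do **not** show about real data: real
databases violate the generator's assumptions in known ways — subtest
correlations attenuated by unreliability that varies by battery,
heterogeneity that is moderated by age and battery family rather than
exchangeable, non-random construct coverage (reading-rich batteries
cluster), and overlapping normative samples across matrices of one
battery. Each matrix id is treated as an independent cluster; matrices
from the same battery or norming program are not given a shared random
effect.

## Problem sizes and numerical choices

The end-to-end recovery experiment used by the acceptance checks runs 50
replicates of 300 matrices (≈27,000 records each), chosen as the smallest
design at which the Monte-Carlo error of the bias estimate (≈0.002 on a
pooled r) is comfortably below the 0.01 acceptance band. At that design,
maximum absolute pooled-r bias over the 78 pairs is ≈0.005, loading RMSE
≤0.018 and path RMSE ≤0.029 against the generating values, and the mean
τ² estimates are unbiased to the third decimal. REML tolerance is 1e−12
on the objective; SEM tolerances 1e−14 (ftol) and 1e−10 (gtol) with a
1e−16/1e−12 polish. Ties in the median-N rule (even pair counts) average
the middle two values. Degenerate inputs are handled explicitly: k = 1
pairs (flagged, no variance components), Q undefined at k < 2, RMSEA/TLI
undefined at df = 0, non-PSD inputs rejected by the SEM and repaired (with
a flag) in Stage-1 assembly.

## Known limitations

- No moderator/meta-regression machinery, robust variance estimation, or
  publication-bias diagnostics in Stage 1.
- ML only in Stage 2 (no WLS/robust estimators, no categorical
  indicators, no multi-group models); SEs use expected information.
- The model in which broads correlate only through a single g is a strong
  restriction; with 13 single indicators, loadings are not comparable to
  composite- or latent-variable loadings.
- Effect decomposition assumes the recursive (acyclic) topology; no
  bootstrap intervals for indirect effects.
- Self-consistency recovery is exact to ≈1e−4 for well-conditioned
  populations but degrades toward ≈1e−3 when the population matrix is
  near-singular.
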