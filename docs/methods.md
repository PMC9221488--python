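# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Marginal model

Each channel is filtered by an AR(1) + GJR-GARCH(1,1) model with symmetric
Student-t innovations:

    x_t       = c0 + c1 x_{t-1} + a_t,        a_t = sigma_t xi_t
    sigma_t^2 = omega + alpha a_{t-1}^2 + beta sigma_{t-1}^2
                + gamma a_{t-1}^2 1{a_{t-1} < 0}
    xi_t      ~ t_d, rescaled by sqrt((d-2)/d) to unit variance.

Parameters (units of the data's squared scale for `omega`; dimensionless
otherwise): `c0` intercept, `c1` AR coefficient (|c1| < 1), `omega > 0`,
`alpha, beta, gamma >= 0` with covariance stationarity
`alpha + beta + gamma/2 < 1` (the 1/2 is exact for symmetric innovations),
degrees of freedom `d > 2`. The leverage indicator 1{a_{t-1} < 0} is the
canonical GJR asymmetry term: negative residuals may raise next-step
variance more than positive ones. A skewness parameter is deliberately not
estimated — the inference path evaluates the symmetric t CDF, and the PIT
contract must match the innovation law exactly.

Estimation is constrained maximum likelihood (L-BFGS-B) from three fixed
deterministic starting points; `sigma_1^2` is initialized at the sample
variance of the mean-equation residuals. Standard errors come from the
numerically differentiated Hessian at the optimum. Because `beta` is not
identified when `alpha + gamma -> 0` (the likelihood is flat along a ridge),
the estimator also fits the nested constant-variance AR(1)-t model and
returns it when BIC prefers it; this is what makes fits on dynamics-free
data report weak persistence instead of an arbitrary `beta`.

The PIT uses the exact CDF of the unit-variance t, i.e.
`u_t = T_d(xi_t * sqrt(d/(d-2)))`, so that correctly specified margins give
exactly uniform `u_t`; the same scaling enters the one-step-ahead
conditional CDF.

## Pair copulas

Families: independence, Gaussian (rho), Student-t (rho, nu in [2.1, 30]),
Clayton (theta > 0), Gumbel (theta >= 1), Frank (theta != 0), plus 90/180/270
degree rotations of Clayton and Gumbel. The 180-degree (survival) rotations
keep the sign of Kendall's tau and swap the dependent tail; the 90/270
rotations provide negative dependence, which one-parameter Archimedean
copulas cannot reach. When fitting, Clayton/Gumbel candidates are replaced
by the rotation matching the sign of the empirical tau.

Numerics worth noting:

* The Gaussian copula CDF is evaluated through Owen's T function
  (~1e-14 absolute accuracy); the Student-t copula CDF by 160-node
  Gauss-Legendre integration of the conditional CDF over the first margin
  (~1e-9). Both are accurate enough to survive central finite differencing
  at step 1e-5, which is how the h-functions are validated.
* h-inverses are closed-form everywhere except Gumbel, which uses 80
  bisection steps (error < 1e-20 in the argument, < 1e-8 after the h-map).
* Kendall's tau: empirical tau-b (`scipy.stats.kendalltau`); closed forms
  per family (Frank via the Debye-1 integral, inverted by Brent); and the
  copula-integral form 4 E[C(U,V)] - 1 evaluated on a deterministic Sobol
  sample of the copula itself (2^17 points, ~2e-4 agreement with the closed
  forms).
* Family selection minimizes AIC by default (BIC available); ties break by
  fewer parameters, then candidate order, so selection is deterministic.
  A Student-t fit whose nu reaches the upper cap is effectively Gaussian
  and loses to it on the AIC penalty.

## R-vine

Structure selection is sequential: tree 1 is the maximum spanning tree on
|empirical tau| (Prim's algorithm, fixed start node, lexicographic
tie-break); each selected edge gets an AIC/BIC-chosen pair copula; both
h-directions of every edge are cached as pseudo-observations; trees
2..p-1 repeat the construction on conditional pseudo-observations with
candidate edges restricted by the proximity condition. Truncation
(independence above a given tree level) is available but off by default;
tree 1 — the reported corticomuscular structure — is identical with and
without truncation because it depends only on the raw-margin taus.

The log-density is the sum of edge copula log-densities evaluated at
h-chained arguments (marginal terms are excluded: the model lives on the
uniform PIT scale). Sampling is the inverse Rosenblatt transform: the vine
is peeled from its top tree to obtain a sampling order and, per variable, a
chain of edges with nested conditioning sets; each variable is generated by
chaining inverse h-functions. Peeling asserts the nesting property at run
time, so a malformed structure fails loudly rather than sampling from the
wrong law.

Validated against: the analytic trivariate Gaussian copula density (1e-6),
unit mass on a 40^3 grid (2e-2), brute-force spanning-tree enumeration for
N <= 5, tau recovery of sampled vines, and exact tree-1 structure recovery
on simulated data.

## Network construction

The weight matrix is |tau| (or the symmetrized band-mean Granger matrix).
Because same-modality dependence is systematically stronger than
cross-modality dependence, the EEG-EEG, EMG-EMG and EEG-EMG blocks are
min-max scaled to [0, 1] separately (off-diagonal cells only, absolute
values, diagonal forced to 0; a constant block maps to 0 with a warning).
Binarization uses A_ij = 1 iff Wn_ij >= t. The threshold is scanned over
{0, 0.05, ..., 1}; per-condition mean node degrees are averaged across
conditions, and the *largest* t with average K >= 2 ln N is selected (the
densest admissible sparsification). Metrics on the binary graph:
characteristic path length L averaged over connected ordered pairs (the
number of excluded disconnected pairs is reported rather than hidden in an
infinite L), clustering C_i = 2E_i/(K_i(K_i-1)) with C_i = 0 for degree < 2,
C = mean C_i, and core nodes = all maximum-degree nodes.

**Limitation of per-block normalization.** Min-max scaling is scale-free
within each block: a cross-modality block containing only estimation noise
is still stretched to fill [0, 1], so counts of supra-threshold cross-block
edges do not measure coupling strength and are not comparable across
conditions. Contrasts between conditions should be read from the raw tau
matrices (exported alongside the normalized ones) or from the tree-1
structure; the tests encode exactly this reading.

## Spectral Granger baseline

Bivariate VAR by least squares, order selected by AIC up to 20 (configurable);
spectral matrix S(f) = H(f) Sigma H(f)* on a 512-point grid over [0, fs/2];
Geweke's measure with the instantaneous-correlation correction
H~_yy = H_yy + (Sigma_xy/Sigma_yy) H_yx. Curves are clipped at 0 against
numerical negatives. The scalar summary is the mean over a configurable
band, default 8-30 Hz (the sensorimotor beta-centred range). The
frequency-averaged measure is checked against the time-domain
log-variance-ratio (10% agreement on directed simulations), nulls calibrate
below 0.02, and the measure is invariant to channel rescaling.

## Synthetic ground truth

`make_scenario` plants a tree-1 vine with Gaussian pairs: an EEG chain, an
EMG chain, and a single EEG-EMG bridge at the C3-like position (third EEG
node), with independence in all higher trees; `tau_within = 0.5`,
`tau_cross = 0.15` by default, mirroring the empirical pattern that
same-type channels co-vary far more strongly than cross-type pairs.
Higher-tree structure is completed deterministically by the same MST
machinery. Marginals default to (c0=0, c1=0.2, omega=0.05, alpha=0.05,
beta=0.85, gamma=0.05, d=8): mild autocorrelation, persistent but
stationary volatility (persistence 0.925), moderately heavy tails —
representative of rectified-envelope-like biosignal dynamics at unit scale.
Dependence is injected at the innovation level (vine-sampled uniforms
mapped through the t quantile into the GARCH recursion), which is exactly
the model class the inference path assumes.

What the generator does *not* emulate: oscillatory band structure, volume
conduction, electrode geometry, nonstationarity across trials, artifacts.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to real-world
EEG/sEMG violations of them.

## Pipeline and problem sizes

The pipeline fits marginals per channel per epoch, concatenates PIT series
across epochs of a task, builds one vine and one tau network per condition,
and shares a single threshold across conditions via the averaged degree
curve. All randomness flows through explicit seeds; rerunning a
configuration reproduces every JSON artifact byte for byte.

Test and acceptance runs use 3000-sample epochs (3 s at 1000 Hz, the
motivating trial length), 14 channels (8 EEG + 6 EMG) for full-scale
recovery, 20-50 seeded replicates for coverage-style checks, and truncation
above tree 3 in the acceptance pipeline run (tree-1 recovery, the reported
quantity, is unaffected by truncation). These sizes were chosen to exercise
the full method at the study's native scale while keeping a complete run in
the minutes range on one CPU.

## Known limitations

* Symmetric-t margins: genuine skew in rectified EMG envelopes is absorbed
  imperfectly by the PIT; a skewed-t extension is the obvious upgrade path.
* Pairwise (not conditional) Granger baseline; common-input effects are not
  removed.
* The degree-rule threshold is a heuristic; reported networks should be
  read jointly with the threshold curve, which is exported.
* ICA-based artifact removal is out of scope; inputs are assumed cleaned.
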