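# Methods

`anngc` estimates Granger causality (GC) between the channels of a
multivariate stochastic process by identifying a vector autoregressive
(VAR) model and converting it to an innovations-form state-space (ISS)
representation from which all restricted-model prediction-error variances
follow without refitting.

## Model

The observed process is assumed stationary, zero-mean and linear:

    Y_n = sum_{k=1..p} Y_{n-k} A_k + U_n,

with `M` channels, order `p`, lag matrices `A_k` (entry `(i, j)` = effect
of driver `i` at lag `k` on target `j`) and white innovations `U` with
covariance `Sigma`.  Conditional GC from `i` to `j` given the remaining
channels `s` is

    F_{i->j|s} = ln( lambda_{j|js} / lambda_{j|ijs} ),

the log ratio of the target's prediction-error variance without and with
the driver's past.  The full-model variance is `Sigma_{jj}`.  Restricted
variances come from the ISS representation: the VAR is written with the
stacked lag vector as state, and a *submodel* that observes only a subset
of channels (state equation unchanged) is returned to innovations form by
solving a discrete algebraic Riccati equation (DARE); the submodel's
innovation covariance contains the restricted variance of every retained
channel.  One DARE solve per excluded driver therefore yields a full
`M x M` conditional-GC matrix; unconditional (pairwise) GC uses the
one- and two-channel observation submodels of the same full model.

### DARE solver

The Riccati equation is solved by a structure-preserving doubling
iteration (quadratic convergence, relative tolerance 1e-12, at most 100
doublings) after absorbing the state/observation noise cross term.  The
test suite cross-checks it against `scipy.linalg.solve_discrete_are`;
the doubling solver is ~8x faster at the state dimensions used here
(60-160), which matters because the surrogate significance path solves
tens of thousands of DAREs.  A stabilizing solution does not exist when
the companion matrix is unstable or the innovation covariance block is
singular; both conditions, and iteration non-convergence, raise
`DareNonConvergenceError`.  This failure is *expected* for OLS at K = 1
(below): with fewer regression rows than coefficients the least-squares
fit interpolates, the residual covariance is singular, and GC is
undefined — the package reports the failure rather than numbers.

## Identification

**OLS.**  `A = (X'X)^{-1} X'y` on the stacked lag design; residual
covariance divisor is the row count `N - p`.  Rank-deficient designs
raise unless the minimum-norm pseudo-inverse solution is explicitly
requested (it is, inside the benchmark driver, so that the downstream
DARE failure is the observable outcome at K = 1).

**Sparse network (SGD-L1).**  A single linear layer maps the `Mp` lagged
inputs to the `M` outputs; its weight matrix *is* the stacked VAR
coefficient matrix.  Training minimizes the mean squared prediction
error under an L1 penalty applied through the cumulative-penalty scheme:
a global budget `u` accumulates the total penalty each weight could have
received, each weight tracks the signed penalty `q` it actually
absorbed, and after every gradient step each weight is clipped toward
zero by the outstanding difference — never past zero — so zeros are
exact and the sparsity pattern is directly interpretable as a link mask.

Training is full batch.  One iteration stands for one pass of the
per-sample reference update loop: with per-sample learning rate `lr`, a
pass accumulates a step of `lr * N` on the mean-MSE gradient, so the
full-batch step is `eta_eff = lr * N`, capped at `0.45 / lambda_max(G)`
(`G` = design Gram matrix / N) to stay inside the monotone-descent
region of the quadratic loss.  A plain full-batch step of size `lr`
would be ~N times slower per iteration and leaves training visibly
unconverged at the recommended `lr = 1e-3`, `N_train = 1000`; the
one-pass equivalence restores the behavior those settings are known for,
and preserves the qualitative under-convergence of very small rates
(1e-5) at a few hundred iterations.  The cumulative penalty advances by
`lam * eta_eff / N` per iteration.  Divergence (non-finite weights) is
detected and raised, although the spectral cap makes it unreachable for
finite inputs.

Defaults: `lr = 1e-3`, `N_train = 1000` (the recommended accuracy /
cost compromise), Glorot-uniform initialization (selectable;
fan-scaled schemes and zeros give indistinguishable results once
training converges).

### Regularization-parameter selection

The search range is `[lambda_u / 1e4, lambda_u]` with `lambda_u` found
by geometric doubling until the trained weight matrix is entirely zero;
the grid is log-spaced (default 300 points; the scaled-down benchmarks
use 50).  A random 10% of the regression rows is held out; both splits
are z-scored with training-split statistics; each grid value is trained
on the 90% split and scored by hold-out RSS.

The winner is the sparsest lambda whose hold-out RSS lies within half a
standard error of the grid minimum (standard error of the RSS estimated
from the per-sample squared errors).  This is the glmnet-style
one-standard-error parsimony rule with a halved margin: the 10% hold-out
is small (14 rows in the K = 1 condition), which makes a full standard
error wide enough to discard genuine links.  A "minimize RSS divided by
the number of nonzero weights" rule was considered and rejected: RSS is
bounded below while the nonzero count varies over three orders of
magnitude, so that ratio is always minimized at maximum density and
cannot produce a sparse network.  All-zero solutions are excluded; if
every grid value is all-zero the selection raises.  The winning weight
matrix (trained on the 90% split) is reused for GC analysis; retraining
on all rows was evaluated and brought no improvement.  Weights learned
on z-scored columns are mapped back to original units by
`W_orig = diag(1/sd_x) W diag(sd_y)`, which preserves the zero pattern;
the innovation covariance is the residual covariance of the rescaled
model over all rows.

### Model order

`bic_order` fits OLS models for `p = 1..p_max` on a common sample window
and minimizes `ln det(Sigma_p) + ln(n)/n * M^2 p`.

## Significance of links

* **OLS path** — 100 IAAFT surrogates (per channel, independently),
  each refitted and scored; a link is significant when its GC exceeds
  the 95th percentile of its surrogate null values.  IAAFT alternates
  spectrum substitution with rank-ordered amplitude substitution
  (tolerance 1e-8 on the relative spectral change, at most 100
  iterations), ending on the amplitude step so the surrogate's sorted
  values equal the original's exactly.  Surrogate-level DARE failures
  are counted; an ensemble with more than 10% failures is flagged
  unresolved.
* **ANN path** — a link `(i, j)` is significant iff any of the `p`
  weights from driver `i`'s lag columns to output `j` is nonzero.  No
  epsilon is involved; the clipping rule produces exact zeros.

## Simulation benchmarks

The data-sufficiency parameter is `K = N*M / (M^2*p)`, so `N = K*M*p`.

* **Study I** (`M = 10`, `p = 16`): exactly 14 of the 90 ordered channel
  pairs carry one nonzero coefficient at a uniformly random lag, values
  uniform in [-0.8, 0.8]; innovations are white with variance 0.1.  Each
  channel also receives one diagonal self-coefficient by the same scheme
  (not counted among the 14) so channels have memory.  Models are
  redrawn until the companion spectral radius is below 1 (at most 1000
  attempts).  Realizations discard a burn-in of `10 p` samples.
* **Study II**: study-I realizations plus white measurement noise with
  per-channel variance `mean(y_j^2)/SNR`.
* **Study III** (`M = 10`, `p = 6`): lag-1 self-coefficients; 80% of
  ordered pairs are candidates and each activates with probability 1/2
  (~36-38 links of 90); an active interaction is a pair of
  consecutive-lag coefficients starting at a uniformly random delay
  (second coefficient within lag 6), magnitudes from the grid
  0.15:0.01:0.5 with random signs; redraw until stable.

Scoring per network: BIAS0/BIAS1 (mean absolute GC error over null /
non-null links against the theoretical GC computed from the true
coefficients), FNR, FPR, and the single-operating-point trapezoidal AUC
through (0,0), (FPR, TPR), (1,1).  The overall score S averages the
per-K means of (BIAS1 normalized by the mean theoretical link GC) and
of (1 - AUC).  Rates are computed per network and averaged; confidence
intervals by percentile bootstrap.

### Problem sizes

The benchmark driver defaults to 10 networks per cell with a 50-point
lambda grid; these sizes keep a full study sweep in minutes on one core
while leaving the per-cell means stable to a few percent (the
distributions are reported with bootstrap intervals for exactly this
reason).  Larger replications are a single argument away.

### What the generators do not emulate

Real physiological or electronic recordings are nonstationary, have
non-Gaussian innovations, measurement artifacts, and unknown true
topology.  Passing benchmarks demonstrates correct recovery under the
model's own assumptions (linear, stationary, Gaussian, known order) —
not performance on arbitrary real data, where order selection,
stationarity screening and preprocessing dominate.

## Signal-level measures

`analytic_signal` (Hilbert envelope/phase; the first and last 5% of
samples are flagged as edge-affected), `max_crosscorr` (normalized
lagged cross-correlation over non-negative lags, driver earlier /
target later, biased normalization so coefficients stay in [-1, 1]),
`spearman_rank` (mean-tie ranks, Student-t significance on n-2 degrees
of freedom), and `in_strength` (sum of significant inward GC weights at
a node; a raw-magnitude variant is available).

## Known limitations

* The sparse estimator shrinks nonzero coefficients, so GC magnitudes
  on true links are biased low even when topology recovery is good; the
  OLS estimator is preferable for magnitudes when data are plentiful.
* In the strongest data-paucity regime (K = 1) the achievable
  miss-rate/false-alarm trade-off is limited: links with small
  coefficients (|a| below roughly 0.15 out of the [-0.8, 0.8] range)
  are statistically indistinguishable from absent links at N = 160,
  whatever the regularization level.
* Asymptotic (F / chi-squared) GC tests, frequency-domain measures,
  partial conditioning and group-sparse penalties are out of scope.
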