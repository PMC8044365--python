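# Methods

## Model

`bnpgcm` fits a linear latent growth curve model whose measurement errors
follow a Dirichlet process mixture (DPM) of multivariate normals.  For
subject i with T repeated measurements,

    y_i = Λ b_i + e_i,        b_i = β + u_i,
    u_i ~ MN₂(0, Ψ),
    e_i | Φ_i ~ MN_T(0, Φ_i),   Φ_i | G ~ G,   G ~ DP(α, G0),

where Λ is the T×2 loading matrix with unit intercept loadings and 0-based
occasion codes 0,…,T−1 as slope loadings, β = (β_L, β_S)′ holds the mean
intercept and slope, and Ψ the random-effect covariance with entries σ²_L,
σ²_S, σ_LS.  The DP prior on the error-covariance distribution relaxes the
usual normality assumption: each subject's error vector is drawn from one
of countably many zero-mean normal components, with the precision
parameter α governing how many components the data occupy.

The DP is represented by its truncated stick-breaking construction with C
components (default C = 50).  Sticks q_j ~ Beta(1, α) define weights
p′_j = q_j ∏_{k<j}(1−q_k), normalized to p_j.  We pin the final stick at
q_C = 1, so the remaining mass goes to component C and the normalization
is exactly the identity; with this convention every full conditional in
the Gibbs sampler is an exact conjugate draw.  The alternative — C free
sticks plus sum normalization — perturbs the stick conditionals by a
factor of order (α/(1+α))^C, which is negligible at C = 50 but would make
the sampler inexact; simulation-based calibration (below) verifies the
implemented choice.

Component means are fixed at zero (errors have mean zero by construction);
component covariances carry the base measure Φ^(j) ~ IW(n0, W0).

## Priors and hyperparameters

| Parameter | Prior | Default | Notes |
|---|---|---|---|
| β | N(0, v I) | v = 10⁶ | diffuse |
| Ψ | IW(S0, df) | S0 = I, df = 2 | weakest proper IW for 2×2 |
| α | Gamma(a1, a2) | Gamma(2, 2) | four named choices shipped: noninformative Gamma(0.001, 0.001), weak Gamma(2, 2), accurate Gamma(100, 100), inaccurate Gamma(10, 100) |
| Φ^(j) | IW(n0, W0) | n0 = T + 2 | weakest IW with a finite mean |
| W0 = w0 I | w0 ~ Gamma(aw, bw) | Gamma(1, 1) | scalar learned scale (default mode) |
| W0 (matrix mode) | Wishart(η0, V0) | η0 = T + 2, V0 = I/(T+2) | full conjugate hyperprior, E[W0] = I |

Both hyperprior forms are conjugate — the IW(n0, W0) likelihood is
Wishart-shaped (gamma-shaped, in the scalar case) in W0 — so the W0
update is a closed-form Gibbs draw either way.  The choice matters more
than it looks: the marginal covariance of y decomposes as ΛΨΛ′ + Φ, and
with unstructured T×T component covariances this split is identified
mainly by the priors, not the likelihood.  Two failure modes were mapped
while validating against an independent implementation of the same model
in JAGS.  A hyperprior centered well above the error scale lets the
mixture absorb random-effect variance (σ²_L drifts down, σ²_e up, along
the likelihood ridge).  And a full-matrix learned W0 — even correctly
centered — lets the heavy-tailed base measure generate structurally
diverse empty components that capture subjects on perfectly normal data,
inflating the occupied cluster count and deflating the pooled residual
error variance.  An isotropic learned scale avoids both, matches the
reference implementation's behavior (it is also the only scale hyperprior
general-purpose Gibbs engines can sample for this model), and is
therefore the default; the matrix mode remains available for sensitivity
analysis, and all hyperparameters are exposed on `DpmSpec` because σ²_e
recovery is sensitive to them.

## Gibbs sweep

Each iteration updates, in order: subject effects b_i (bivariate normal,
batched over components), fixed effects β (bivariate normal), Ψ (inverse
Wishart), allocations z_i (categorical over C components in log space),
the base scale W0, all component covariances Φ^(j), and the sticks and α.

W0's conditional uses the occupied components only: unoccupied Φ^(j)
integrate out of it exactly, and are refreshed from the base measure
IW(n0, W0) in the same block immediately afterwards (an empty component's
"posterior" IW(n0 + 0, W0 + 0) is the base measure).  This is exact
blocked Gibbs, not an approximation.

Two α updates are available.  `run_chain`'s default is the
stick-conjugate draw α ~ Gamma(a1 + C − 1, a2 − Σ_{j<C} log(1−q_j)), the
exact conditional under the truncated construction actually sampled.  The
augmented two-gamma-mixture update (x ~ Beta(α+1, N), then a mixture of
Gamma(a1+K, a2−log x) and Gamma(a1+K−1, a2−log x)) conditions on the
occupied cluster count K only and is exact for the unconditional DP.  The
two are not interchangeable in their posteriors for α: the stick update
is additionally informed by the C − 1 sticks (most of them unoccupied)
and shifts tight priors upward, while the augmented update tracks K.
The study harness uses the augmented update — it is the conditional
posterior whose prior-sensitivity the simulation study analyzes — while
library fits default to the exact stick form.  `bnpgcm.dp` also exposes
the one-gamma approximation Gamma(a1+K−1, a2+γ+log N) together with a
total-variation measurement of its quality, since that approximation is
reported rather than relied on.

Monitored quantities per stored iteration: β_L, β_S, σ²_L, σ²_S, σ_LS,
two error-scale summaries (below), α, and the number of occupied clusters
K.  Default chain protocol: 50,000 iterations, first half burn-in, no
thinning.

### Error-scale summaries

Because Φ is not a single estimated matrix under the DPM, two scalar
summaries are recorded each iteration:

* `sigma2_e` — the pooled residual second moment, the mean diagonal of
  (1/N) Σ_i e_i e_i′ at the sampled residuals e_i = y_i − Λ b_i.  This is
  the summary used in study tables; it directly measures the error scale
  the sampled residuals carry.
* `sigma2_e_mix` — the stick-weighted mixture variance, the occasion-mean
  diagonal of Σ_j p_j Φ^(j) (`derive_error_scale`).  This is the
  model-implied marginal error variance, including the weight the prior
  places on unoccupied components.

Under the default hyperpriors the two agree closely on clean data.

## Numerical choices

* Allocation probabilities are computed in log space and sampled by
  inverse CDF against the row maximum, immune to underflow.
* Inverse-Wishart draws use the Bartlett decomposition on the precision
  side; the two hot loops (allocation, batched IW) are compiled with
  numba, with NumPy reference implementations consuming the identical
  random stream kept and tested for agreement.
* Near-singular solves fall back to a 1e−8 diagonal jitter with a warning;
  a numerical failure in a sweep is retried once, then the chain aborts
  with a diagnostic.
* The initial Φ is the homoscedastic least-squares residual scale times I.
  The raw LS residual scatter is rank-deficient (residuals live in the
  (T−2)-dimensional complement of col(Λ)) and must not be used directly.
* Discrete cluster-count quantiles use the convention "smallest k whose
  CDF ≥ prob", which reproduces the reference quantile table exactly; the
  Euler–Mascheroni constant enters at double precision.
* HPD intervals are the shortest window containing ⌈mass·n⌉ sorted draws.

## Convergence assessment

The Geweke statistic compares the first 10% and last 50% of a stored
chain, standardized by AR-spectral estimates of the variance at frequency
zero (AIC-selected order, the convention of standard MCMC diagnostic
software).  A chain passes when |z| < 1.96 strictly; a model "converges"
when all monitored parameters pass.  The default monitor list is β_L,
β_S, σ²_L, σ²_S, σ_LS, σ²_e, α, K — the label-invariant model summaries;
per-component quantities are excluded as label-dependent, and the list is
configurable because the resulting convergence rate depends on it.  A
degenerate chain — one with a zero-variance segment, including a chain
constant over the whole stored run (e.g. K frozen at 1 when a diffuse α
prior collapses the mixture) — is counted as non-converged, matching the
standard R pipeline where a constant chain yields z = NaN and NaN fails
the |z| < 1.96 test.

## Synthetic data

`generate_normal_panel` draws balanced panels from the model itself with
the study's population values as defaults: β = (6.2, 0.3), T = 4,
σ²_e = 0.5, σ²_L = 1, σ²_S = 0.1, σ_LS = 0.  `contaminate` emulates
mean-shifted outliers: at each occasion, round(r·N) subjects (half-even
rounding, selection without replacement within an occasion, independent
across occasions) have that cell replaced by a draw from one of 10
outlier components, each normal with mean L_i + S_i·t + m_c·σ_e and the
clean error variance; the multipliers m_c are i.i.d. Poisson draws
truncated to m ≥ 5, drawn once per panel, so the full generating law is
an 11-component mixture.  The truncated-Poisson rate defaults to 5 (the
untruncated mean equals the truncation floor) — the rate and what
distinguishes the 10 components are modeling choices here, exposed on
`OutlierSpec`, and summary statistics of contaminated conditions depend
on them.  The generator reproduces clean data exactly; features of real
longitudinal data it does not emulate include skewed populations,
missingness, unbalanced occasions and time-varying covariates, so passing
tests speak to the estimator's behavior under this generating law only.

## Study harness and problem sizes

`run_condition` executes generate → contaminate → fit → diagnose per
replication and aggregates Est, Bias, ASE, ESE, MSE and 95% HPD coverage
per parameter, using converged replications only (the convergence rate is
over all replications).  No truth is defined for σ²_e under contamination
(the marginal error law is the 11-component mixture), nor ever for K and
α; those cells are reported as absent.  The full protocol is 500
replications of 50,000-iteration chains per condition across the
2 × 4 × 4 grid (N ∈ {200, 600} × outlier share ∈ {0, 5, 10, 20%} × four
α priors); `Condition.scaled` and the CLI `--scale` flag shrink
replications and chain length jointly for desk-scale runs.

The acceptance script and tests run a scaled-down version of the normal
N = 200 conditions: ten replications with 10,000-iteration chains.  On
this weakly identified model the variance-split chains mix on a ~10⁴
iteration timescale, so at desk scale only a minority of replications
pass the strict all-parameter Geweke screen — consistent with the low
full-scale convergence rates this model family is known for, and the
reason the diffuse α prior's rate is the lowest.  When fewer than two
replications converge the script aggregates over all replications and
says so (`aggregated_over`).

## Known limitations

* Single chain per fit; no Gelman–Rubin or effective-sample-size
  diagnostics.
* The ΛΨΛ′/Φ variance split is prior-identified on normal data;
  conclusions about σ²_L and σ²_e at other hyperprior centers require the
  sensitivity analysis the exposed hyperparameters enable.
* DPM on the random effects, non-normal base measures, unbalanced panels
  and model-fit indices (DIC/WAIC) are out of scope.
* Label switching is not corrected; all monitored quantities are
  label-invariant.
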