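# bnpgcm — Bayesian non-parametric growth curve modeling

`bnpgcm` fits linear latent growth curve models whose measurement errors
follow a Dirichlet process mixture (DPM) of multivariate normals, and
ships the simulation machinery to study how the prior on the DP precision
parameter α affects convergence and estimation.  It is aimed at
methodologists and applied longitudinal researchers who want
distribution-free error modeling — robust to outliers and non-normality —
without committing to a fixed number of mixture components.

## Model

For N subjects measured at T occasions,

    y_i = Λ b_i + e_i,      b_i = β + u_i,      u_i ~ MN₂(0, Ψ),
    e_i | Φ_i ~ MN_T(0, Φ_i),    Φ_i | G ~ G,    G ~ DP(α, G0),

with Λ the linear design (intercept + slope at occasions 0,…,T−1).  The
DP is sampled through a truncated stick-breaking construction with C
components and inverse-Wishart base measure IW(n0, W0), W0 itself learned
under a conjugate Wishart hyperprior; estimation is by Gibbs sampling with
exact conjugate conditionals throughout.  The number of occupied error
clusters K follows, asymptotically, K = 1 + x with
x ~ Poisson(α(γ + log N)) — the package's `dp` module carries this law,
its quantile table, and the exact (two-gamma mixture) and approximate
posteriors of α under a Gamma(a1, a2) prior.

See `docs/methods.md` for the full model, priors, sweep and design
rationale.

## Worked example

```python
import numpy as np
from bnpgcm import (
    DpmSpec, FixedEffects, GammaPrior, RandomEffectCov,
    generate_normal_panel, linear_design, run_chain,
)
from bnpgcm.diagnostics import diagnose_draws, hpd_interval

panel = generate_normal_panel(
    FixedEffects(6.2, 0.3), RandomEffectCov(1.0, 0.1, 0.0),
    sigma2_e=0.5, n=200, design=linear_design(4), seed=103,
)
spec = DpmSpec(alpha_prior=GammaPrior(2.0, 2.0))   # weakly informative
draws = run_chain(panel, spec, n_iter=10_000, burn_in=5_000, seed=103)

for name in ("beta_L", "beta_S", "sigma2_L", "sigma2_e", "alpha", "K"):
    iv = hpd_interval(draws[name], 0.95)
    print(f"{name:9s} {np.mean(draws[name]):7.3f}  [{iv.lower:6.3f}, {iv.upper:6.3f}]")
```

prints

```
beta_L      6.078  [ 5.929,  6.238]
beta_S      0.361  [ 0.300,  0.423]
sigma2_L    0.877  [ 0.452,  1.227]
sigma2_e    0.553  [ 0.342,  0.831]
alpha       1.028  [ 0.122,  2.223]
K           5.946  [ 2.000, 11.000]
```

The mean intercept and slope sit near this panel's generating values
(6.2, 0.3).  The intercept variance σ²_L and the error variance σ²_e
land near 1 and 0.5 with wide, overlapping-looking intervals — the
decomposition of cov(y) into ΛΨΛ′ + Φ is only weakly identified with
unstructured mixture covariances, so these two chains mix slowly and
trade off against each other (the methods note discusses this at
length).  With the Gamma(2, 2) prior the chain occupies about six error
clusters even on purely normal data.  `diagnose_draws(draws)` returns
the per-parameter Geweke z statistics behind the convergence decision.

The same pipeline is scriptable from the shell:

```bash
bnpgcm simulate --n 200 --seed 103 --out panel.csv
bnpgcm fit panel.csv --n-iter 10000 --seed 103 --out-dir fit/
bnpgcm diagnose fit/draws.csv
bnpgcm table1            # analytic cluster-count quantile table
bnpgcm study examples/study.yaml --scale 0.02 --out-dir study/
```

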