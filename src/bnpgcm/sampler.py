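"""Gibbs sampler for the BNP growth curve model.

The model couples a linear latent growth curve, y_i = Lambda b_i + e_i with
b_i ~ MN(beta, Psi), to a Dirichlet process mixture for the measurement
errors: e_i | Phi_i ~ MN_T(0, Phi_i) with Phi_i | G ~ G and G ~ DP(alpha, G0).
The DP is represented by its truncated stick-breaking construction with C
components: sticks q_j ~ Beta(1, alpha) give weights p_j (sum-normalized),
component covariances Phi^(j) carry inverse-Wishart IW(n0, W0) base priors
with a Wishart hyperprior on the scale matrix W0, and each subject's error
vector is allocated to one component.

Priors on the structural parameters follow the conventional diffuse choices:
beta ~ N(0, 10^6 I) and Psi ~ IW(2, I).

All full conditionals are conjugate, so every block is a closed-form Gibbs
draw.  The scale matrix W0 and the unoccupied component covariances are
updated as one exact block: W0 is drawn given the occupied components only
(the unoccupied ones integrate out of its conditional), after which every
component covariance — occupied and empty alike — is refreshed from
IW(n0 + n_j, W0 + S_j), which for an empty component is exactly the base
measure IW(n0, W0).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # compiled inner loops; the NumPy paths below are the reference
    from . import _kernels
except ImportError:  # pragma: no cover
    _kernels = None

from .dp import GammaPrior, StickWeights, sample_alpha_augmented, stick_break
from .gcm import FixedEffects, GrowthDesign, RandomEffectCov, linear_design
from .simulate import LongitudinalPanel

__all__ = [
    "DpmSpec",
    "ChainState",
    "PosteriorDraws",
    "init_state",
    "run_chain",
    "update_fixed_effects",
    "update_subject_effects",
    "update_psi",
    "update_allocations",
    "update_component_covs",
    "update_base_scale",
    "update_sticks_and_alpha",
    "derive_error_scale",
    "residual_error_scale",
    "sample_prior_predictive",
    "MONITORED",
]

# quantities recorded per stored iteration
MONITORED = (
    "beta_L", "beta_S", "sigma2_L", "sigma2_S", "sigma_LS",
    "sigma2_e", "sigma2_e_mix", "alpha", "K",
)

_JITTER = 1e-8


@dataclass(frozen=True)
class DpmSpec:
    """Prior and truncation settings for the DPM growth curve model.

    Parameters
    ----------
    truncation
        Stick-breaking truncation level C (>= 2).  The default of 50 far
        exceeds the 95th-percentile cluster count for the precision values
        and sample sizes this model is typically run at.
    alpha_prior
        Gamma(a1, a2) prior for the DP precision parameter.
    base_df
        Inverse-Wishart shape n0 of the component-covariance base measure;
        ``None`` resolves to T + 2 at initialization (weakest proper IW
        with a finite mean).
    base_scale_mode
        "scalar" (default): W0 = w0 I with w0 ~ Gamma(1, 1), updated by its
        conjugate gamma conditional.  An isotropic learned scale keeps the
        base measure from generating structurally diverse empty components
        that capture subjects and split the error scale; it is also the
        only scale hyperprior the standard general-purpose Gibbs engines
        can sample for this model.  "matrix": full Wishart hyperprior
        W0 ~ Wishart(base_scale_df, base_scale_matrix).
    base_scale_df, base_scale_matrix
        Hyperparameters of the matrix-mode Wishart hyperprior (the
        conjugate family for the scale of an inverse-Wishart likelihood);
        ``None`` resolve to df = T + 2 with scale I / (T + 2), centering
        the hyperprior at E[W0] = I (the unit error scale).  The
        equilibrium of the weakly identified random-effect/error variance
        split is sensitive to these choices, so they are exposed rather
        than buried.
    fixed_effect_prior_var
        Prior variance of the diffuse N(0, v I) prior on beta.
    psi_prior_df, psi_prior_scale
        Inverse-Wishart prior for Psi (identity scale, 2 degrees of freedom
        by default).
    alpha_update
        "stick" for the stick-conjugate gamma update implied by the
        truncated construction (default), or "escobar_west" for the
        augmented two-gamma-mixture update.
    """

    truncation: int = 50
    alpha_prior: GammaPrior = field(default_factory=lambda: GammaPrior(2.0, 2.0))
    base_df: float | None = None
    base_scale_mode: str = "scalar"
    base_scale_prior: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 1.0))
    base_scale_df: float | None = None
    base_scale_matrix: np.ndarray | None = None
    fixed_effect_prior_var: float = 1e6
    psi_prior_df: float = 2.0
    psi_prior_scale: np.ndarray | None = None
    alpha_update: str = "stick"
    component_means_fixed_zero: bool = True

    def __post_init__(self) -> None:
        if self.truncation < 2:
            raise ValueError("truncation must be >= 2")
        if self.alpha_update not in ("stick", "escobar_west"):
            raise ValueError("alpha_update must be 'stick' or 'escobar_west'")
        if self.base_scale_mode not in ("scalar", "matrix"):
            raise ValueError("base_scale_mode must be 'scalar' or 'matrix'")
        if not self.component_means_fixed_zero:
            raise NotImplementedError("only zero-mean mixture components are supported")

    def resolve(self, n_occasions: int) -> "_ResolvedSpec":
        t = n_occasions
        base_df = self.base_df if self.base_df is not None else t + 2.0
        if base_df <= t - 1:
            raise ValueError("base_df must exceed T - 1 for a proper base measure")
        scale_df = self.base_scale_df if self.base_scale_df is not None else t + 2.0
        scale_mat = (
            np.eye(t) / scale_df if self.base_scale_matrix is None
            else np.asarray(self.base_scale_matrix, dtype=float)
        )
        psi_scale = (
            np.eye(2) if self.psi_prior_scale is None
            else np.asarray(self.psi_prior_scale, dtype=float)
        )
        return _ResolvedSpec(
            truncation=self.truncation,
            alpha_prior=self.alpha_prior,
            base_df=float(base_df),
            base_scale_mode=self.base_scale_mode,
            base_scale_prior=self.base_scale_prior,
            base_scale_df=float(scale_df),
            base_scale_matrix=scale_mat,
            fixed_effect_prior_var=self.fixed_effect_prior_var,
            psi_prior_df=self.psi_prior_df,
            psi_prior_scale=psi_scale,
            alpha_update=self.alpha_update,
        )


@dataclass(frozen=True)
class _ResolvedSpec:
    truncation: int
    alpha_prior: GammaPrior
    base_df: float
    base_scale_mode: str
    base_scale_prior: GammaPrior
    base_scale_df: float
    base_scale_matrix: np.ndarray
    fixed_effect_prior_var: float
    psi_prior_df: float
    psi_prior_scale: np.ndarray
    alpha_update: str


@dataclass
class ChainState:
    """Full parameter state of one Gibbs iteration."""

    beta: np.ndarray            # (2,)
    b: np.ndarray               # (N, 2) subject effects
    psi: np.ndarray             # (2, 2)
    z: np.ndarray               # (N,) component labels in 0..C-1
    phis: np.ndarray            # (C, T, T) component covariances
    precisions: np.ndarray      # (C, T, T) their inverses
    logdet_phis: np.ndarray     # (C,)
    sticks: StickWeights
    alpha: float
    w0: np.ndarray              # (T, T) base-measure scale

    @property
    def n_occupied(self) -> int:
        return int(np.unique(self.z).size)

    @property
    def fixed_effects(self) -> FixedEffects:
        return FixedEffects(float(self.beta[0]), float(self.beta[1]))

    @property
    def random_effect_cov(self) -> RandomEffectCov:
        return RandomEffectCov.from_matrix(self.psi)


@dataclass(frozen=True)
class PosteriorDraws:
    """Stored post-burn-in draws of the monitored quantities."""

    draws: dict
    total_iterations: int
    burn_in: int
    seed: int
    runtime_seconds: float = float("nan")

    def __post_init__(self) -> None:
        n = self.total_iterations - self.burn_in
        for name, arr in self.draws.items():
            if len(arr) != n:
                raise ValueError(f"draw array '{name}' has length {len(arr)}, expected {n}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws)

    def posterior_means(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.draws.items()}

    def posterior_sds(self) -> dict:
        return {k: float(np.std(v, ddof=1)) for k, v in self.draws.items()}


# ---------------------------------------------------------------------------
# numerical helpers

from functools import lru_cache


@lru_cache(maxsize=None)
def _tril_idx(p: int):
    return np.tril_indices(p, -1)


def _inv_2x2(a: np.ndarray, warn_label: str | None = None) -> np.ndarray:
    """Closed-form 2x2 inverse with jitter fallback (faster than LAPACK here)."""
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < 1e-300:
        if warn_label:
            warnings.warn(f"singular {warn_label}: applying diagonal jitter", stacklevel=2)
        a = a + _JITTER * np.eye(2)
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    return np.array([[a[1, 1], -a[0, 1]], [-a[1, 0], a[0, 0]]]) / det


def _sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def _safe_inv(a: np.ndarray, warn_label: str | None = None) -> np.ndarray:
    """Inverse with diagonal jitter fallback for near-singular matrices."""
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError:
        if warn_label:
            warnings.warn(f"singular {warn_label}: applying diagonal jitter", stacklevel=2)
        eye = np.eye(a.shape[-1])
        return np.linalg.inv(a + _JITTER * eye)


def _wishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Wishart(df, scale) draw via the Bartlett decomposition."""
    p = scale.shape[0]
    chol = np.linalg.cholesky(scale)
    a = np.zeros((p, p))
    for i in range(p):
        a[i, i] = np.sqrt(rng.chisquare(df - i))
    if p > 1:
        rows, cols = _tril_idx(p)
        a[rows, cols] = rng.standard_normal(len(rows))
    m = chol @ a
    return _sym(m @ m.T)


def _inv_wishart_batch(
    dfs: np.ndarray, scales: np.ndarray, rng: np.random.Generator, use_kernels: bool = True
):
    """Batched IW(df_j, S_j) draws.

    Returns (covariances, precisions, logdet covariances).  Uses the
    Bartlett construction on the precision side: Phi^-1 ~ Wishart(df, S^-1).
    """
    c, t, _ = scales.shape
    if _kernels is not None and use_kernels:
        chi = np.empty((c, t))
        for i in range(t):
            chi[:, i] = rng.chisquare(dfs - i)
        n_tril = t * (t - 1) // 2
        norms = rng.standard_normal((c, n_tril))
        return _kernels.inv_wishart_kernel(np.ascontiguousarray(scales, dtype=float), chi, norms)
    inv_scales = _safe_inv(_sym(scales), "inverse-Wishart scale")
    chol = np.linalg.cholesky(_sym(inv_scales))
    a = np.zeros((c, t, t))
    for i in range(t):
        a[:, i, i] = np.sqrt(rng.chisquare(dfs - i))
    if t > 1:
        rows, cols = _tril_idx(t)
        a[:, rows, cols] = rng.standard_normal((c, len(rows)))
    m = chol @ a
    precisions = _sym(m @ np.swapaxes(m, 1, 2))
    diag = np.abs(np.diagonal(m, axis1=1, axis2=2))
    logdet_prec = 2.0 * np.log(diag).sum(axis=1)
    covs = _sym(np.linalg.inv(precisions))
    return covs, precisions, -logdet_prec


def _inv_wishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    covs, _, _ = _inv_wishart_batch(np.array([df]), scale[None], rng)
    return covs[0]


# ---------------------------------------------------------------------------
# initialization

def init_state(panel: LongitudinalPanel, spec: DpmSpec, seed: int) -> ChainState:
    """Deterministic starting state.

    Fixed and subject effects start at least squares; Psi at the sample
    covariance of the least-squares effects; all subjects are allocated to
    the first component; every component covariance starts at the pooled
    least-squares error covariance; alpha starts at its prior mean.
    """
    t = panel.n_occasions
    if t < 2:
        raise ValueError("at least two occasions are required (slope unidentifiable)")
    rs = spec.resolve(t)
    n = panel.n_subjects
    lam = np.column_stack([np.ones(t), np.asarray(panel.occasion_codes, dtype=float)])
    y = panel.outcomes
    b = np.linalg.lstsq(lam, y.T, rcond=None)[0].T  # (N, 2)
    beta = b.mean(axis=0) if n > 0 else np.zeros(2)
    if n > 1:
        psi = np.cov(b, rowvar=False)
    else:
        psi = np.eye(2)
    psi = _sym(psi) + _JITTER * np.eye(2)
    if n > 0:
        resid = y - b @ lam.T
        # least-squares residuals are confined to the complement of col(Lambda),
        # so their scatter is rank deficient; start from the homoscedastic
        # residual scale instead of the raw scatter matrix
        err_cov = max(float(np.mean(resid**2)), _JITTER) * np.eye(t)
    else:
        err_cov = np.eye(t)
    c = rs.truncation
    phis = np.broadcast_to(err_cov, (c, t, t)).copy()
    precisions = np.broadcast_to(_safe_inv(err_cov), (c, t, t)).copy()
    logdet = float(np.linalg.slogdet(err_cov)[1]) * np.ones(c)
    alpha = rs.alpha_prior.mean
    q0 = np.full(c, 1.0 / (1.0 + alpha))  # prior-mean sticks
    q0[-1] = 1.0
    return ChainState(
        beta=beta,
        b=b,
        psi=psi,
        z=np.zeros(n, dtype=np.int64),
        phis=phis,
        precisions=precisions,
        logdet_phis=logdet,
        sticks=stick_break(q0),
        alpha=float(alpha),
        w0=(
            rs.base_scale_prior.mean * np.eye(t)
            if rs.base_scale_mode == "scalar"
            else rs.base_scale_matrix * rs.base_scale_df
        ),
    )


# ---------------------------------------------------------------------------
# full-conditional updates

def update_fixed_effects(
    state: ChainState, panel: LongitudinalPanel, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    """beta | {b_i}, Psi — conjugate bivariate normal."""
    n = state.b.shape[0]
    psi_inv = _inv_2x2(state.psi, "Psi")
    prec = n * psi_inv + np.eye(2) / spec.fixed_effect_prior_var
    cov = _inv_2x2(prec)
    mean = cov @ psi_inv @ state.b.sum(axis=0) if n > 0 else np.zeros(2)
    state.beta = mean + np.linalg.cholesky(_sym(cov)) @ rng.standard_normal(2)
    return state


def update_subject_effects(
    state: ChainState, panel: LongitudinalPanel, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    """b_i | y_i, z_i, Phi, beta, Psi — conjugate normal, batched by component."""
    n = panel.n_subjects
    if n == 0:
        return state
    t = panel.n_occasions
    lam = np.column_stack([np.ones(t), np.asarray(panel.occasion_codes, dtype=float)])
    psi_inv = _inv_2x2(state.psi, "Psi")
    p = state.precisions                              # (C, T, T)
    g = lam.T @ p                                     # (C, 2, T) = Lambda' P_j
    m = g @ lam                                       # (C, 2, 2) = Lambda' P_j Lambda
    v = _safe_inv(m + psi_inv, "subject-effect precision")   # (C, 2, 2)
    chol_v = np.linalg.cholesky(_sym(v))
    z = state.z
    rhs = np.einsum("iau,iu->ia", g[z], panel.outcomes) + psi_inv @ state.beta
    mean = np.einsum("iab,ib->ia", v[z], rhs)
    noise = np.einsum("iab,ib->ia", chol_v[z], rng.standard_normal((n, 2)))
    state.b = mean + noise
    return state


def update_psi(state: ChainState, spec: _ResolvedSpec, rng: np.random.Generator) -> ChainState:
    """Psi | {u_i} ~ IW(df0 + N, S0 + sum u_i u_i')."""
    u = state.b - state.beta
    n = u.shape[0]
    scale = spec.psi_prior_scale + u.T @ u
    w = _wishart(spec.psi_prior_df + n, _inv_2x2(scale), rng)
    state.psi = _inv_2x2(w)
    return state


def update_allocations(
    state: ChainState, panel: LongitudinalPanel, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    """z_i ~ Categorical with P(z_i = j) ∝ p_j MN(e_i; 0, Phi^(j))."""
    n = panel.n_subjects
    if n == 0:
        return state
    t = panel.n_occasions
    lam = np.column_stack([np.ones(t), np.asarray(panel.occasion_codes, dtype=float)])
    e = panel.outcomes - state.b @ lam.T
    logp = np.log(state.sticks.normalized + 1e-300)
    uniforms = rng.random(n)
    if _kernels is not None:
        state.z = _kernels.alloc_kernel(
            np.ascontiguousarray(e), state.precisions, state.logdet_phis, logp, uniforms
        )
        return state
    # quadratic forms e_i' P_j e_i for all (i, j), via one BLAS contraction
    ep = np.tensordot(e, state.precisions, axes=([1], [1]))  # (N, C, T)
    quad = np.einsum("ijt,it->ij", ep, e)
    logw = logp[None, :] - 0.5 * state.logdet_phis[None, :] - 0.5 * quad
    # inverse-CDF categorical draw in log space (identical stream to the kernel)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    cdf = np.cumsum(w, axis=1)
    target = uniforms * cdf[:, -1]
    state.z = (cdf < target[:, None]).sum(axis=1)
    return state


def update_base_scale(
    state: ChainState, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    """W0 | occupied {Phi^(j)} — conjugate Wishart-form update.

    The IW(n0, W0) likelihood is Wishart-shaped in W0.  In scalar mode
    (W0 = w0 I) the conditional for w0 is Gamma(a + n0 T K / 2,
    b + sum_occ tr(Phi_j^-1) / 2); in matrix mode it is the full Wishart
    Wishart(eta0 + n0 K, (V0^-1 + sum_occ Phi_j^-1)^-1).  Unoccupied
    components integrate out of this conditional (they carry no likelihood
    terms) and are refreshed from the base measure immediately afterwards
    by ``update_component_covs``.
    """
    occupied = np.unique(state.z)
    k = occupied.size
    t = state.phis.shape[1]
    if spec.base_scale_mode == "scalar":
        prior = spec.base_scale_prior
        trace_sum = (
            float(np.trace(state.precisions[occupied].sum(axis=0))) if k else 0.0
        )
        shape = prior.shape + spec.base_df * t * k / 2.0
        rate = prior.rate + trace_sum / 2.0
        w0 = float(rng.gamma(shape=shape, scale=1.0 / rate))
        state.w0 = w0 * np.eye(t)
        return state
    v0_inv = _safe_inv(spec.base_scale_matrix, "base-scale hyperprior matrix")
    prec_sum = state.precisions[occupied].sum(axis=0) if k else np.zeros((t, t))
    df = spec.base_scale_df + spec.base_df * k
    scale = _safe_inv(v0_inv + prec_sum, "base-scale posterior matrix")
    state.w0 = _wishart(df, scale, rng)
    return state


def update_component_covs(
    state: ChainState, panel: LongitudinalPanel, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    """Phi^(j) ~ IW(n0 + n_j, W0 + S_j); empty components draw the base IW(n0, W0)."""
    c = spec.truncation
    t = state.phis.shape[1]
    counts = np.bincount(state.z, minlength=c).astype(float)
    scatter = np.zeros((c, t, t))
    if panel.n_subjects:
        lam = np.column_stack([np.ones(t), np.asarray(panel.occasion_codes, dtype=float)])
        e = panel.outcomes - state.b @ lam.T
        if _kernels is not None:
            scatter = _kernels.scatter_kernel(np.ascontiguousarray(e), state.z, c)
        else:
            # per-component residual scatter via bincount on each (t, u) pair
            for ti in range(t):
                for tu in range(ti, t):
                    col = np.bincount(state.z, weights=e[:, ti] * e[:, tu], minlength=c)
                    scatter[:, ti, tu] = col
                    if tu != ti:
                        scatter[:, tu, ti] = col
    dfs = spec.base_df + counts
    scales = state.w0[None] + scatter
    state.phis, state.precisions, state.logdet_phis = _inv_wishart_batch(dfs, scales, rng)
    return state


def update_sticks_and_alpha(
    state: ChainState, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    """q_j ~ Beta(1 + n_j, alpha + n_>j); weights by stick-breaking; then alpha.

    The final stick is pinned at 1, so the truncated construction allocates
    all remaining mass to component C and the stick-breaking normalization
    is exact; every conditional below is then an exact Gibbs draw.  The
    default alpha update is the stick-conjugate gamma draw
    Gamma(a1 + C - 1, a2 - sum_{j<C} log(1 - q_j)) implied by the
    Beta(1, alpha) likelihood of the C - 1 free sticks; the augmented
    Escobar–West mixture update is available as an option.
    """
    c = spec.truncation
    counts = np.bincount(state.z, minlength=c).astype(float)
    tail = counts.sum() - np.cumsum(counts)          # n_{>j}
    q = rng.beta(1.0 + counts[:-1], state.alpha + tail[:-1])
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    q = np.append(q, 1.0)
    state.sticks = stick_break(q)
    prior = spec.alpha_prior
    if spec.alpha_update == "stick":
        shape = prior.shape + c - 1
        rate = prior.rate - np.log1p(-q[:-1]).sum()
        state.alpha = float(rng.gamma(shape=shape, scale=1.0 / rate))
    else:
        state.alpha = sample_alpha_augmented(
            prior, state.n_occupied, max(len(state.z), 1), state.alpha, rng
        )
    # a gamma draw with near-zero shape (diffuse prior, K = 1) can underflow
    state.alpha = max(state.alpha, 1e-12)
    return state


def derive_error_scale(state: ChainState) -> float:
    """Stick-weighted marginal error variance.

    Mean over occasions of the diagonal of sum_j p_j Phi^(j), the
    model-implied marginal covariance of e_i under the mixture.
    """
    p = state.sticks.normalized
    mixture_diag = np.einsum("j,jtt->t", p, state.phis)
    return float(mixture_diag.mean())


def residual_error_scale(state: ChainState, panel: LongitudinalPanel) -> float:
    """Pooled residual error variance.

    The sampled residuals e_i = y_i - Lambda b_i determine the pooled error
    covariance Phi = (1/N) sum_i e_i e_i'; returns the mean of its diagonal,
    i.e. the homoscedastic error-scale summary sigma2_e.
    """
    if panel.n_subjects == 0:
        return 0.0
    t = panel.n_occasions
    lam = np.column_stack([np.ones(t), np.asarray(panel.occasion_codes, dtype=float)])
    e = panel.outcomes - state.b @ lam.T
    return float(np.mean(e**2))


# ---------------------------------------------------------------------------
# chain driver

def _sweep(
    state: ChainState, panel: LongitudinalPanel, spec: _ResolvedSpec, rng: np.random.Generator
) -> ChainState:
    update_subject_effects(state, panel, spec, rng)
    update_fixed_effects(state, panel, spec, rng)
    update_psi(state, spec, rng)
    update_allocations(state, panel, spec, rng)
    update_base_scale(state, spec, rng)
    update_component_covs(state, panel, spec, rng)
    update_sticks_and_alpha(state, spec, rng)
    return state


def _record(state: ChainState, panel: LongitudinalPanel, out: dict, idx: int) -> None:
    out["beta_L"][idx] = state.beta[0]
    out["beta_S"][idx] = state.beta[1]
    out["sigma2_L"][idx] = state.psi[0, 0]
    out["sigma2_S"][idx] = state.psi[1, 1]
    out["sigma_LS"][idx] = state.psi[0, 1]
    out["sigma2_e"][idx] = residual_error_scale(state, panel)
    out["sigma2_e_mix"][idx] = derive_error_scale(state)
    out["alpha"][idx] = state.alpha
    out["K"][idx] = state.n_occupied


def run_chain(
    panel: LongitudinalPanel,
    spec: DpmSpec,
    n_iter: int = 50_000,
    burn_in: int | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Run one Gibbs chain and store post-burn-in draws.

    The defaults follow the standard protocol for this model: 50,000
    iterations with the first half as burn-in and no thinning.  A
    numerical failure in any block is retried once from the current state;
    a second failure aborts the chain with a diagnostic message.
    """
    if burn_in is None:
        burn_in = n_iter // 2
    if not 0 <= burn_in < n_iter:
        raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
    rs = spec.resolve(panel.n_occasions)
    state = init_state(panel, spec, seed)
    rng = np.random.default_rng(seed)
    n_store = n_iter - burn_in
    out = {name: np.empty(n_store) for name in MONITORED}
    start = time.perf_counter()
    for it in range(n_iter):
        try:
            _sweep(state, panel, rs, rng)
        except (np.linalg.LinAlgError, FloatingPointError) as first_err:
            warnings.warn(
                f"numerical failure at iteration {it} ({first_err}); retrying once",
                stacklevel=2,
            )
            try:
                _sweep(state, panel, rs, rng)
            except (np.linalg.LinAlgError, FloatingPointError) as err:
                raise RuntimeError(
                    f"chain aborted at iteration {it} after retry: {err}"
                ) from err
        if it >= burn_in:
            _record(state, panel, out, it - burn_in)
    runtime = time.perf_counter() - start
    return PosteriorDraws(
        draws=out,
        total_iterations=n_iter,
        burn_in=burn_in,
        seed=seed,
        runtime_seconds=runtime,
    )


# ---------------------------------------------------------------------------
# prior-predictive generation (used for sampler validation)

def sample_prior_predictive(
    spec: DpmSpec,
    n: int,
    design: GrowthDesign,
    rng: np.random.Generator,
) -> tuple[dict, LongitudinalPanel]:
    """Draw parameters from the model's priors and a panel from them.

    Returns the drawn parameter dictionary (keys matching the monitored
    quantities where defined) and the generated panel.  This is the
    generator side of simulation-based calibration: data produced here
    follow exactly the joint law the Gibbs sampler targets.
    """
    t = design.n_occasions
    rs = spec.resolve(t)
    lam = design.loading_matrix
    beta = rng.normal(0.0, np.sqrt(rs.fixed_effect_prior_var), size=2)
    psi = _inv_wishart(rs.psi_prior_df, rs.psi_prior_scale, rng)
    alpha = rng.gamma(shape=rs.alpha_prior.shape, scale=1.0 / rs.alpha_prior.rate)
    q = np.clip(rng.beta(1.0, alpha, size=rs.truncation - 1), 1e-12, 1 - 1e-12)
    weights = stick_break(np.append(q, 1.0)).normalized
    if rs.base_scale_mode == "scalar":
        w0 = float(
            rng.gamma(shape=rs.base_scale_prior.shape, scale=1.0 / rs.base_scale_prior.rate)
        ) * np.eye(t)
    else:
        w0 = _wishart(rs.base_scale_df, rs.base_scale_matrix, rng)
    phis, _, _ = _inv_wishart_batch(
        np.full(rs.truncation, rs.base_df), np.broadcast_to(w0, (rs.truncation, t, t)).copy(), rng
    )
    z = rng.choice(rs.truncation, size=n, p=weights)
    b = beta + rng.multivariate_normal(np.zeros(2), psi, size=n, method="cholesky")
    chols = np.linalg.cholesky(phis)
    e = np.einsum("itu,iu->it", chols[z], rng.standard_normal((n, t)))
    y = b @ lam.T + e
    panel = LongitudinalPanel(outcomes=y, occasion_codes=design.occasion_codes, true_effects=b)
    params = {
        "beta_L": float(beta[0]),
        "beta_S": float(beta[1]),
        "sigma2_L": float(psi[0, 0]),
        "sigma2_S": float(psi[1, 1]),
        "sigma_LS": float(psi[0, 1]),
        "alpha": float(alpha),
    }
    return params, panel
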