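"""Growth curve model structure: design matrices, parameters, implied moments.

A linear growth curve model for a balanced panel of N subjects measured at
T occasions is

    y_i = Lambda b_i + e_i,        b_i = beta + u_i,

where ``Lambda`` is the T x q factor loading matrix, ``b_i`` the subject's
random effects (intercept L_i and slope S_i for the linear design),
``beta`` the fixed effects and ``e_i`` the measurement errors.  With
normal u_i ~ MN(0, Psi) and homoscedastic e_i ~ MN(0, sigma2_e I) the
implied marginal moments are E[y] = Lambda beta and
Cov[y] = Lambda Psi Lambda' + sigma2_e I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthDesign",
    "FixedEffects",
    "RandomEffectCov",
    "SubjectEffects",
    "linear_design",
    "implied_moments",
]


@dataclass(frozen=True)
class GrowthDesign:
    """Factor loading structure of a growth curve model.

    Parameters
    ----------
    loading_matrix
        T x q loading matrix Lambda.  For the linear two-factor design the
        first column is all ones (intercept) and the second column holds the
        0-based occasion codes 0, 1, ..., T-1 (slope).
    """

    loading_matrix: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.loading_matrix, dtype=float)
        if lam.ndim != 2 or lam.shape[0] < 1 or lam.shape[1] < 1:
            raise ValueError("loading_matrix must be a T x q matrix with T, q >= 1")
        if not np.all(np.isfinite(lam)):
            raise ValueError("loading_matrix must be finite")
        object.__setattr__(self, "loading_matrix", lam)

    @property
    def n_occasions(self) -> int:
        return self.loading_matrix.shape[0]

    @property
    def n_growth_factors(self) -> int:
        return self.loading_matrix.shape[1]

    @property
    def occasion_codes(self) -> np.ndarray:
        """Occasion codes 0..T-1 (the slope loadings of the linear design)."""
        return np.arange(self.n_occasions)


@dataclass(frozen=True)
class FixedEffects:
    """Mean intercept beta_L and mean slope beta_S (outcome units)."""

    intercept_mean: float
    slope_mean: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept_mean) and np.isfinite(self.slope_mean)):
            raise ValueError("fixed effects must be finite")

    def as_vector(self) -> np.ndarray:
        return np.array([self.intercept_mean, self.slope_mean], dtype=float)


@dataclass(frozen=True)
class RandomEffectCov:
    """Covariance of the random intercept and slope.

    ``var_intercept`` (sigma2_L), ``var_slope`` (sigma2_S) and their
    covariance ``cov_int_slope`` (sigma_LS) must form a symmetric positive
    semidefinite 2 x 2 matrix Psi.
    """

    var_intercept: float
    var_slope: float
    cov_int_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.var_intercept < 0 or self.var_slope < 0:
            raise ValueError("random-effect variances must be nonnegative")
        if self.cov_int_slope**2 > self.var_intercept * self.var_slope + 1e-12:
            raise ValueError("Psi must be positive semidefinite: sigma_LS^2 <= sigma2_L * sigma2_S")

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.var_intercept, self.cov_int_slope],
             [self.cov_int_slope, self.var_slope]],
            dtype=float,
        )

    @classmethod
    def from_matrix(cls, psi: np.ndarray) -> "RandomEffectCov":
        psi = np.asarray(psi, dtype=float)
        return cls(var_intercept=float(psi[0, 0]), var_slope=float(psi[1, 1]),
                   cov_int_slope=float(psi[0, 1]))


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject random effects b_i = (L_i, S_i) and deviations u_i = b_i - beta."""

    effects: np.ndarray  # N x 2, rows (L_i, S_i)
    fixed: FixedEffects

    def __post_init__(self) -> None:
        b = np.asarray(self.effects, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("effects must be an N x 2 matrix")
        object.__setattr__(self, "effects", b)

    @property
    def deviations(self) -> np.ndarray:
        return self.effects - self.fixed.as_vector()


def linear_design(n_occasions: int) -> GrowthDesign:
    """Linear growth design: T x 2 matrix with unit intercept loadings and
    0-based occasion codes as slope loadings.

    >>> linear_design(4).loading_matrix
    array([[1., 0.],
           [1., 1.],
           [1., 2.],
           [1., 3.]])
    """
    if int(n_occasions) != n_occasions or n_occasions < 1:
        raise ValueError("n_occasions must be a positive integer")
    t = int(n_occasions)
    lam = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    return GrowthDesign(loading_matrix=lam)


def implied_moments(
    fx: FixedEffects,
    cov: RandomEffectCov,
    sigma2_e: float,
    design: GrowthDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied marginal mean and covariance of y_i.

    Returns ``(Lambda beta, Lambda Psi Lambda' + sigma2_e I)``.
    """
    if sigma2_e < 0:
        raise ValueError("sigma2_e must be nonnegative")
    lam = design.loading_matrix
    if lam.shape[1] != 2:
        raise ValueError("implied_moments requires a two-factor (intercept, slope) design")
    mean = lam @ fx.as_vector()
    covariance = lam @ cov.as_matrix() @ lam.T + sigma2_e * np.eye(design.n_occasions)
    # enforce exact symmetry against floating-point drift
    covariance = 0.5 * (covariance + covariance.T)
    return mean, covariance
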