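"""Seeded synthetic longitudinal panels, clean or outlier-contaminated.

The clean generator draws balanced N x T panels from the linear growth
curve model: b_i ~ MN(beta, Psi), e_i ~ MN(0, sigma2_e I),
y_i = Lambda b_i + e_i.  The contamination step emulates mean-shifted
outliers: at each occasion a fixed proportion of observations is replaced
by draws whose mean sits at least ``min_multiplier`` error-SDs above the
subject's own trajectory, with the replacement values coming from a small
bank of shifted normal components (10 by default) so that the overall
generating law for contaminated data is an 11-component mixture — the
clean component plus the 10 outlier components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .gcm import FixedEffects, GrowthDesign, RandomEffectCov

__all__ = ["LongitudinalPanel", "OutlierSpec", "generate_normal_panel", "contaminate"]


@dataclass(frozen=True)
class LongitudinalPanel:
    """Balanced longitudinal panel of N subjects at T occasions.

    ``outcomes`` is the N x T matrix of measurements; ``occasion_codes``
    holds the 0-based time codes; ``true_effects`` (when generated
    synthetically) the N x 2 matrix of subject intercepts and slopes;
    ``contamination_mask`` flags replaced cells.
    """

    outcomes: np.ndarray
    occasion_codes: np.ndarray
    true_effects: np.ndarray | None = None
    contamination_mask: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.outcomes, dtype=float)
        if y.ndim != 2:
            raise ValueError("outcomes must be an N x T matrix")
        codes = np.asarray(self.occasion_codes)
        if codes.shape != (y.shape[1],):
            raise ValueError("occasion_codes length must match T")
        object.__setattr__(self, "outcomes", y)
        object.__setattr__(self, "occasion_codes", codes)
        if self.true_effects is not None:
            b = np.asarray(self.true_effects, dtype=float)
            if b.shape != (y.shape[0], 2):
                raise ValueError("true_effects must be N x 2")
            object.__setattr__(self, "true_effects", b)
        mask = self.contamination_mask
        if mask is None:
            mask = np.zeros(y.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != y.shape:
                raise ValueError("contamination_mask must match outcomes shape")
        object.__setattr__(self, "contamination_mask", mask)

    @property
    def n_subjects(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.outcomes.shape[1]

    def to_long_frame(self):
        """Long-format DataFrame with columns id, occasion, y, contaminated."""
        import pandas as pd

        n, t = self.outcomes.shape
        return pd.DataFrame(
            {
                "id": np.repeat(np.arange(n), t),
                "occasion": np.tile(self.occasion_codes, n),
                "y": self.outcomes.ravel(),
                "contaminated": self.contamination_mask.ravel(),
            }
        )

    def to_wide_frame(self):
        """Wide-format DataFrame with columns id, y1..yT."""
        import pandas as pd

        n, t = self.outcomes.shape
        data = {"id": np.arange(n)}
        for j in range(t):
            data[f"y{j + 1}"] = self.outcomes[:, j]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class OutlierSpec:
    """Contamination settings.

    ``proportion`` is the fraction of observations replaced at each
    occasion.  Replacements come from ``n_components`` normal component
    distributions; component c has mean L_i + S_i * t + m_c * sigma_e and
    variance ``component_variance`` (the clean error variance), where the
    shift multipliers m_c are i.i.d. draws from a Poisson(multiplier_rate)
    truncated below at ``min_multiplier``.
    """

    proportion: float
    n_components: int = 10
    min_multiplier: int = 5
    multiplier_rate: float = 5.0
    component_variance: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.proportion < 1:
            raise ValueError("proportion must lie in [0, 1)")
        if self.min_multiplier < 1 or self.n_components < 1:
            raise ValueError("min_multiplier and n_components must be >= 1")
        if self.multiplier_rate <= 0 or self.component_variance <= 0:
            raise ValueError("multiplier_rate and component_variance must be positive")

    def draw_multipliers(self, rng: np.random.Generator) -> np.ndarray:
        """One truncated-Poisson multiplier per outlier component (m >= floor)."""
        m = np.empty(self.n_components, dtype=int)
        for c in range(self.n_components):
            draw = rng.poisson(self.multiplier_rate)
            while draw < self.min_multiplier:
                draw = rng.poisson(self.multiplier_rate)
            m[c] = draw
        return m


def generate_normal_panel(
    fx: FixedEffects,
    cov: RandomEffectCov,
    sigma2_e: float,
    n: int,
    design: GrowthDesign,
    seed: int,
) -> LongitudinalPanel:
    """Draw a clean panel from the linear growth curve model.

    b_i ~ MN(beta, Psi); e_i ~ MN(0, sigma2_e I); y_i = Lambda b_i + e_i.
    Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma2_e < 0:
        raise ValueError("sigma2_e must be nonnegative")
    rng = np.random.default_rng(seed)
    lam = design.loading_matrix
    psi = cov.as_matrix()
    # eigh-based square root tolerates the semidefinite (zero-variance) cases
    vals, vecs = np.linalg.eigh(psi)
    if np.any(vals < -1e-10):
        raise ValueError("Psi must be positive semidefinite")
    sqrt_psi = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    b = fx.as_vector() + rng.standard_normal((n, 2)) @ sqrt_psi.T
    e = np.sqrt(sigma2_e) * rng.standard_normal((n, design.n_occasions))
    y = b @ lam.T + e
    return LongitudinalPanel(
        outcomes=y,
        occasion_codes=design.occasion_codes,
        true_effects=b,
        seed=seed,
    )


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def contaminate(panel: LongitudinalPanel, spec: OutlierSpec, seed: int) -> LongitudinalPanel:
    """Replace a fixed share of observations per occasion by extreme values.

    At every occasion, round(proportion * N) subjects are selected without
    replacement (independently across occasions).  Each selected cell is
    replaced by a draw from one of the spec's outlier components: normal
    with mean L_i + S_i * t_code + m_c * sigma_e and the clean error
    variance.  The returned panel's mask flags all replaced cells.
    """
    if spec.proportion == 0:
        return replace(panel, contamination_mask=np.zeros_like(panel.outcomes, dtype=bool))
    if panel.true_effects is None:
        raise ValueError("contaminate requires a panel with true_effects")
    n, t = panel.outcomes.shape
    n_replace = _round_half_even(spec.proportion * n)
    if n_replace < 1:
        warnings.warn("proportion * N < 1: no observations replaced", stacklevel=2)
        return replace(panel, contamination_mask=np.zeros_like(panel.outcomes, dtype=bool))

    rng = np.random.default_rng(seed)
    multipliers = spec.draw_multipliers(rng)
    sigma_e = np.sqrt(spec.component_variance)
    y = panel.outcomes.copy()
    mask = np.zeros((n, t), dtype=bool)
    intercepts = panel.true_effects[:, 0]
    slopes = panel.true_effects[:, 1]
    for j, code in enumerate(np.asarray(panel.occasion_codes, dtype=float)):
        rows = rng.choice(n, size=n_replace, replace=False)
        comp = rng.integers(0, spec.n_components, size=n_replace)
        mean = intercepts[rows] + slopes[rows] * code + multipliers[comp] * sigma_e
        y[rows, j] = mean + sigma_e * rng.standard_normal(n_replace)
        mask[rows, j] = True
    return replace(panel, outcomes=y, contamination_mask=mask)
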