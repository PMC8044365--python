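"""MCMC chain diagnostics: Geweke stationarity tests and HPD intervals.

The Geweke test compares the mean of an early segment of a chain (the
first 10% by default) with a late segment (the last 50%).  Under
stationarity the standardized difference is asymptotically standard
normal; a chain is flagged non-converged when |z| >= 1.96.  Segment
variances use the spectral density at frequency zero, estimated by
fitting an autoregressive process to each segment — the common default
in MCMC diagnostic software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GewekeResult",
    "HpdInterval",
    "geweke_z",
    "model_converged",
    "hpd_interval",
    "spectral_density_zero",
    "diagnose_draws",
    "DEFAULT_MONITOR",
]

# parameters whose chains enter the convergence decision by default: the
# label-invariant model summaries (component-level quantities are excluded
# as label-dependent)
DEFAULT_MONITOR = (
    "beta_L", "beta_S", "sigma2_L", "sigma2_S", "sigma_LS", "sigma2_e", "alpha", "K",
)

Z_BOUND = 1.96


@dataclass(frozen=True)
class GewekeResult:
    """Geweke z statistic for one monitored parameter."""

    parameter_name: str
    z_statistic: float
    first_fraction: float = 0.10
    last_fraction: float = 0.50

    @property
    def converged(self) -> bool:
        # |z| = 1.96 exactly counts as non-converged (strictly between the bounds)
        return abs(self.z_statistic) < Z_BOUND


@dataclass(frozen=True)
class HpdInterval:
    """Highest posterior density interval: the shortest interval holding ``mass``."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _ar_fit(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Yule-Walker AR(order) fit; returns (coefficients, innovation variance)."""
    n = len(x)
    xc = x - x.mean()
    acov = np.array([xc[: n - k] @ xc[k:] for k in range(order + 1)]) / n
    if order == 0:
        return np.empty(0), float(acov[0])
    r = acov[1 : order + 1]
    toeplitz = np.empty((order, order))
    for i in range(order):
        for j in range(order):
            toeplitz[i, j] = acov[abs(i - j)]
    try:
        rho = np.linalg.solve(toeplitz, r)
    except np.linalg.LinAlgError:
        return np.empty(0), float(acov[0])
    sigma2 = float(acov[0] - rho @ r)
    return rho, max(sigma2, 0.0)


def spectral_density_zero(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via an AIC-selected AR fit.

    s(0) = sigma2 / (1 - sum rho_k)^2 for an AR process with coefficients
    rho and innovation variance sigma2.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_order is None:
        max_order = min(int(10 * np.log10(n)), n - 2, 30)
    best_aic = np.inf
    best = (np.empty(0), float(np.var(x)))
    for order in range(max_order + 1):
        rho, sigma2 = _ar_fit(x, order)
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2.0 * order
        if aic < best_aic:
            best_aic = aic
            best = (rho, sigma2)
    rho, sigma2 = best
    denom = (1.0 - rho.sum()) ** 2 if rho.size else 1.0
    if denom <= 1e-12:
        denom = 1e-12
    return sigma2 / denom


def geweke_z(
    chain,
    first_fraction: float = 0.10,
    last_fraction: float = 0.50,
    parameter_name: str = "",
) -> GewekeResult:
    """Geweke stationarity statistic for one chain.

    z = (mean_first - mean_last) / sqrt(s0_first/n_first + s0_last/n_last)
    with s0 the AR-estimated spectral density at zero of each segment.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain must have at least 100 draws")
    if not (0 < first_fraction < 1 and 0 < last_fraction < 1):
        raise ValueError("fractions must lie in (0, 1)")
    if first_fraction + last_fraction > 1:
        raise ValueError("first and last segments must not overlap")
    n1 = int(np.floor(first_fraction * n))
    n2 = int(np.floor(last_fraction * n))
    first = x[:n1]
    last = x[n - n2 :]
    if np.ptp(first) == 0 or np.ptp(last) == 0:
        raise ValueError("degenerate chain: a segment has zero variance")
    s1 = spectral_density_zero(first)
    s2 = spectral_density_zero(last)
    se = np.sqrt(s1 / n1 + s2 / n2)
    if se == 0:
        raise ValueError("degenerate chain: zero spectral variance")
    z = (first.mean() - last.mean()) / se
    return GewekeResult(
        parameter_name=parameter_name,
        z_statistic=float(z),
        first_fraction=first_fraction,
        last_fraction=last_fraction,
    )


def model_converged(results) -> bool:
    """True iff every monitored parameter has |z| strictly below 1.96."""
    results = list(results)
    if not results:
        raise ValueError("model_converged requires at least one Geweke result")
    return all(r.converged for r in results)


def hpd_interval(draws, mass: float = 0.95) -> HpdInterval:
    """Shortest contiguous interval over sorted draws containing ceil(mass*n) draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 50:
        raise ValueError("hpd_interval requires at least 50 draws")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    if n - k < 1:
        raise ValueError("too few draws outside the target mass to locate an interval")
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HpdInterval(lower=float(x[i]), upper=float(x[i + k - 1]), mass=mass)


def diagnose_draws(
    draws,
    monitor=DEFAULT_MONITOR,
    first_fraction: float = 0.10,
    last_fraction: float = 0.50,
) -> list[GewekeResult]:
    """Geweke results for each monitored parameter of a PosteriorDraws object.

    A degenerate chain (a zero-variance segment, including a chain that is
    constant over the whole stored run) is reported with an infinite z
    statistic, i.e. counted as non-converged.  This matches the standard
    R diagnostic pipeline, where a constant chain yields z = NaN and NaN
    fails the |z| < 1.96 test: a chain frozen at one value cannot
    demonstrate stationary exploration of its posterior.
    """
    results = []
    for name in monitor:
        chain = np.asarray(draws[name], dtype=float)
        try:
            results.append(
                geweke_z(chain, first_fraction, last_fraction, parameter_name=name)
            )
        except ValueError:
            results.append(
                GewekeResult(
                    parameter_name=name,
                    z_statistic=float("inf"),
                    first_fraction=first_fraction,
                    last_fraction=last_fraction,
                )
            )
    return results
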