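"""Unconditional (random-predictor) power of the extended Welch slope test.

At the design stage the predictor values are themselves random; power must
therefore be averaged over their sampling distribution rather than computed
conditionally on observed covariates.  With normal predictors
X_ij ~ N(theta_i, tau_i^2), the centered predictor sum of squares satisfies
SSX_i / tau_i^2 ~ chi-square(n_i - 1), independently across groups.

Two analytic approximations are implemented:

* **Simplified t (ST)** — replace each random SSX_i by its expectation
  (n_i - 1) tau_i^2.  The test statistic is then approximately noncentral t
  with plug-in degrees of freedom nu* and noncentrality

      Delta* = beta1D / sqrt(sigma1^2/((n1-1)tau1^2) + sigma2^2/((n2-1)tau2^2)),

  giving a single noncentral-t tail evaluation.  The working effect size
  delta* = Delta* / (n1 + n2) is the dimensionless summary used to rank
  design configurations.

* **Mixed t (MT)** — retain the chi-square law of the predictor sums of
  squares: conditional on K_i = SSX_i / tau_i^2, the statistic is
  noncentral t with K-dependent noncentrality and Satterthwaite degrees of
  freedom; the unconditional power is the expectation over (K1, K2),
  evaluated here by deterministic tensor-product Gauss--Legendre quadrature
  on the probability scale.  MT is more accurate than ST in small samples,
  markedly so for large effects and unbalanced allocation.

Both constructions reduce exactly to the significance level when the slope
difference is zero, because the central-t critical value is applied to a
(then central) t variate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "PlanningConfig",
    "DesignSizes",
    "PowerResult",
    "MixingGrid",
    "expected_ncp",
    "effect_size_delta_star",
    "plugin_df",
    "power_simplified",
    "power_mixed",
    "power_mixed_mc",
    "QuadratureWarning",
]

MIN_GROUP_SIZE = 4  # planning floor: c_i >= 2 and chi-square mixing df >= 3


class QuadratureWarning(UserWarning):
    """Raised when doubling quadrature nodes moves the result noticeably."""


@dataclass(frozen=True)
class PlanningConfig:
    """Population parameters specifying a two-group interaction design.

    Parameters
    ----------
    beta11, beta12
        Population slopes of groups 1 and 2; their difference
        beta1d = beta11 - beta12 is the interaction effect under test.
    sigma2_1, sigma2_2
        Error variances (> 0).
    tau2_1, tau2_2
        Predictor variances (> 0).
    beta01, beta02, theta1, theta2
        Intercepts and predictor means.  Accepted for completeness but
        irrelevant to power: slope inference is invariant to location
        shifts of x and y.
    alpha
        Two-sided significance level.
    """

    beta11: float
    beta12: float
    sigma2_1: float
    sigma2_2: float
    tau2_1: float
    tau2_2: float
    beta01: float = 0.0
    beta02: float = 0.0
    theta1: float = 0.0
    theta2: float = 0.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sigma2_1", "sigma2_2", "tau2_1", "tau2_2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def beta1d(self) -> float:
        return self.beta11 - self.beta12

    def swapped(self) -> "PlanningConfig":
        """The same design with group labels exchanged."""
        return PlanningConfig(
            beta11=self.beta12,
            beta12=self.beta11,
            sigma2_1=self.sigma2_2,
            sigma2_2=self.sigma2_1,
            tau2_1=self.tau2_2,
            tau2_2=self.tau2_1,
            beta01=self.beta02,
            beta02=self.beta01,
            theta1=self.theta2,
            theta2=self.theta1,
            alpha=self.alpha,
        )


@dataclass(frozen=True)
class DesignSizes:
    """Group sample sizes (n1, n2) of a planned design."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < MIN_GROUP_SIZE or self.n2 < MIN_GROUP_SIZE:
            raise ValueError(
                f"group sizes must be >= {MIN_GROUP_SIZE} for planning, "
                f"got ({self.n1}, {self.n2})"
            )

    @property
    def n_t(self) -> int:
        return self.n1 + self.n2

    @property
    def r(self) -> Fraction:
        """Allocation ratio n2 / n1."""
        return Fraction(self.n2, self.n1)

    def swapped(self) -> "DesignSizes":
        return DesignSizes(self.n2, self.n1)


@dataclass(frozen=True)
class PowerResult:
    """Analytic power with its noncentrality and effect-size diagnostics."""

    method: str  # "ST" or "MT"
    power: float
    ncp: float
    delta_star: float
    nu_star: float
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MixingGrid:
    """Quadrature rule for the two chi-square mixing variables.

    K_i = SSX_i / tau_i^2 ~ chi-square(n_i - 1).  Nodes are Gauss--Legendre
    points on the probability scale u in (eps, 1 - eps), mapped through the
    chi-square quantile function; weights are renormalized to sum to one so
    the truncated tail mass (2 * eps per dimension) is redistributed.
    """

    n_nodes: int = 48
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("need at least 4 quadrature nodes per dimension")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")

    def nodes_weights(self, df: int) -> tuple[np.ndarray, np.ndarray]:
        """Chi-square(df) nodes and renormalized weights for one group."""
        x, w = np.polynomial.legendre.leggauss(self.n_nodes)
        u = self.eps + (1.0 - 2.0 * self.eps) * (x + 1.0) / 2.0
        nodes = stats.chi2.ppf(u, df)
        weights = w / w.sum()
        return nodes, weights

    def refined(self) -> "MixingGrid":
        return MixingGrid(n_nodes=2 * self.n_nodes, eps=self.eps)


def _plan_variance_terms(config: PlanningConfig, sizes: DesignSizes) -> tuple[float, float]:
    """a_i = sigma_i^2 / E[SSX_i] with E[SSX_i] = (n_i - 1) tau_i^2."""
    a1 = config.sigma2_1 / ((sizes.n1 - 1) * config.tau2_1)
    a2 = config.sigma2_2 / ((sizes.n2 - 1) * config.tau2_2)
    return a1, a2


def _satterthwaite(a1, a2, c1: int, c2: int):
    den = a1 + a2
    w1 = a1 / den
    w2 = a2 / den
    return 1.0 / (w1 * w1 / c1 + w2 * w2 / c2)


def _noncentral_two_sided(crit, nu, ncp):
    """P(|T'| > crit) for T' ~ noncentral t(nu, ncp).

    scipy's noncentral t can return NaN in a far tail at very large df,
    where the true mass is negligible; those entries fall back to the
    large-df normal limit T' -> N(ncp, 1).
    """
    crit_b, nu_b, ncp_b = np.broadcast_arrays(
        np.asarray(crit, float), np.asarray(nu, float), np.asarray(ncp, float)
    )
    hi = np.asarray(stats.nct.sf(crit_b, nu_b, ncp_b), float)
    lo = np.asarray(stats.nct.cdf(-crit_b, nu_b, ncp_b), float)
    bad = ~np.isfinite(hi)
    if bad.any():
        hi = np.where(bad, stats.norm.sf(crit_b - ncp_b), hi)
    bad = ~np.isfinite(lo)
    if bad.any():
        lo = np.where(bad, stats.norm.cdf(-crit_b - ncp_b), lo)
    out = hi + lo
    return float(out) if out.shape == () else out


def expected_ncp(config: PlanningConfig, sizes: DesignSizes) -> float:
    """Noncentrality Delta* at the expected predictor sums of squares."""
    a1, a2 = _plan_variance_terms(config, sizes)
    return config.beta1d / float(np.sqrt(a1 + a2))


def effect_size_delta_star(config: PlanningConfig, sizes: DesignSizes) -> float:
    """Working effect size delta* = Delta* / (n1 + n2), dimensionless."""
    return expected_ncp(config, sizes) / sizes.n_t


def plugin_df(config: PlanningConfig, sizes: DesignSizes) -> float:
    """Satterthwaite df evaluated at population variances and expected SSX."""
    a1, a2 = _plan_variance_terms(config, sizes)
    return float(_satterthwaite(a1, a2, sizes.n1 - 2, sizes.n2 - 2))


def power_simplified(config: PlanningConfig, sizes: DesignSizes) -> PowerResult:
    """Simplified-t power: one noncentral-t evaluation at plug-in df.

    Exact at the null (returns alpha when beta1d = 0); an approximation
    otherwise, degrading for small samples and unbalanced variance/size
    pairings.
    """
    ncp = expected_ncp(config, sizes)
    nu = plugin_df(config, sizes)
    crit = stats.t.ppf(1 - config.alpha / 2, nu)
    power = float(_noncentral_two_sided(crit, nu, ncp))
    return PowerResult(
        method="ST",
        power=power,
        ncp=ncp,
        delta_star=ncp / sizes.n_t,
        nu_star=nu,
    )


def _mixed_power_on_grid(
    config: PlanningConfig, sizes: DesignSizes, grid: MixingGrid
) -> float:
    k1, w1 = grid.nodes_weights(sizes.n1 - 1)
    k2, w2 = grid.nodes_weights(sizes.n2 - 1)
    a1 = (config.sigma2_1 / (config.tau2_1 * k1))[:, None]
    a2 = (config.sigma2_2 / (config.tau2_2 * k2))[None, :]
    den = a1 + a2
    ncp = config.beta1d / np.sqrt(den)
    nu = _satterthwaite(a1, a2, sizes.n1 - 2, sizes.n2 - 2)
    crit = stats.t.ppf(1 - config.alpha / 2, nu)
    cond = _noncentral_two_sided(crit, nu, ncp)
    return float(w1 @ cond @ w2)


def power_mixed(
    config: PlanningConfig,
    sizes: DesignSizes,
    grid: MixingGrid | None = None,
    *,
    check_convergence: bool = True,
    strict: bool = False,
    convergence_tol: float = 5e-5,
) -> PowerResult:
    """Mixed-t power: expectation of the conditional noncentral-t rejection
    probability over the chi-square laws of both predictor sums of squares.

    Conditional on K_i = SSX_i / tau_i^2, the variance terms are
    a_i(K) = sigma_i^2 / (tau_i^2 K_i), the noncentrality is
    beta1d / sqrt(a1 + a2) and the degrees of freedom follow the
    Satterthwaite weight formula.  The expectation uses the deterministic
    tensor-product rule of ``grid``.

    With ``check_convergence`` the integral is recomputed on a grid with
    doubled nodes; a discrepancy above ``convergence_tol`` raises (strict)
    or warns.
    """
    grid = grid or MixingGrid()
    power = _mixed_power_on_grid(config, sizes, grid)
    diagnostics = {"n_nodes": grid.n_nodes, "eps": grid.eps}
    if check_convergence:
        refined = _mixed_power_on_grid(config, sizes, grid.refined())
        diagnostics["refinement_delta"] = abs(refined - power)
        if abs(refined - power) > convergence_tol:
            msg = (
                f"mixed-t quadrature not converged: {grid.n_nodes} vs "
                f"{2 * grid.n_nodes} nodes differ by {abs(refined - power):.2e}"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, QuadratureWarning)
        power = refined
    ncp = expected_ncp(config, sizes)
    return PowerResult(
        method="MT",
        power=power,
        ncp=ncp,
        delta_star=ncp / sizes.n_t,
        nu_star=plugin_df(config, sizes),
        diagnostics=diagnostics,
    )


def power_mixed_mc(
    config: PlanningConfig,
    sizes: DesignSizes,
    reps: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte Carlo estimate of the mixed-t power (oracle for the quadrature).

    Draws (K1, K2) from their chi-square laws and averages the conditional
    rejection probability.  Returns the mean and its standard error.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 Monte Carlo draws")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k1 = rng.chisquare(sizes.n1 - 1, size=reps)
    k2 = rng.chisquare(sizes.n2 - 1, size=reps)
    a1 = config.sigma2_1 / (config.tau2_1 * k1)
    a2 = config.sigma2_2 / (config.tau2_2 * k2)
    den = a1 + a2
    ncp = config.beta1d / np.sqrt(den)
    nu = _satterthwaite(a1, a2, sizes.n1 - 2, sizes.n2 - 2)
    crit = stats.t.ppf(1 - config.alpha / 2, nu)
    cond = _noncentral_two_sided(crit, nu, ncp)
    est = float(cond.mean())
    se = float(cond.std(ddof=1) / np.sqrt(reps))
    return est, se
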