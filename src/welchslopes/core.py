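"""Extended Welch test for the difference between two regression slopes.

Two groups each follow a simple linear regression

    Y_ij = beta0_i + beta1_i * X_ij + e_ij,   e_ij ~ N(0, sigma_i^2),

with possibly unequal error variances sigma_1^2 != sigma_2^2.  Testing
H0: beta1_1 = beta1_2 (no treatment-by-covariate interaction) under
heteroscedasticity is a Behrens--Fisher problem for slopes.  The extended
Welch statistic standardizes the slope difference by per-group variance
estimates,

    T* = (b1 - b2) / sqrt(s1^2/SSX1 + s2^2/SSX2),

and refers it to a central t distribution whose degrees of freedom are a
Satterthwaite-type moment match of the denominator.  The classical pooled
test (pooled residual variance, N1 + N2 - 4 df) is provided for comparison;
it loses type-I control when error variances and group sizes are paired
unequally.

All inference consumes :class:`GroupSummary` sufficient statistics, so the
tests can be run either from raw data (via :func:`summarize_group`) or from
published per-group summaries alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "GroupSummary",
    "WelchTestResult",
    "summarize_group",
    "welch_statistic",
    "welch_df",
    "welch_test",
    "pooled_slope_test",
    "read_two_group_csv",
]


@dataclass(frozen=True)
class GroupSample:
    """Raw observations for one group.

    Parameters
    ----------
    label
        Group identifier (1 or 2).
    x, y
        Predictor and response vectors of equal length >= 3; the predictor
        must take at least two distinct values so that its centered sum of
        squares is positive.
    """

    label: int
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-d vectors of equal length")
        if x.size < 3:
            raise ValueError(
                f"group {self.label}: need at least 3 observations for a "
                f"residual degree of freedom, got {x.size}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError(f"group {self.label}: non-finite values in data")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group's simple linear regression.

    Attributes
    ----------
    n
        Group sample size (>= 3).
    slope_hat, intercept_hat
        Ordinary least-squares estimates.
    ssx
        Centered predictor sum of squares, sum (x - xbar)^2.
    sse
        Residual sum of squares.
    sigma2_hat
        Unbiased error-variance estimate sse / (n - 2).
    xbar
        Predictor sample mean.
    """

    n: int
    slope_hat: float
    intercept_hat: float
    ssx: float
    sse: float
    sigma2_hat: float
    xbar: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")
        if not self.ssx > 0:
            raise ValueError("ssx must be strictly positive")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")
        if not np.isclose(self.sigma2_hat * self.c, self.sse, rtol=1e-8, atol=1e-10):
            raise ValueError("sigma2_hat * (n - 2) must equal sse")

    @property
    def c(self) -> int:
        """Residual degrees of freedom, n - 2."""
        return self.n - 2

    @classmethod
    def from_moments(
        cls,
        n: int,
        slope_hat: float,
        sigma2_hat: float,
        *,
        ssx: float | None = None,
        tau2_hat: float | None = None,
        intercept_hat: float = 0.0,
        xbar: float = 0.0,
    ) -> "GroupSummary":
        """Build a summary from published per-group statistics.

        Exactly one of ``ssx`` or ``tau2_hat`` must be given; a predictor
        sample variance ``tau2_hat`` is converted as ssx = (n - 1) * tau2_hat.
        """
        if (ssx is None) == (tau2_hat is None):
            raise ValueError("give exactly one of ssx or tau2_hat")
        if ssx is None:
            ssx = (n - 1) * float(tau2_hat)
        return cls(
            n=int(n),
            slope_hat=float(slope_hat),
            intercept_hat=float(intercept_hat),
            ssx=float(ssx),
            sse=float(sigma2_hat) * (int(n) - 2),
            sigma2_hat=float(sigma2_hat),
            xbar=float(xbar),
        )


@dataclass(frozen=True)
class WelchTestResult:
    """Outcome of a two-sided slope-difference test."""

    slope_diff_hat: float
    se: float
    t_star: float
    nu_hat: float
    alpha: float
    crit: float
    p_value: float
    reject: bool
    method: str = "welch"


def summarize_group(sample: GroupSample) -> GroupSummary:
    """Reduce raw observations to regression sufficient statistics.

    Raises
    ------
    ValueError
        If all predictor values coincide (SSX = 0, slope not estimable).
    """
    x, y = sample.x, sample.y
    xbar = float(x.mean())
    ybar = float(y.mean())
    dx = x - xbar
    ssx = float(dx @ dx)
    if ssx <= 0 or not np.isfinite(1.0 / ssx):
        raise ValueError(
            f"group {sample.label}: predictor is constant (SSX = 0); "
            "slope is not estimable"
        )
    sxy = float(dx @ (y - ybar))
    slope = sxy / ssx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sse = float(resid @ resid)
    return GroupSummary(
        n=sample.n,
        slope_hat=slope,
        intercept_hat=intercept,
        ssx=ssx,
        sse=sse,
        sigma2_hat=sse / (sample.n - 2),
        xbar=xbar,
    )


def welch_statistic(s1: GroupSummary, s2: GroupSummary) -> tuple[float, float, float]:
    """Slope difference, its heteroscedastic standard error, and T*."""
    a1 = s1.sigma2_hat / s1.ssx
    a2 = s2.sigma2_hat / s2.ssx
    if a1 + a2 <= 0:
        raise ValueError("zero standard error: both variance terms vanish")
    diff = s1.slope_hat - s2.slope_hat
    se = float(np.sqrt(a1 + a2))
    return diff, se, diff / se


def welch_df(s1: GroupSummary, s2: GroupSummary) -> float:
    """Satterthwaite approximate degrees of freedom for T*.

    With a_i = sigma_i_hat^2 / SSX_i and weights w_i = a_i / (a1 + a2),

        1 / nu_hat = w1^2 / c1 + w2^2 / c2,   c_i = n_i - 2.

    nu_hat always lies in [min(c1, c2), c1 + c2].
    """
    a1 = s1.sigma2_hat / s1.ssx
    a2 = s2.sigma2_hat / s2.ssx
    if a1 + a2 <= 0:
        raise ValueError("degrees of freedom undefined: a1 + a2 = 0")
    w1 = a1 / (a1 + a2)
    w2 = a2 / (a1 + a2)
    return 1.0 / (w1 * w1 / s1.c + w2 * w2 / s2.c)


def welch_test(s1: GroupSummary, s2: GroupSummary, alpha: float = 0.05) -> WelchTestResult:
    """Two-sided extended Welch test of equal slopes at level ``alpha``.

    The boundary case |T*| = critical value is treated as non-rejection.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    diff, se, t_star = welch_statistic(s1, s2)
    nu = welch_df(s1, s2)
    crit = float(stats.t.ppf(1 - alpha / 2, nu))
    p = float(2 * stats.t.sf(abs(t_star), nu))
    return WelchTestResult(
        slope_diff_hat=diff,
        se=se,
        t_star=t_star,
        nu_hat=nu,
        alpha=alpha,
        crit=crit,
        p_value=p,
        reject=bool(abs(t_star) > crit),
        method="welch",
    )


def pooled_slope_test(
    s1: GroupSummary, s2: GroupSummary, alpha: float = 0.05
) -> WelchTestResult:
    """Classical equal-variance slope comparison (pooled residual variance).

    Pools Sp^2 = (SSE1 + SSE2) / (n1 + n2 - 4) and uses fixed df n1 + n2 - 4.
    Valid only under homogeneous error variance; kept for comparison with
    the heteroscedasticity-robust test.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = s1.n + s2.n - 4
    if df < 1:
        raise ValueError("pooled test needs n1 + n2 > 4")
    sp2 = (s1.sse + s2.sse) / df
    diff = s1.slope_hat - s2.slope_hat
    se = float(np.sqrt(sp2 * (1.0 / s1.ssx + 1.0 / s2.ssx)))
    if se <= 0:
        raise ValueError("zero pooled standard error")
    t_stat = diff / se
    crit = float(stats.t.ppf(1 - alpha / 2, df))
    p = float(2 * stats.t.sf(abs(t_stat), df))
    return WelchTestResult(
        slope_diff_hat=diff,
        se=se,
        t_star=t_stat,
        nu_hat=float(df),
        alpha=alpha,
        crit=crit,
        p_value=p,
        reject=bool(abs(t_stat) > crit),
        method="pooled",
    )


def read_two_group_csv(path) -> tuple[GroupSample, GroupSample]:
    """Read raw two-group data from a CSV with header ``group,x,y``.

    ``group`` must be 1 or 2; x and y must be finite numbers.  Malformed
    cells are reported with their 1-based file line numbers (header is
    line 1).
    """
    df = pd.read_csv(path)
    expected = ["group", "x", "y"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected header 'group,x,y', got {','.join(map(str, df.columns))}"
        )
    bad_lines: list[int] = []
    for col in expected:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((df.index[coerced.isna()] + 2).tolist())
        df[col] = coerced
    if bad_lines:
        lines = ", ".join(str(i) for i in sorted(set(bad_lines)))
        raise ValueError(f"{path}: non-numeric or missing values at line(s) {lines}")
    bad_group = df.index[~df["group"].isin([1, 2])] + 2
    if len(bad_group):
        lines = ", ".join(str(i) for i in bad_group.tolist())
        raise ValueError(f"{path}: group must be 1 or 2 at line(s) {lines}")
    samples = []
    for label in (1, 2):
        sub = df[df["group"] == label]
        if sub.empty:
            raise ValueError(f"{path}: no rows for group {label}")
        samples.append(
            GroupSample(label=label, x=sub["x"].to_numpy(), y=sub["y"].to_numpy())
        )
    return samples[0], samples[1]
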