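"""Minimal sample sizes attaining nominal power at a fixed allocation ratio.

Given planning values (slopes, error variances, predictor variances), a
significance level, an allocation ratio r = n2/n1 and a nominal power, the
solver returns the smallest n1 (with n2 = ceil(r * n1)) whose design reaches
the target power under the chosen analytic method (simplified t or mixed t).

The search seeds n1 from the normal-approximation identity
Delta* = z_{alpha/2} + z_{beta}, then walks down to the first failure and up
to the first success; since power is monotone in n1 at fixed ratio this is
equivalent to an exhaustive scan from the floor but far cheaper for large
designs.  Power evaluations are cached per n1, and the visited (n1, power)
pairs are recorded in the result trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from scipy import stats

from .power import (
    MIN_GROUP_SIZE,
    DesignSizes,
    MixingGrid,
    PlanningConfig,
    power_mixed,
    power_simplified,
)

__all__ = ["SampleSizeRequest", "SampleSizeResult", "solve_sample_size"]


@dataclass(frozen=True)
class SampleSizeRequest:
    config: PlanningConfig
    target_power: float
    ratio: float | Fraction = 1
    method: str = "MT"
    n1_floor: int = MIN_GROUP_SIZE
    n1_cap: int = 100_000

    def __post_init__(self) -> None:
        if not self.config.alpha < self.target_power < 1:
            raise ValueError(
                f"target power must lie in (alpha, 1) = "
                f"({self.config.alpha}, 1), got {self.target_power}"
            )
        if self.method not in ("ST", "MT"):
            raise ValueError(f"method must be 'ST' or 'MT', got {self.method!r}")
        if not self.ratio > 0:
            raise ValueError("allocation ratio must be positive")
        if self.n1_floor < MIN_GROUP_SIZE:
            raise ValueError(f"n1_floor must be >= {MIN_GROUP_SIZE}")


@dataclass(frozen=True)
class SampleSizeResult:
    n1: int
    n2: int
    n_t: int
    achieved_power: float
    method: str
    trace: tuple = field(default_factory=tuple)


def _n2_for(n1: int, ratio) -> int:
    # ceil of r*n1 via exact Fraction arithmetic to dodge float-ratio edge cases
    return max(int(math.ceil(Fraction(ratio).limit_denominator(10**6) * n1)), MIN_GROUP_SIZE)


def _seed_n1(request: SampleSizeRequest) -> int:
    """Normal-approximation starting point for the search."""
    cfg = request.config
    beta1d = abs(cfg.beta1d)
    z = stats.norm.ppf(1 - cfg.alpha / 2) + stats.norm.ppf(request.target_power)
    r = float(request.ratio)
    # Delta* ~ beta1d * sqrt(n1) / sqrt(s1/t1 + s2/(r t2)); solve for n1
    scale = cfg.sigma2_1 / cfg.tau2_1 + cfg.sigma2_2 / (r * cfg.tau2_2)
    n1 = 1 + scale * (z / beta1d) ** 2
    return min(max(int(round(n1)), request.n1_floor), request.n1_cap)


def solve_sample_size(request: SampleSizeRequest) -> SampleSizeResult:
    """Smallest n1 (n2 = ceil(ratio * n1)) reaching the target power.

    Raises
    ------
    ValueError
        If the slope difference is zero (power cannot exceed alpha) or the
        search ceiling is exceeded.
    """
    cfg = request.config
    if cfg.beta1d == 0:
        raise ValueError(
            "slope difference is zero: power equals alpha for every sample "
            "size, target power is unattainable"
        )
    grid = MixingGrid()
    cache: dict[int, float] = {}

    def power_at(n1: int) -> float:
        if n1 not in cache:
            sizes = DesignSizes(n1, _n2_for(n1, request.ratio))
            if request.method == "ST":
                cache[n1] = power_simplified(cfg, sizes).power
            else:
                cache[n1] = power_mixed(cfg, sizes, grid, check_convergence=False).power
        return cache[n1]

    n1 = _seed_n1(request)
    if power_at(n1) >= request.target_power:
        while n1 > request.n1_floor and power_at(n1 - 1) >= request.target_power:
            n1 -= 1
    else:
        while power_at(n1) < request.target_power:
            n1 += 1
            if n1 > request.n1_cap:
                raise ValueError(
                    f"sample-size search exceeded the ceiling n1 = {request.n1_cap} "
                    "without reaching the target power"
                )

    trace = tuple(sorted(cache.items()))
    for (na, pa), (nb, pb) in zip(trace, trace[1:]):
        if nb == na + 1 and pb < pa - 1e-9:
            warnings.warn(
                f"power decreased from n1={na} ({pa:.6f}) to n1={nb} ({pb:.6f}); "
                "search assumes monotonicity",
                RuntimeWarning,
            )
    return SampleSizeResult(
        n1=n1,
        n2=_n2_for(n1, request.ratio),
        n_t=n1 + _n2_for(n1, request.ratio),
        achieved_power=power_at(n1),
        method=request.method,
        trace=trace,
    )
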