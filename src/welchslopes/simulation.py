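"""Monte Carlo validation of the analytic power approximations.

Each replicate draws normal predictors x_ij ~ N(theta_i, tau_i^2), builds
responses y = beta0_i + beta1_i x + N(0, sigma_i^2), fits the two
regressions, and applies the selected slope-equality test.  The empirical
rejection rate over many replicates estimates the true (unconditional)
power, against which the simplified-t and mixed-t analytic values are
compared.  Regenerating a full design table evaluates, for each variance
pattern, the minimal sample sizes of both methods, their analytic powers
and the simulated powers.

All replicates are fitted in vectorized form; a run is reproducible
bit-for-bit from its seed, and table cells use independent child streams
spawned deterministically from the table seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .power import DesignSizes, MixingGrid, PlanningConfig, power_mixed, power_simplified
from .samplesize import SampleSizeRequest, solve_sample_size

__all__ = [
    "SimScenario",
    "SimResult",
    "TableSpec",
    "TableRow",
    "simulate_rejection_rate",
    "simulate_type1",
    "reproduce_table",
    "table_to_dataframe",
    "VARIANCE_CASES",
]

# the 15 variance patterns crossed in each design table:
# tau^2 patterns x sigma^2 patterns
TAU_PATTERNS = [(1.0, 1.0), (1.0, 4.0), (4.0, 1.0)]
SIGMA_PATTERNS = [(1.0, 1.0), (1.0, 2.0), (1.0, 4.0), (2.0, 1.0), (4.0, 1.0)]
VARIANCE_CASES = [(t, s) for t in TAU_PATTERNS for s in SIGMA_PATTERNS]


@dataclass(frozen=True)
class SimScenario:
    """One Monte Carlo condition: population, sizes, replicate count, test."""

    config: PlanningConfig
    sizes: DesignSizes
    reps: int = 10_000
    seed: int | None = None
    test: str = "welch"

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("reps must be >= 100")
        if self.test not in ("welch", "pooled"):
            raise ValueError(f"test must be 'welch' or 'pooled', got {self.test!r}")


@dataclass(frozen=True)
class SimResult:
    rejection_rate: float
    mc_se: float
    reps: int
    analytic_st: float
    analytic_mt: float
    error_st: float  # analytic - empirical
    error_mt: float
    n_redraws: int = 0


@dataclass(frozen=True)
class TableSpec:
    """A design table: slope difference and allocation ratio crossed with
    the 15 variance patterns at alpha and nominal power."""

    beta1d: float
    ratio: float
    alpha: float = 0.05
    target_power: float = 0.80


@dataclass(frozen=True)
class TableRow:
    case: int
    tau2: tuple
    sigma2: tuple
    delta_star: float
    st: dict = field(default_factory=dict)
    mt: dict = field(default_factory=dict)


def _fit_slopes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise OLS: slope, SSX, SSE for (reps, n) arrays."""
    dx = x - x.mean(axis=1, keepdims=True)
    dy = y - y.mean(axis=1, keepdims=True)
    ssx = np.einsum("ij,ij->i", dx, dx)
    sxy = np.einsum("ij,ij->i", dx, dy)
    slope = sxy / ssx
    sse = np.einsum("ij,ij->i", dy, dy) - slope * sxy
    return slope, ssx, np.maximum(sse, 0.0)


def _draw_group(rng, reps, n, theta, tau2, beta0, beta1, sigma2):
    x = rng.normal(theta, np.sqrt(tau2), size=(reps, n))
    y = beta0 + beta1 * x + rng.normal(0.0, np.sqrt(sigma2), size=(reps, n))
    return x, y


def simulate_rejection_rate(scenario: SimScenario) -> SimResult:
    """Empirical rejection rate of the chosen test over the replicates.

    Replicates whose predictor draw is numerically degenerate (SSX ~ 0,
    probability zero for continuous normals) are redrawn and counted.
    """
    cfg, sizes = scenario.config, scenario.sizes
    rng = np.random.default_rng(scenario.seed)
    reps = scenario.reps

    x1, y1 = _draw_group(rng, reps, sizes.n1, cfg.theta1, cfg.tau2_1,
                         cfg.beta01, cfg.beta11, cfg.sigma2_1)
    x2, y2 = _draw_group(rng, reps, sizes.n2, cfg.theta2, cfg.tau2_2,
                         cfg.beta02, cfg.beta12, cfg.sigma2_2)

    n_redraws = 0
    for _ in range(100):
        b1, ssx1, sse1 = _fit_slopes(x1, y1)
        b2, ssx2, sse2 = _fit_slopes(x2, y2)
        tiny = np.finfo(float).tiny
        bad = (ssx1 <= tiny * sizes.n1) | (ssx2 <= tiny * sizes.n2)
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        idx = np.flatnonzero(bad)
        x1[idx], y1[idx] = _draw_group(rng, idx.size, sizes.n1, cfg.theta1,
                                       cfg.tau2_1, cfg.beta01, cfg.beta11, cfg.sigma2_1)
        x2[idx], y2[idx] = _draw_group(rng, idx.size, sizes.n2, cfg.theta2,
                                       cfg.tau2_2, cfg.beta02, cfg.beta12, cfg.sigma2_2)
    else:  # pragma: no cover - pathological RNG state
        raise RuntimeError("persistent degenerate predictor draws")

    c1, c2 = sizes.n1 - 2, sizes.n2 - 2
    diff = b1 - b2
    if scenario.test == "welch":
        a1 = (sse1 / c1) / ssx1
        a2 = (sse2 / c2) / ssx2
        t_stat = diff / np.sqrt(a1 + a2)
        w1 = a1 / (a1 + a2)
        nu = 1.0 / (w1 * w1 / c1 + (1 - w1) ** 2 / c2)
        crit = stats.t.ppf(1 - cfg.alpha / 2, nu)
    else:
        sp2 = (sse1 + sse2) / (c1 + c2)
        t_stat = diff / np.sqrt(sp2 * (1.0 / ssx1 + 1.0 / ssx2))
        crit = stats.t.ppf(1 - cfg.alpha / 2, c1 + c2)

    rate = float(np.mean(np.abs(t_stat) > crit))
    mc_se = float(np.sqrt(rate * (1 - rate) / reps))
    st = power_simplified(cfg, sizes).power
    mt = power_mixed(cfg, sizes, check_convergence=False).power
    return SimResult(
        rejection_rate=rate,
        mc_se=mc_se,
        reps=reps,
        analytic_st=st,
        analytic_mt=mt,
        error_st=st - rate,
        error_mt=mt - rate,
        n_redraws=n_redraws,
    )


def simulate_type1(
    config: PlanningConfig,
    sizes: DesignSizes,
    reps: int = 10_000,
    seed: int | None = None,
    test: str = "welch",
) -> SimResult:
    """Empirical type-I error under the forced null beta11 = beta12 = 0.

    Raises if the supplied configuration carries a non-null slope
    difference, to prevent silently mislabelling a power run.
    """
    if config.beta1d != 0:
        raise ValueError(
            "type-I simulation requires beta11 = beta12; got slope "
            f"difference {config.beta1d}"
        )
    null_cfg = replace(config, beta11=0.0, beta12=0.0)
    return simulate_rejection_rate(
        SimScenario(config=null_cfg, sizes=sizes, reps=reps, seed=seed, test=test)
    )


def reproduce_table(
    spec: TableSpec,
    reps: int = 10_000,
    seed: int | None = None,
    cases: list[int] | None = None,
    progress=None,
) -> list[TableRow]:
    """Regenerate one design table: sizes, analytic and simulated power.

    For each variance case, both methods' minimal sample sizes are solved at
    the nominal power, the analytic power is evaluated at its own sizes, and
    the empirical power is estimated with ``reps`` replicates.  ``cases``
    restricts to a 1-based subset; ``progress`` is an optional callable
    receiving status strings.
    """
    wanted = set(cases) if cases is not None else set(range(1, 16))
    children = np.random.SeedSequence(seed).spawn(2 * len(VARIANCE_CASES))
    grid = MixingGrid()
    rows: list[TableRow] = []
    for i, (tau2, sigma2) in enumerate(VARIANCE_CASES, start=1):
        if i not in wanted:
            continue
        cfg = PlanningConfig(
            beta11=spec.beta1d, beta12=0.0,
            sigma2_1=sigma2[0], sigma2_2=sigma2[1],
            tau2_1=tau2[0], tau2_2=tau2[1],
            alpha=spec.alpha,
        )
        per_method = {}
        for j, method in enumerate(("ST", "MT")):
            res = solve_sample_size(SampleSizeRequest(
                config=cfg, target_power=spec.target_power,
                ratio=spec.ratio, method=method,
            ))
            sizes = DesignSizes(res.n1, res.n2)
            estimated = (power_simplified(cfg, sizes).power if method == "ST"
                         else power_mixed(cfg, sizes, grid, check_convergence=False).power)
            child_seed = children[2 * (i - 1) + j]
            sim = simulate_rejection_rate(SimScenario(
                config=cfg, sizes=sizes, reps=reps,
                seed=int(child_seed.generate_state(1)[0] % (2**31)),
            ))
            per_method[method] = {
                "n1": res.n1, "n2": res.n2, "n_t": res.n_t,
                "estimated": estimated,
                "simulated": sim.rejection_rate,
                "error": estimated - sim.rejection_rate,
                "mc_se": sim.mc_se,
            }
            if progress is not None:
                progress(f"case {i} {method}: n=({res.n1},{res.n2}) "
                         f"est={estimated:.4f} sim={sim.rejection_rate:.4f}")
        st_sizes = DesignSizes(per_method["ST"]["n1"], per_method["ST"]["n2"])
        rows.append(TableRow(
            case=i, tau2=tau2, sigma2=sigma2,
            # delta* is tabulated at the simplified-method sizes
            delta_star=power_simplified(cfg, st_sizes).delta_star,
            st=per_method["ST"], mt=per_method["MT"],
        ))
    return rows


def table_to_dataframe(rows: list[TableRow]) -> pd.DataFrame:
    """Flatten table rows to the published column order (ST block, MT block)."""
    records = []
    for row in rows:
        rec = {
            "case": row.case,
            "tau2_1": row.tau2[0], "tau2_2": row.tau2[1],
            "sigma2_1": row.sigma2[0], "sigma2_2": row.sigma2[1],
            "delta_star": row.delta_star,
        }
        for tag, block in (("st", row.st), ("mt", row.mt)):
            for key in ("n1", "n2", "n_t", "estimated", "simulated", "error"):
                rec[f"{tag}_{key}"] = block[key]
        records.append(rec)
    return pd.DataFrame.from_records(records)
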