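"""Bundled worked-example summary statistics.

The ``bishop_mice`` fixture carries the per-group regression summaries of a
classic organ-weight study in crossbred diabetic (group 1, n=9) and normal
(group 2, n=25) mice, with body weight (grams) predicting kidney weight.
Only the published summary statistics are available — sample sizes, slope
estimates, error-variance estimates, predictor means and predictor sample
variances — so the fixture is expressed in summary form and the predictor
sum of squares is reconstructed as SSX_i = (n_i - 1) * tau2_hat_i from the
printed predictor variances (which are defined with the n-1 divisor).
"""

from __future__ import annotations

from .core import GroupSummary
from .power import PlanningConfig

__all__ = ["BISHOP_MICE", "FIXTURES", "mice_summaries", "mice_planning_config"]

BISHOP_MICE = {
    "n1": 9,
    "n2": 25,
    "beta11": 15.9286,
    "beta12": 3.8398,
    "sigsq1": 10124.8980,
    "sigsq2": 9097.9625,
    "tausq1": 31.1111,
    "tausq2": 23.8600,
    "xbar1": 42.8889,
    "xbar2": 33.8800,
}

FIXTURES = {"bishop_mice": BISHOP_MICE}


def mice_summaries() -> tuple[GroupSummary, GroupSummary]:
    """The two group summaries of the diabetic-mice example."""
    f = BISHOP_MICE
    s1 = GroupSummary.from_moments(
        f["n1"], f["beta11"], f["sigsq1"], tau2_hat=f["tausq1"], xbar=f["xbar1"]
    )
    s2 = GroupSummary.from_moments(
        f["n2"], f["beta12"], f["sigsq2"], tau2_hat=f["tausq2"], xbar=f["xbar2"]
    )
    return s1, s2


def mice_planning_config(alpha: float = 0.05) -> PlanningConfig:
    """Planning values for future mice interaction studies, taken from the
    example's estimates (slopes, error variances, predictor variances)."""
    f = BISHOP_MICE
    return PlanningConfig(
        beta11=f["beta11"],
        beta12=f["beta12"],
        sigma2_1=f["sigsq1"],
        sigma2_2=f["sigsq2"],
        tau2_1=f["tausq1"],
        tau2_2=f["tausq2"],
        theta1=f["xbar1"],
        theta2=f["xbar2"],
        alpha=alpha,
    )
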