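"""Two-proportion power calculations behind the effect-size screen.

The burden screen flags carrier-proportion differences exceeding 0.35.
This module quantifies the power of the two-sided test of equal carrier
proportions at that effect size for the observed group sizes, using the
pooled-variance normal approximation:

    power = Phi((|d| - z * se0) / se1) + Phi((-|d| - z * se0) / se1)

with z the upper alpha/2 normal quantile, se0 the pooled null standard
error and se1 the unpooled alternative standard error.  At d = 0 the
power equals alpha (the size of the test equals its level).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-proportion power calculation."""

    n1: int
    n2: int
    p_without: float
    delta: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha out of (0,1): {self.alpha}")
        p1 = self.p_without + self.delta
        if not (0.0 <= self.p_without <= 1.0) or not (0.0 <= p1 <= 1.0):
            raise ValueError(
                f"infeasible proportions: baseline {self.p_without}, shifted {p1}")


def power_two_proportion(n1: int, n2: int, p_without: float, delta: float,
                         alpha: float = 0.05) -> float:
    """Power of the two-sided level-alpha test of p1 = p2 at p1 = p_without + delta."""
    spec = PowerSpec(n1=n1, n2=n2, p_without=p_without, delta=delta, alpha=alpha)
    p2 = spec.p_without
    p1 = p2 + spec.delta
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    se1 = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if se1 == 0.0:
        return 1.0 if abs(delta) > z * se0 else 0.0
    d = abs(spec.delta)
    upper = stats.norm.cdf((d - z * se0) / se1)
    lower = stats.norm.cdf((-d - z * se0) / se1)
    return float(min(1.0, upper + lower))
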