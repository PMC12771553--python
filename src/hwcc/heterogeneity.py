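"""Between-estimate heterogeneity tests with Bonferroni adjustment.

Two effect estimates E1 and E2 (percent change per degree C, with standard
errors SE1 and SE2 on the same scale) are compared through their difference
d = E1 - E2, whose standard error is SE_d = sqrt(SE1^2 + SE2^2); z = d / SE_d
gives a two-sided normal p-value. Comparisons are made on the percent-change
scale, the scale on which stratified results are reported. When several
subgroup levels are compared against a reference, the p-values are Bonferroni
adjusted by the family size m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimator import Z95, EffectEstimate


@dataclass
class HeterogeneityResult:
    label_1: str
    label_2: str
    d: float            # percentage-point difference E1 - E2
    se_d: float
    z: float
    p_value: float
    ci95: tuple[float, float]

    def bonferroni(self, m: int) -> float:
        return bonferroni_adjust([self.p_value], m)[0]


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Recover a Wald SE from a symmetric 95% CI: (high - low) / (2 x 1.96)."""
    if not ci_high > ci_low:
        raise ValueError("degenerate CI: upper bound must exceed lower bound")
    return (ci_high - ci_low) / (2.0 * 1.96)


def estimate_from_ci(
    percent: float, ci_low: float, ci_high: float, label: str = ""
) -> EffectEstimate:
    """Build an EffectEstimate from a published percent change and 95% CI."""
    se_pc = se_from_ci(ci_low, ci_high)
    beta = math.log1p(percent / 100.0)
    se_beta = se_pc / 100.0 / math.exp(beta)  # inverse delta method
    z = percent / se_pc
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(label, beta, se_beta, percent, se_pc, (ci_low, ci_high), p)


def compare_estimates(
    e1: EffectEstimate, e2: EffectEstimate
) -> HeterogeneityResult:
    """z-test on the difference of two percent-change estimates."""
    d = e1.percent_change - e2.percent_change
    se_d = math.sqrt(e1.se_percent**2 + e2.se_percent**2)
    if se_d <= 0:
        raise ValueError("both estimates have zero SE; nothing to test")
    z = d / se_d
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (d - Z95 * se_d, d + Z95 * se_d)
    return HeterogeneityResult(e1.label, e2.label, d, se_d, z, p, ci)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Multiply each p by the family size m (default len(p_values)), cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return list(np.minimum(1.0, m * p))
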