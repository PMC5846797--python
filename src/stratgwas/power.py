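"""Analytic power for detecting a cross-stratum effect difference.

For a biallelic variant with effect allele frequency ``eaf`` under
Hardy-Weinberg equilibrium, the large-sample variance of a case-control
log-odds-ratio estimate in a stratum with ``n_case`` cases and ``n_ctrl``
controls is approximately

    se^2 = (1/n_case + 1/n_ctrl) / (2 * eaf * (1 - eaf)).

The difference Z-test then has noncentrality

    ncp = (ln OR_A - ln OR_B) / sqrt(se_A^2 + se_B^2 - 2 r se_A se_B)

and two-sided power at level alpha

    power = Phi(-z_{alpha/2} + |ncp|) + Phi(-z_{alpha/2} - |ncp|),

which reduces to alpha itself when the stratum odds ratios coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

__all__ = ["PowerScenario", "stratum_se", "power_diff"]


@dataclass(frozen=True)
class PowerScenario:
    """Design and effect sizes for a cross-stratum difference power question.

    Attributes
    ----------
    n_cases_a, n_controls_a, n_cases_b, n_controls_b : stratum sample sizes.
    or_a, or_b : per-stratum odds ratios for the effect allele.
    eaf : effect allele frequency in (0, 1).
    alpha : two-sided significance level.
    r : cross-stratum correlation of the effect estimates.
    """

    n_cases_a: int
    n_controls_a: int
    n_cases_b: int
    n_controls_b: int
    or_a: float
    or_b: float
    eaf: float = 0.3
    alpha: float = 5e-8
    r: float = 0.03

    def __post_init__(self) -> None:
        for n in (self.n_cases_a, self.n_controls_a, self.n_cases_b, self.n_controls_b):
            if n <= 0:
                raise ValueError("sample counts must be positive")
        if not 0 < self.eaf < 1:
            raise ValueError("eaf must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.or_a <= 0 or self.or_b <= 0:
            raise ValueError("odds ratios must be positive")


def stratum_se(n_cases: int, n_controls: int, eaf: float) -> float:
    """Approximate se of a stratum log-OR under HWE allele counting."""
    return math.sqrt((1.0 / n_cases + 1.0 / n_controls) / (2.0 * eaf * (1.0 - eaf)))


def power_diff(scenario: PowerScenario) -> float:
    """Two-sided power of the difference Z-test for the given scenario."""
    s = scenario
    se_a = stratum_se(s.n_cases_a, s.n_controls_a, s.eaf)
    se_b = stratum_se(s.n_cases_b, s.n_controls_b, s.eaf)
    var = se_a**2 + se_b**2 - 2.0 * s.r * se_a * se_b
    if var <= 0:
        raise ValueError(f"r={s.r} yields a non-positive difference variance")
    ncp = abs(math.log(s.or_a) - math.log(s.or_b)) / math.sqrt(var)
    z_crit = -ndtri(s.alpha / 2.0)
    return float(ndtr(-z_crit + ncp) + ndtr(-z_crit - ncp))
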