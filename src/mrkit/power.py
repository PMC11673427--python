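"""Statistical power for two-sample MR with a binary outcome.

The Wald test of the causal log odds ratio b = ln(OR) per SD of exposure
has, to normal-approximation accuracy, non-centrality

    nu = b * sqrt(N * R2 * K * (1 - K))

where N is the outcome study's total sample size, K its case fraction
and R2 the proportion of exposure variance explained by the instruments.
Two-sided power at level alpha is then

    power = Phi(nu - z_{1-alpha/2}) + Phi(-nu - z_{1-alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerInput", "mr_power_binary"]


@dataclass
class PowerInput:
    n_outcome: float
    case_fraction: float
    or_hypothesis: float
    r2_xz: float
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 < self.r2_xz < 1:
            raise ValueError("r2_xz must be in (0, 1)")
        if not self.or_hypothesis > 0:
            raise ValueError("or_hypothesis must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.n_outcome > 0:
            raise ValueError("n_outcome must be positive")


def mr_power_binary(p: PowerInput) -> float:
    """Analytic power in [0, 1] for the two-sample MR Wald test."""
    p.validate()
    b = math.log(p.or_hypothesis)
    nu = b * math.sqrt(p.n_outcome * p.r2_xz * p.case_fraction * (1 - p.case_fraction))
    z = stats.norm.ppf(1 - p.alpha / 2)
    return float(stats.norm.cdf(nu - z) + stats.norm.cdf(-nu - z))
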