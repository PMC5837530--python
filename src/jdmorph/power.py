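"""Effect sizes and atrophy-endpoint sample-size calculations.

Cohen's d with the pooled standard deviation, and the two-arm sample size
for 80% power at two-sided alpha = 0.05 to detect a fractional treatment
effect TE on an atrophy endpoint with group effect size ES:

    N per arm = ceil( 2 * ((1.96 + 0.842) / (TE * ES))^2 )

The z constants are fixed at their conventional printed precision (1.96 for
alpha = 0.05 two-sided, 0.842 for 80% power). This is the "n80" biomarker-
efficiency criterion used to compare volumetric and Jacobian-determinant
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import pandas as pd

__all__ = ["EffectSize", "TrialDesign", "cohens_d", "sample_size_per_arm", "power_curve"]

Z_ALPHA = 1.96   # two-sided alpha = 0.05
Z_POWER = 0.842  # 80% power


@dataclass(frozen=True)
class EffectSize:
    d: float
    m1: float
    m2: float
    s1: float
    s2: float
    n1: int
    n2: int
    pooled_sd: float

    @property
    def ci95(self) -> tuple[float, float]:
        """Normal-approximation 95% CI of d."""
        se = sqrt(
            (self.n1 + self.n2) / (self.n1 * self.n2)
            + self.d**2 / (2 * (self.n1 + self.n2 - 2))
        )
        return (self.d - 1.96 * se, self.d + 1.96 * se)


@dataclass(frozen=True)
class TrialDesign:
    treatment_effectiveness: float
    effect_size: float
    n_per_arm: int


def cohens_d(m1, s1, n1, m2, s2, n2) -> EffectSize:
    """Pooled-SD Cohen's d, first group minus second."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("SDs must be >= 0 and not both zero")
    pooled = sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return EffectSize(
        d=(m1 - m2) / pooled, m1=m1, m2=m2, s1=s1, s2=s2, n1=n1, n2=n2,
        pooled_sd=pooled,
    )


def sample_size_per_arm(te: float, es: float) -> int:
    """Per-arm N for 80% power / alpha 0.05 at treatment effectiveness te."""
    if te <= 0 or es <= 0:
        raise ValueError("te and es must be > 0")
    return ceil(2.0 * ((Z_ALPHA + Z_POWER) / (te * es)) ** 2)


def power_curve(es: float, te_grid) -> pd.DataFrame:
    """Table of (te, N per arm) over a treatment-effectiveness grid."""
    rows = []
    for te in te_grid:
        if not 0 < te <= 1:
            raise ValueError("treatment effectiveness must be in (0, 1]")
        rows.append(dict(te=float(te), n_per_arm=sample_size_per_arm(te, es)))
    return pd.DataFrame(rows)
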