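"""Case-control power for a dominant-model exposure comparison.

The design treats carrying at least one copy of the minor allele as the
exposure: under Hardy-Weinberg the carrier probability among controls is
p0 = 1 - (1 - MAF)^2.  A genotype relative risk R for carriers maps to
the case exposure probability p1 = R p0 / (R p0 + 1 - p0).  Power for
the two-sided two-proportion z-test uses the pooled-proportion standard
error under the null and the unpooled standard error under the
alternative:

    power = Phi( (|p1 - p0| - z_{a/2} SE0) / SE1 ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerDesign",
    "dominant_exposure_prob",
    "case_exposure",
    "power_two_prop",
    "grr_for_power",
]


@dataclass(frozen=True)
class PowerDesign:
    """Inputs of the dominant-model case-control power calculation."""

    maf: float
    grr: float
    n_case: int
    n_control: int
    alpha: float
    model: str = "dominant"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf must lie in [0, 1]")
        if self.grr <= 0:
            raise ValueError("genotype relative risk must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.model != "dominant":
            raise ValueError("only the dominant penetrance model is supported")


def dominant_exposure_prob(maf: float) -> float:
    """Carrier (exposure) probability among controls: 1 - (1 - maf)^2."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must lie in [0, 1]")
    return 1.0 - (1.0 - maf) ** 2


def case_exposure(p0: float, grr: float) -> float:
    """Exposure probability among cases when carriers have grr-fold risk.

    Bayes with equal baseline weighting: p1 = R p0 / (R p0 + 1 - p0).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("control exposure must lie strictly in (0, 1)")
    if grr <= 0:
        raise ValueError("genotype relative risk must be positive")
    return grr * p0 / (grr * p0 + 1.0 - p0)


def power_two_prop(design: PowerDesign) -> float:
    """Two-sided two-proportion z-test power for the dominant design."""
    p0 = dominant_exposure_prob(design.maf)
    if not 0.0 < p0 < 1.0:
        raise ValueError("degenerate design: control exposure is 0 or 1")
    p1 = case_exposure(p0, design.grr)
    n1, n0 = design.n_case, design.n_control
    pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
    se0 = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n0))
    se1 = np.sqrt(p1 * (1.0 - p1) / n1 + p0 * (1.0 - p0) / n0)
    if se1 == 0 or se0 == 0:
        raise ValueError("degenerate design: zero standard error")
    z_alpha = stats.norm.isf(design.alpha / 2.0)
    return float(stats.norm.cdf((abs(p1 - p0) - z_alpha * se0) / se1))


def grr_for_power(
    target_power: float,
    maf: float,
    n_case: int,
    n_control: int,
    alpha: float,
    tol: float = 1e-4,
    grr_max: float = 1000.0,
) -> float:
    """Genotype relative risk at which the design reaches ``target_power``.

    Bisection on grr over [1, grr_max]; raises if the target is not
    attainable inside that range.
    """
    if not alpha < target_power < 1.0:
        raise ValueError("target power must lie in (alpha, 1)")

    def gap(grr: float) -> float:
        d = PowerDesign(
            maf=maf, grr=grr, n_case=n_case, n_control=n_control, alpha=alpha
        )
        return power_two_prop(d) - target_power

    lo, hi = 1.0, grr_max
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("target power not attainable for grr in [1, grr_max]")
    return float(optimize.brentq(gap, lo, hi, xtol=tol))
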