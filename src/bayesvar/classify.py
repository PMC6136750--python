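"""5-tier class assignment from probability credible intervals.

A variant is assigned a definitive tier only when its whole equal-tailed
95% credible interval clears the corresponding probability boundary;
anything straddling a boundary stays VUS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .ivp_model import ProbabilityDistribution


@dataclass(frozen=True)
class TierThresholds:
    """Probability boundaries of the 5-tier scheme (strictly increasing)."""

    benign: float = 0.001
    vlb: float = 0.1
    vlp: float = 0.9
    pathogenic: float = 0.99

    def __post_init__(self) -> None:
        t = (self.benign, self.vlb, self.vlp, self.pathogenic)
        if not all(a < b for a, b in zip(t, t[1:])):
            raise InvalidInputError(f"tier thresholds must be strictly increasing: {t}")


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise InvalidInputError(
                f"invalid credible interval [{self.lower}, {self.upper}]"
            )


def credible_interval(
    dist: ProbabilityDistribution | np.ndarray, level: float = 0.95, min_samples: int = 100
) -> CredibleInterval:
    """Equal-tailed credible interval from Monte-Carlo probability samples."""
    samples = np.asarray(getattr(dist, "samples", dist), dtype=float)
    if samples.size < min_samples:
        raise InvalidInputError(
            f"need at least {min_samples} samples for a credible interval, got {samples.size}"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    return CredibleInterval(lower=float(lo), upper=float(hi), level=level)


def assign_class(pci: CredibleInterval, thresholds: TierThresholds | None = None) -> str:
    """Assign one of benign/VLB/VUS/VLP/pathogenic from a credible interval.

    Pathogenic-side tiers require the interval's lower bound at or above the
    boundary; benign-side tiers require the upper bound strictly below it.
    """
    t = thresholds or TierThresholds()
    if pci.lower >= t.pathogenic:
        return "pathogenic"
    if pci.lower >= t.vlp:
        return "VLP"
    if pci.upper < t.benign:
        return "benign"
    if pci.upper < t.vlb:
        return "VLB"
    return "VUS"


def classify_distribution(
    dist: ProbabilityDistribution | np.ndarray,
    thresholds: TierThresholds | None = None,
    level: float = 0.95,
) -> tuple[str, CredibleInterval]:
    """Convenience wrapper: credible interval plus the assigned tier."""
    pci = credible_interval(dist, level=level)
    return assign_class(pci, thresholds), pci
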