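"""Rescaled priors and multifactorial posterior updating.

The IVP probability distribution is first shifted into [0.1, 0.9]
(``0.8 * p + 0.1``) and then spread around its median so the relative
variability of the original distribution is preserved; the resulting prior
cannot on its own clear the benign/pathogenic tier boundaries, which is how
the at-least-two-lines-of-evidence principle is enforced.  The posterior is
a per-sample Bayes-rule update against the total evidence likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .ivp_model import ProbabilityDistribution

_MED_EPS = 1e-12


@dataclass
class RescaledPrior(ProbabilityDistribution):
    role: str = "prior"
    ivp_median: float = float("nan")
    shifted_median: float = float("nan")


@dataclass
class PosteriorDistribution(ProbabilityDistribution):
    role: str = "posterior"
    lr_total: float = 1.0
    has_evidence: bool = True


def rescale_prior(
    ivp: ProbabilityDistribution, clip: tuple[float, float] = (0.001, 0.999)
) -> RescaledPrior:
    """Rescale an IVP distribution into a prior distribution.

    With shifted samples ``s_n = 0.8 * p_n + 0.1`` and medians ``m`` (IVP)
    and ``ms`` (shifted), returns
    ``ms + (s_n - ms) * sd(ms) / sd(m)`` where ``sd(p) = sqrt(p (1 - p))``,
    clipped to ``clip``.  A degenerate (constant) input yields the constant
    ``0.8 * p + 0.1``.
    """
    p = np.asarray(ivp.samples, dtype=float)
    shifted = 0.8 * p + 0.1
    med = float(np.median(p))
    med_s = float(np.median(shifted))
    sd = np.sqrt(max(med * (1.0 - med), _MED_EPS))
    sd_s = np.sqrt(max(med_s * (1.0 - med_s), 0.0))
    out = med_s + (shifted - med_s) * (sd_s / sd)
    out = np.clip(out, clip[0], clip[1])
    return RescaledPrior(samples=out, ivp_median=med, shifted_median=med_s)


def posterior_update(
    prior: ProbabilityDistribution, lr_total: float, has_evidence: bool = True
) -> PosteriorDistribution:
    """Elementwise Bayes update: ``q = p * LR / (1 - p + p * LR)``.

    ``has_evidence=False`` tags the result as produced without any evidence
    (all seven category LRs missing), in which case ``lr_total`` must be 1
    and the posterior equals the prior.
    """
    if not np.isfinite(lr_total) or lr_total <= 0:
        raise InvalidInputError(f"LR_total must be positive, got {lr_total}")
    p = np.asarray(prior.samples, dtype=float)
    q = p * lr_total / (1.0 - p + p * lr_total)
    return PosteriorDistribution(samples=q, lr_total=float(lr_total), has_evidence=has_evidence)
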