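"""Re-expressing SEM-scale effects in years via Cohen's d.

Regression coefficients on the log epimutation burden live on a log-count
scale and are not directly comparable to clock coefficients, which are in
years. The conversion is a two-step standardization: first divide the
coefficient (and its SE) by the outcome's standard deviation to obtain a
unitless Cohen's d, then multiply by the standard deviation of a reference
clock's age acceleration, expressing the same standardized effect on the
reference clock's year scale. Both SDs are treated as known constants, so
the CI scales by the same factor and significance is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import AssocEstimate, Z975

__all__ = ["RescaledEffect", "rescale_sem_effect"]


@dataclass
class RescaledEffect:
    source: AssocEstimate
    cohen_d: float
    sigma_outcome: float
    sigma_reference_years: float
    beta_years: float
    se_years: float
    ci95_years: tuple[float, float]

    def as_estimate(self, outcome_name: str | None = None) -> AssocEstimate:
        """The rescaled effect as an AssocEstimate in years, poolable like
        any clock estimate."""
        s = self.source
        return AssocEstimate.from_fit(
            s.cohort_id, outcome_name or f"{s.outcome}_years", s.factor,
            s.category, s.model, self.beta_years, self.se_years, s.n)


def rescale_sem_effect(est: AssocEstimate, sigma_outcome: float,
                       sigma_reference_years: float) -> RescaledEffect:
    """Two-step rescaling: d = beta / sigma_outcome, then
    beta_years = d * sigma_reference_years (same factor on the SE)."""
    if sigma_outcome <= 0:
        raise ValueError(f"sigma_outcome must be > 0, got {sigma_outcome}")
    if sigma_reference_years <= 0:
        raise ValueError(f"sigma_reference_years must be > 0, got {sigma_reference_years}")
    d = est.beta / sigma_outcome
    se_d = est.se / sigma_outcome
    beta_years = d * sigma_reference_years
    se_years = se_d * sigma_reference_years
    return RescaledEffect(
        source=est, cohen_d=d, sigma_outcome=float(sigma_outcome),
        sigma_reference_years=float(sigma_reference_years),
        beta_years=beta_years, se_years=se_years,
        ci95_years=(beta_years - Z975 * se_years, beta_years + Z975 * se_years))
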