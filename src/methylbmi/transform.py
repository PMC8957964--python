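"""Piecewise BMI trait transformation.

The trait is mapped to a scale on which a linear methylation predictor is
fitted: logarithmic below a healthy-BMI anchor, linear above it,

    F(b) = ln(b + 1) - ln(h + 1)      if b <= h
    F(b) = (b - h) / (h + 1)          if b >  h

with anchor h = 25 kg/m2 by default (the upper limit of the healthy BMI
range). F is continuously differentiable at the anchor — both one-sided
derivatives equal 1/(h+1) — strictly increasing, and F(h) = 0, so the
transformed scale reads as "log-fold below healthy, linear excess above".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_HEALTHY_BMI = 25.0


class DomainError(ValueError):
    """Input outside the domain of the transform or its inverse."""


@dataclass(frozen=True)
class TraitTransform:
    """The piecewise BMI map and its exact inverse.

    Parameters
    ----------
    healthy_bmi : float
        Anchor (kg/m2) where the log and linear branches meet and F = 0.
    """

    healthy_bmi: float = DEFAULT_HEALTHY_BMI

    def __post_init__(self) -> None:
        if not self.healthy_bmi > 0:
            raise ValueError("healthy_bmi must be positive")

    @property
    def image_lower_bound(self) -> float:
        """Infimum of the image of F: F(b) -> -ln(h+1) as b -> 0+."""
        return -np.log(self.healthy_bmi + 1.0)

    def forward(self, bmi):
        """F(bmi); scalar in, scalar out; arrays elementwise."""
        b = np.asarray(bmi, dtype=float)
        if np.any(b <= 0):
            raise DomainError("BMI must be strictly positive")
        h = self.healthy_bmi
        out = np.where(b <= h,
                       np.log(b + 1.0) - np.log(h + 1.0),
                       (b - h) / (h + 1.0))
        return out.item() if np.isscalar(bmi) or out.ndim == 0 else out

    def inverse(self, y):
        """F^{-1}(y); domain y > -ln(healthy_bmi + 1)."""
        v = np.asarray(y, dtype=float)
        if np.any(v <= self.image_lower_bound):
            raise DomainError(
                f"transformed value must exceed {self.image_lower_bound:.6f}"
            )
        h = self.healthy_bmi
        out = np.where(v <= 0,
                       np.exp(v) * (h + 1.0) - 1.0,
                       h + v * (h + 1.0))
        return out.item() if np.isscalar(y) or out.ndim == 0 else out


def f_bmi(bmi, t: TraitTransform | None = None):
    """Transform BMI (kg/m2) to the model's trait scale."""
    return (t or TraitTransform()).forward(bmi)


def inv_f_bmi(y, t: TraitTransform | None = None):
    """Map a transformed trait value back to the BMI scale (kg/m2)."""
    return (t or TraitTransform()).inverse(y)
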