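"""Two-component reference-based deconvolution of beta values.

Breast tissue methylomes are modelled as a mixture of an epithelial and an
adipose reference profile. The basis is restricted to probes whose
reference beta values differ by strictly more than a contrast threshold
(default 0.7), and the adipose fraction of each sample is the constrained
least-squares mixture weight. For two components the constrained problem
has a closed form: with contrast d = beta_adipose - beta_epithelial on the
basis probes, the unconstrained minimizer of
    sum_p (beta_sample - [f * beta_adipose + (1-f) * beta_epithelial])^2
is  f* = <beta_sample - beta_epithelial, d> / <d, d>,
and the [0, 1]-constrained solution is f* clipped to [0, 1] (projection of
a 1-D quadratic onto an interval). Residual RMSE is computed at the clipped
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ReferenceProfiles

DEFAULT_CONTRAST_THRESHOLD = 0.7


class BasisEmptyError(ValueError):
    """No probe exceeds the contrast threshold; lower the threshold."""


class DegenerateBasisError(ValueError):
    """The two references coincide on the basis, so the fraction is unidentifiable."""


@dataclass
class DeconvolutionResult:
    """Per-sample adipose fractions with fit diagnostics."""

    sample_ids: list[str]
    adipose_fraction: np.ndarray
    residual_rmse: np.ndarray
    basis_probes: list[str]

    def __post_init__(self) -> None:
        self.adipose_fraction = np.asarray(self.adipose_fraction, dtype=float)
        self.residual_rmse = np.asarray(self.residual_rmse, dtype=float)
        n = len(self.sample_ids)
        if self.adipose_fraction.shape != (n,) or self.residual_rmse.shape != (n,):
            raise ValueError("result arrays must align with sample_ids")
        if not self.basis_probes:
            raise ValueError("basis_probes must be nonempty")
        if (self.adipose_fraction < 0).any() or (self.adipose_fraction > 1).any():
            raise ValueError("fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "adipose_fraction": self.adipose_fraction,
            "residual_rmse": self.residual_rmse,
        })


def select_discriminating_probes(refs: ReferenceProfiles,
                                 threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                                 ) -> list[str]:
    """Probes with |beta_adipose - beta_epithelial| strictly above threshold.

    Input order is preserved. An empty selection raises
    :class:`BasisEmptyError` rather than returning a useless basis.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mask = refs.abs_difference > threshold
    selected = [p for p, m in zip(refs.probe_ids, mask) if m]
    if not selected:
        raise BasisEmptyError(
            f"no probe has |delta beta| > {threshold}; lower the threshold"
        )
    return selected


def estimate_adipose_fraction(beta: BetaMatrix, refs: ReferenceProfiles,
                              basis: list[str]) -> DeconvolutionResult:
    """Closed-form constrained mixture fractions on the basis probes."""
    if not basis:
        raise BasisEmptyError("basis probe list is empty")
    sub = beta.subset_probes(list(basis))
    if np.isnan(sub.values).any():
        raise ValueError("missing values on basis probes; impute first")
    ref = refs.subset(list(basis))
    d = ref.beta_adipose - ref.beta_epithelial
    denom = float(d @ d)
    if denom == 0.0:
        raise DegenerateBasisError("references identical on the basis probes")
    resid0 = sub.values - ref.beta_epithelial[:, None]
    f = (d @ resid0) / denom
    f_clipped = np.clip(f, 0.0, 1.0)
    fitted = (ref.beta_epithelial[:, None]
              + d[:, None] * f_clipped[None, :])
    rmse = np.sqrt(((sub.values - fitted) ** 2).mean(axis=0))
    return DeconvolutionResult(list(beta.sample_ids), f_clipped, rmse,
                               list(basis))


class TwoComponentDeconvolution:
    """Model-style wrapper: build from data, ``fit()`` returns the result.

    Parameters
    ----------
    beta : BetaMatrix
        Bulk methylomes to decompose.
    refs : ReferenceProfiles
        Epithelial and adipose reference betas covering the matrix probes.
    threshold : float
        Contrast cut for basis selection (strict >), default 0.7.
    """

    def __init__(self, beta: BetaMatrix, refs: ReferenceProfiles,
                 threshold: float = DEFAULT_CONTRAST_THRESHOLD):
        self.beta = beta
        self.refs = refs
        self.threshold = threshold

    def fit(self) -> DeconvolutionResult:
        basis = select_discriminating_probes(self.refs, self.threshold)
        basis = [p for p in basis if p in set(self.beta.probe_ids)]
        if not basis:
            raise BasisEmptyError(
                "no discriminating probe present in the beta matrix"
            )
        return estimate_adipose_fraction(self.beta, self.refs, basis)
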