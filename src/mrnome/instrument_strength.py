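"""Instrument-strength diagnostics for MR-Egger: F statistics and I2GX.

The per-variant F statistic F_j = beta_exposure_j^2 / se_exposure_j^2
measures individual instrument strength for an IVW analysis.  For MR-Egger
the relevant quantity is collective: Cochran's Q computed on the SNP-exposure
associations,

    Q_GX = sum_j (gamma_hat_j - gamma_bar)^2 / sigma_Xj^2,

with gamma_bar the 1/sigma_Xj^2-weighted mean, yields

    I2GX = (Q_GX - (L - 1)) / Q_GX,

truncated at 0.  I2GX estimates the fraction of the true causal effect
retained by the MR-Egger slope under measurement error in the exposure
associations (regression dilution): the expected relative dilution is
1 - I2GX.  An I2GX of 0.9 plays the role the rule-of-thumb F of 10 plays in
classical IV analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SizeError, SummaryDataset

__all__ = [
    "f_stats",
    "q_gx",
    "i2_gx",
    "crude_adjust",
    "strength_report",
    "StrengthReport",
    "UndefinedCorrectionError",
]

#: Below this I2GX the MR-Egger point estimate should be treated with caution
#: and SIMEX adjustment considered.
DILUTION_WARNING_THRESHOLD = 0.9


class UndefinedCorrectionError(ValueError):
    """Crude dilution correction requested with a non-positive I2GX."""


@dataclass(frozen=True)
class StrengthReport:
    """Instrument-strength summary for one dataset/weighting mode."""

    f_stats: np.ndarray
    mean_f: float
    q_gx: float
    i2_gx: float
    weighted: bool
    L: int

    def to_dict(self) -> dict:
        return {
            "mean_f": self.mean_f,
            "q_gx": self.q_gx,
            "i2_gx": self.i2_gx,
            "weighted": self.weighted,
            "L": self.L,
        }


def f_stats(dataset: SummaryDataset) -> tuple[np.ndarray, float]:
    """Per-variant F_j = beta_exposure^2 / se_exposure^2 and their mean."""
    f = dataset.beta_exposure**2 / dataset.se_exposure**2
    return f, float(f.mean())


def _q_from_pairs(g: np.ndarray, s: np.ndarray) -> float:
    w = 1.0 / s**2
    gbar = float(np.sum(w * g) / np.sum(w))
    return float(np.sum(w * (g - gbar) ** 2))


def q_gx(dataset: SummaryDataset, weighted: bool = False) -> float:
    """Cochran's Q for the SNP-exposure associations.

    In unweighted mode the statistic is computed from (beta_exposure,
    se_exposure).  In weighted mode — matching an Egger regression weighted by
    1/se_outcome^2 — each variant is first transformed to
    (beta_exposure/se_outcome, se_exposure/se_outcome) and the identical
    formula applied to the transformed pairs.
    """
    if dataset.L < 2:
        raise SizeError("Q_GX needs at least 2 variants")
    if weighted:
        return _q_from_pairs(
            dataset.beta_exposure / dataset.se_outcome,
            dataset.se_exposure / dataset.se_outcome,
        )
    return _q_from_pairs(dataset.beta_exposure, dataset.se_exposure)


def i2_gx(dataset: SummaryDataset, weighted: bool = False) -> float:
    """I2GX = max(0, (Q_GX - (L - 1)) / Q_GX).

    Negative raw values (Q below its null expectation L - 1) are truncated to
    0, the standard I2 convention; Q = 0 (total homogeneity of the exposure
    associations) also returns 0.
    """
    q = q_gx(dataset, weighted=weighted)
    if q == 0:
        return 0.0
    return max(0.0, (q - (dataset.L - 1)) / q)


def crude_adjust(slope: float, i2: float) -> float:
    """Crude dilution-corrected causal estimate: slope / I2GX.

    Divides the MR-Egger slope by the estimated retention fraction.  Because
    the I2GX estimate is itself noisy — and can be near zero under weak
    instruments — this correction can be unstable; a warning is emitted when
    i2 < 0.9.  SIMEX is the recommended adjustment in that regime.
    """
    if i2 <= 0:
        raise UndefinedCorrectionError(
            f"crude dilution correction undefined for I2GX = {i2}"
        )
    if i2 < DILUTION_WARNING_THRESHOLD:
        warnings.warn(
            f"I2GX = {i2:.3f} < {DILUTION_WARNING_THRESHOLD}: the crude "
            "slope/I2GX correction is unstable; consider SIMEX",
            UserWarning,
            stacklevel=2,
        )
    return slope / i2


def strength_report(dataset: SummaryDataset, weighted: bool = False) -> StrengthReport:
    """Bundle F statistics, Q_GX and I2GX for one weighting mode."""
    f, mean_f = f_stats(dataset)
    q = q_gx(dataset, weighted=weighted)
    i2 = 0.0 if q == 0 else max(0.0, (q - (dataset.L - 1)) / q)
    return StrengthReport(
        f_stats=f, mean_f=mean_f, q_gx=q, i2_gx=i2, weighted=weighted, L=dataset.L
    )
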