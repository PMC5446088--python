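"""Ratio, IVW and MR-Egger estimators for two-sample summary data.

The inverse-variance-weighted (IVW) estimate is the weighted mean of the
per-variant ratio estimates b_j = Gamma_hat_j / gamma_hat_j with NOME weights
w_j = gamma_hat_j^2 / sigma_Yj^2; it equals the slope of the zero-intercept
regression of the outcome associations on the exposure associations weighted
by 1/sigma_Yj^2.  MR-Egger regression frees the intercept, which then
estimates the average directional pleiotropic effect while the slope
estimates the causal effect under the InSIDE assumption.

Inference uses a multiplicative random-effects model: fixed-effect standard
errors are inflated by the residual over-dispersion factor
phi = max(1, sqrt(weighted RSS / df)) and referred to a Student-t with
df = L - 1 (IVW) or L - 2 (Egger).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DegenerateInstrumentError,
    EggerResult,
    MRResult,
    SingularDesignError,
    SizeError,
    SummaryDataset,
    orient_exposure_positive,
)

__all__ = ["ratio_estimates", "ivw", "egger"]


def _t_test(estimate: float, se: float, df: int) -> tuple[float, float]:
    """Two-sided t test of estimate = 0; returns (t, p)."""
    if se == 0:
        t = np.inf if estimate != 0 else 0.0
        return t, 0.0 if estimate != 0 else 1.0
    t = estimate / se
    return t, float(2.0 * stats.t.sf(abs(t), df))


def ratio_estimates(dataset: SummaryDataset) -> pd.DataFrame:
    """Per-variant Wald ratio estimates with first-order (NOME) SEs.

    Returns a DataFrame with columns ``variant_id``, ``estimate``
    (= beta_outcome / beta_exposure) and ``se`` (= se_outcome /
    \\|beta_exposure\\|, the leading Taylor term that ignores uncertainty in
    the exposure association).
    """
    _check_nonzero_exposure(dataset)
    return pd.DataFrame(
        {
            "variant_id": dataset.variant_id,
            "estimate": dataset.beta_outcome / dataset.beta_exposure,
            "se": dataset.se_outcome / np.abs(dataset.beta_exposure),
        }
    )


def _check_nonzero_exposure(dataset: SummaryDataset) -> None:
    zero = dataset.beta_exposure == 0
    if np.any(zero):
        bad = dataset.variant_id[zero][0]
        raise DegenerateInstrumentError(
            f"beta_exposure is exactly 0 for variant {bad!r}; "
            "ratio-based estimators are undefined for null instruments"
        )


def ivw(dataset: SummaryDataset) -> MRResult:
    """Inverse-variance-weighted causal estimate.

    Point estimate: sum(w_j b_j) / sum(w_j) with b_j the ratio estimates and
    w_j = beta_exposure_j^2 / se_outcome_j^2.  The fixed-effect variance
    1/sum(w_j) is inflated by phi^2 with phi = max(1, sqrt(RSS_w/(L-1)))
    from the equivalent zero-intercept weighted regression; p-value from a
    two-sided t test with df = L - 1.
    """
    if dataset.L < 2:
        raise SizeError("IVW needs at least 2 variants")
    _check_nonzero_exposure(dataset)
    x = dataset.beta_exposure
    y = dataset.beta_outcome
    sy2 = dataset.se_outcome**2
    w = x**2 / sy2
    estimate = float(np.sum(w * (y / x)) / np.sum(w))
    rss_w = float(np.sum((y - estimate * x) ** 2 / sy2))
    df = dataset.L - 1
    phi = max(1.0, np.sqrt(rss_w / df))
    se = float(phi / np.sqrt(np.sum(w)))
    t, p = _t_test(estimate, se, df)
    return MRResult(
        estimate=estimate,
        se=se,
        t_value=t,
        p_value=p,
        df=df,
        method="ivw",
        n_variants=dataset.L,
        overdispersion=phi,
    )


def _egger_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray, weighted: bool):
    """Closed-form straight-line (W)LS fit of y on x.

    ``x`` may be 1-D (one design) or 2-D ``(B, L)`` (B designs sharing y, w;
    used by the SIMEX pseudo-replicate loop).  Returns arrays
    (intercept, slope, var_intercept, var_slope, scale) where ``scale`` is the
    residual SD on the weighted scale, floored at 1 when ``weighted`` (the
    multiplicative random-effects convention: heterogeneity can only inflate
    fixed-effect SEs) and unfloored for the plain OLS fit.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    L = x.shape[1]
    sw = float(np.sum(w))
    sy = float(np.sum(w * y))
    sx = np.sum(w * x, axis=1)
    sxx = np.sum(w * x * x, axis=1)
    sxy = np.sum((w * y) * x, axis=1)
    det = sw * sxx - sx**2
    if np.any(det <= 0):
        raise SingularDesignError(
            "no spread in the exposure associations: Egger design is singular"
        )
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / sw
    resid = y - intercept[:, None] - slope[:, None] * x
    rss_w = np.sum(w * resid**2, axis=1)
    scale2 = rss_w / (L - 2)
    if weighted:
        scale2 = np.maximum(1.0, scale2)
    var_slope = scale2 * sw / det
    var_intercept = scale2 * sxx / det
    return intercept, slope, var_intercept, var_slope, np.sqrt(scale2)


def egger(
    dataset: SummaryDataset, weighted: bool = True, orient: bool = True
) -> EggerResult:
    """MR-Egger regression of outcome on exposure associations.

    Parameters
    ----------
    weighted : bool
        If True (recommended for observed data), weighted least squares with
        inverse-variance weights 1/se_outcome^2 and SEs inflated by
        phi = max(1, sqrt(RSS_w/(L-2))).  If False, ordinary least squares
        with the usual OLS residual variance.
    orient : bool
        If True, apply :func:`orient_exposure_positive` first (MR-Egger is
        not invariant to allele coding; the convention is all-positive
        exposure associations).  Set False only for data already generated
        under the positive-coding convention, e.g. the simulation harness.

    Returns an :class:`EggerResult`; intercept and slope each carry a
    two-sided t test (df = L - 2): intercept vs 0 is the directional-
    pleiotropy test, slope vs 0 the causal test.
    """
    if dataset.L < 3:
        raise SizeError("MR-Egger needs at least 3 variants (df = L - 2 >= 1)")
    n_flipped = 0
    if orient:
        oriented = orient_exposure_positive(dataset)
        n_flipped = int(np.sum(oriented.beta_exposure != dataset.beta_exposure))
        dataset = oriented
    x = dataset.beta_exposure
    y = dataset.beta_outcome
    if np.ptp(x) == 0:
        raise SingularDesignError(
            "all exposure associations are identical: Egger design is singular"
        )
    w = 1.0 / dataset.se_outcome**2 if weighted else np.ones(dataset.L)
    b0, b1, v0, v1, scale = _egger_fit(x, y, w, weighted)
    df = dataset.L - 2
    results = []
    for name, est, var in (
        ("egger_intercept", b0[0], v0[0]),
        ("egger_slope", b1[0], v1[0]),
    ):
        se = float(np.sqrt(var))
        t, p = _t_test(float(est), se, df)
        results.append(
            MRResult(
                estimate=float(est),
                se=se,
                t_value=t,
                p_value=p,
                df=df,
                method=name + ("_weighted" if weighted else "_unweighted"),
                n_variants=dataset.L,
                overdispersion=float(scale[0]),
            )
        )
    return EggerResult(
        intercept=results[0],
        slope=results[1],
        weighted=weighted,
        n_flipped=n_flipped,
    )
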