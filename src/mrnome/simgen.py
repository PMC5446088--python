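"""Synthetic two-sample summary-data generator with moment calibration.

Datasets are generated from the standard two-sample model: for each variant j,

    gamma_hat_j ~ N(gamma_j, sigma_Xj^2)
    Gamma_hat_j ~ N(alpha_j + beta * gamma_j, sigma_Yj^2),

with true exposure associations gamma_j ~ U(gamma_low, gamma_high), exposure
SEs sigma_Xj ~ U(sx_low, sx_high), pleiotropic effects alpha_j uniform per
scenario, and sigma_Yj = 2 * sigma_Xj (same allele frequency, different
sample sizes in the two cohorts).  All parameters are redrawn independently
for every dataset, so instrument strength is independent of the direct
effects (a weak form of InSIDE by construction).

Five pleiotropy scenarios are supported:

1. balanced pleiotropy, positive causal effect: alpha ~ U(-0.2, 0.2), beta=1
2. negative directional pleiotropy:             alpha ~ U(-0.2, 0),   beta=1
3. positive directional pleiotropy:             alpha ~ U(0, 0.2),    beta=1
4. positive directional pleiotropy, null:       alpha ~ U(0, 0.2),    beta=0
5. no pleiotropy, null:                         alpha = 0,            beta=0

Calibration
-----------
:func:`calibrate` solves for uniform bounds hitting a target mean F statistic
and true I2GX.  The moment equations (sigma_gamma^2 = Var(gamma),
mu_gamma = E[gamma]) are

    i2_true = sigma_gamma^2 / (sigma_gamma^2 + s2),   s2 = 1 / E[1/sigma_X^2]
    mean_f  = 1 + (sigma_gamma^2 + mu_gamma^2) * E[1/sigma_X^2]

where the effective error variance s2 is the precision-weighted (harmonic)
mean sx_low * sx_high — the dilution factor the 1/sigma_X^2-weighted Q
statistic actually estimates.  Two equations leave two free conventions:
``sx_ratio`` fixes sx_high / sx_low (default 2), and the remaining overall
scale is pinned by the asymptotic bias multiplier of the IVW estimate under
directional pleiotropy, mu_gamma * E[1/sigma_X^2] / mean_f =
``ivw_bias_factor`` (default 2.1, so mean pleiotropy 0.1 biases IVW by 0.21).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .core import SummaryDataset
from .instrument_strength import i2_gx

__all__ = [
    "ScenarioSpec",
    "CalibrationTarget",
    "CalibratedBounds",
    "SimTruth",
    "CalibrationError",
    "calibrate",
    "simulate_dataset",
    "verify_calibration",
]


class CalibrationError(ValueError):
    """No positive uniform bounds can hit the requested (mean_f, i2) pair."""


_SCENARIOS = {
    1: (-0.2, 0.2, 1.0),
    2: (-0.2, 0.0, 1.0),
    3: (0.0, 0.2, 1.0),
    4: (0.0, 0.2, 0.0),
    5: (0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Pleiotropy scenario: alpha_j ~ U(alpha_low, alpha_high), causal beta."""

    scenario_id: int
    alpha_low: float
    alpha_high: float
    beta: float

    @classmethod
    def from_id(cls, scenario_id: int) -> "ScenarioSpec":
        try:
            lo, hi, beta = _SCENARIOS[scenario_id]
        except KeyError:
            raise ValueError(f"unknown scenario {scenario_id}; valid: 1-5") from None
        return cls(scenario_id=scenario_id, alpha_low=lo, alpha_high=hi, beta=beta)

    @property
    def beta0_true(self) -> float:
        """Implied MR-Egger intercept: the mean pleiotropic effect."""
        return 0.5 * (self.alpha_low + self.alpha_high)


@dataclass(frozen=True)
class CalibrationTarget:
    """Requested study conditions: mean F, true I2GX, variants per dataset."""

    mean_f: float
    i2_true: float
    L: int = 25
    sigma_y_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not self.mean_f > 1:
            raise ValueError("mean_f must exceed 1")
        if not 0 < self.i2_true < 1:
            raise ValueError("i2_true must be in (0, 1)")
        if self.L < 3:
            raise ValueError("L must be at least 3")
        if self.sigma_y_multiplier <= 0:
            raise ValueError("sigma_y_multiplier must be positive")


@dataclass(frozen=True)
class CalibratedBounds:
    """Uniform bounds for the true exposure associations and their SEs."""

    gamma_low: float
    gamma_high: float
    sx_low: float
    sx_high: float

    def __post_init__(self) -> None:
        if not 0 < self.sx_low < self.sx_high:
            raise ValueError("need 0 < sx_low < sx_high")
        if not 0 <= self.gamma_low < self.gamma_high:
            raise ValueError("need 0 <= gamma_low < gamma_high")

    @property
    def mu_gamma(self) -> float:
        return 0.5 * (self.gamma_low + self.gamma_high)

    @property
    def sigma_gamma_sq(self) -> float:
        return (self.gamma_high - self.gamma_low) ** 2 / 12.0

    @property
    def mean_sx_sq(self) -> float:
        """Arithmetic E[sigma_X^2] for sigma_X ~ U(sx_low, sx_high)."""
        return (self.sx_low**2 + self.sx_low * self.sx_high + self.sx_high**2) / 3.0

    @property
    def harmonic_sx_sq(self) -> float:
        """Precision-weighted error variance 1 / E[1/sigma_X^2] = sx_low*sx_high."""
        return self.sx_low * self.sx_high

    @property
    def implied_i2(self) -> float:
        """Population I2GX: expected retention of the Egger slope."""
        s2 = self.harmonic_sx_sq
        return self.sigma_gamma_sq / (self.sigma_gamma_sq + s2)

    @property
    def implied_mean_f(self) -> float:
        """Population mean of the estimated per-variant F statistic."""
        return 1.0 + (self.sigma_gamma_sq + self.mu_gamma**2) / self.harmonic_sx_sq


@dataclass(frozen=True)
class SimTruth:
    """Latent parameters of one simulated dataset, for oracle checks."""

    gamma: np.ndarray
    alpha: np.ndarray
    beta: float


def calibrate(
    target: CalibrationTarget,
    sx_ratio: float = 2.0,
    ivw_bias_factor: float = 2.1,
) -> CalibratedBounds:
    """Solve the uniform bounds for a (mean F, I2GX) target.

    Raises :class:`CalibrationError` when no bounds with gamma_low >= 0
    exist: the target needs mean_f >= 1 + 4 * i2/(1 - i2), so high I2GX
    values are not attainable when the mean F statistic is low.
    """
    if sx_ratio <= 1:
        raise ValueError("sx_ratio must exceed 1")
    if ivw_bias_factor <= 0:
        raise ValueError("ivw_bias_factor must be positive")
    k = target.i2_true / (1.0 - target.i2_true)
    feasible_f = 1.0 + 4.0 * k
    if target.mean_f < feasible_f:
        raise CalibrationError(
            f"I2GX = {target.i2_true} is not attainable at mean F = "
            f"{target.mean_f}: positive uniform bounds require mean F >= "
            f"{feasible_f:.1f} (high I2GX values are not mathematically "
            "possible when the mean F statistic is low)"
        )
    c1 = np.sqrt(k * sx_ratio)                      # sigma_gamma / sx_low
    c2 = np.sqrt(sx_ratio * (target.mean_f - 1.0 - k))  # mu_gamma / sx_low
    sx_low = c2 / (sx_ratio * target.mean_f * ivw_bias_factor)
    sx_high = sx_ratio * sx_low
    sigma_gamma = c1 * sx_low
    mu_gamma = c2 * sx_low
    half_width = np.sqrt(3.0) * sigma_gamma
    return CalibratedBounds(
        gamma_low=float(mu_gamma - half_width),
        gamma_high=float(mu_gamma + half_width),
        sx_low=float(sx_low),
        sx_high=float(sx_high),
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_dataset(
    scenario: Union[ScenarioSpec, int],
    bounds: CalibratedBounds,
    L: int = 25,
    seed=None,
    sigma_y_multiplier: float = 2.0,
) -> tuple[SummaryDataset, SimTruth]:
    """Draw one two-sample summary dataset plus its latent truth.

    Per variant: sigma_X ~ U(sx_low, sx_high), gamma ~ U(gamma_low,
    gamma_high), alpha ~ U(alpha_low, alpha_high), sigma_Y =
    sigma_y_multiplier * sigma_X, then gamma_hat ~ N(gamma, sigma_X^2) and
    Gamma_hat ~ N(alpha + beta*gamma, sigma_Y^2).  ``seed`` may be an int,
    a ``numpy.random.Generator`` or a ``SeedSequence``; the same seed gives a
    bit-identical dataset.
    """
    if isinstance(scenario, int):
        scenario = ScenarioSpec.from_id(scenario)
    rng = _as_rng(seed)
    sx = rng.uniform(bounds.sx_low, bounds.sx_high, L)
    gamma = rng.uniform(bounds.gamma_low, bounds.gamma_high, L)
    if scenario.alpha_low == scenario.alpha_high:
        alpha = np.full(L, scenario.alpha_low)
    else:
        alpha = rng.uniform(scenario.alpha_low, scenario.alpha_high, L)
    sy = sigma_y_multiplier * sx
    gamma_hat = rng.normal(gamma, sx)
    big_gamma_hat = rng.normal(alpha + scenario.beta * gamma, sy)
    dataset = SummaryDataset(
        variant_id=np.array([f"snp{i + 1}" for i in range(L)], dtype=object),
        beta_exposure=gamma_hat,
        se_exposure=sx,
        beta_outcome=big_gamma_hat,
        se_outcome=sy,
    )
    return dataset, SimTruth(gamma=gamma, alpha=alpha, beta=scenario.beta)


def verify_calibration(
    bounds: CalibratedBounds,
    target: CalibrationTarget,
    n_datasets: int = 5000,
    seed: Optional[int] = 0,
    scenario: int = 1,
) -> dict:
    """Monte-Carlo check of the calibration moments.

    Returns achieved mean estimated F and mean truncated I2GX over
    ``n_datasets`` simulated datasets.  The achieved mean F should be within
    ~2% of the target; the mean I2GX estimate sits at or slightly below the
    true value (the downward finite-sample bias grows as mean F falls).
    """
    spec = ScenarioSpec.from_id(scenario)
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    fbars = np.empty(n_datasets)
    i2s = np.empty(n_datasets)
    for r, child in enumerate(children):
        d, _ = simulate_dataset(
            spec, bounds, L=target.L, seed=np.random.default_rng(child),
            sigma_y_multiplier=target.sigma_y_multiplier,
        )
        fbars[r] = np.mean(d.beta_exposure**2 / d.se_exposure**2)
        i2s[r] = i2_gx(d, weighted=False)
    return {
        "mean_f": float(fbars.mean()),
        "mean_i2": float(i2s.mean()),
        "p_i2_zero": float(np.mean(i2s == 0.0)),
        "n_datasets": n_datasets,
    }
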