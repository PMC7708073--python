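"""Two-state UV melting simulation and van't Hoff analysis.

A bimolecular duplex of two distinct strands at total strand concentration
Ct (equimolar, non-self-complementary) melts with duplex fraction alpha(T)
given by the equilibrium constant

    K(T) = exp(-(dH*1000 - T*dS) / (R*T)) = 2 alpha / ((1 - alpha)^2 Ct)

so alpha = 1/2 exactly where K = 4/Ct, which is the definition of Tm and is
equivalent to 1/Tm = R ln(Ct/4)/dH + dS/dH.  Simulated absorbance curves
are a linear-baseline mixture of the single-strand and duplex states plus
optional Gaussian noise; Tm is extracted by fitting the two baselines and
interpolating the half-fraction crossing, and (dH, dS) are recovered from
the linear dependence of 1/Tm on ln(Ct/4) over a concentration series.

Temperatures are kelvin at the regression interface (1/Tm must be
absolute); degrees Celsius are accepted and converted only at the user
boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KELVIN_OFFSET, R_CAL
from .predict import predict_tm

__all__ = [
    "MeltingCurve",
    "MeltingDataset",
    "VantHoffResult",
    "two_state_fraction",
    "simulate_melting_curve",
    "simulate_melting_dataset",
    "extract_tm",
    "vant_hoff_fit",
]


@dataclass(frozen=True)
class MeltingCurve:
    """Absorbance-versus-temperature curve (temperature in degC, ascending)."""

    temperature: np.ndarray
    absorbance: np.ndarray
    Ct: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("temperature and absorbance must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class MeltingDataset:
    """(Ct, Tm) points feeding the van't Hoff regression; Tm in kelvin."""

    ct: np.ndarray
    tm_K: np.ndarray

    def __post_init__(self) -> None:
        ct = np.asarray(self.ct, dtype=float)
        tm = np.asarray(self.tm_K, dtype=float)
        if ct.shape != tm.shape or ct.ndim != 1:
            raise ValueError("ct and tm_K must be equal-length 1-D arrays")
        if len(ct) < 3:
            raise ValueError("need at least 3 (Ct, Tm) points")
        if np.any(ct <= 0):
            raise ValueError("all Ct must be positive")
        if len(np.unique(ct)) != len(ct):
            raise ValueError("Ct values must be distinct")
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "tm_K", tm)

    @classmethod
    def from_celsius(cls, ct: Sequence[float], tm_C: Sequence[float]) -> "MeltingDataset":
        return cls(np.asarray(ct, float), np.asarray(tm_C, float) + KELVIN_OFFSET)


def two_state_fraction(
    temperature_C: np.ndarray, dH: float, dS: float, Ct: float
) -> np.ndarray:
    """Duplex fraction alpha(T) of the two-state bimolecular equilibrium."""
    T = np.asarray(temperature_C, dtype=float) + KELVIN_OFFSET
    # dG(T) in cal/mol; K dimensionless in mol/L standard state
    dg = dH * 1000.0 - T * dS
    K = np.exp(-dg / (R_CAL * T))
    kc = K * Ct
    # kc*alpha^2 - 2(kc + 1)*alpha + kc = 0; root in [0, 1]
    alpha = (kc + 1.0 - np.sqrt(2.0 * kc + 1.0)) / np.where(kc > 0, kc, 1.0)
    return np.clip(alpha, 0.0, 1.0)


def simulate_melting_curve(
    dH: float,
    dS: float,
    Ct: float,
    grid: np.ndarray | None = None,
    ss_baseline: tuple[float, float] = (0.80, 6e-4),
    ds_baseline: tuple[float, float] = (0.70, 4e-4),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> MeltingCurve:
    """Simulate a two-state UV melting curve.

    dH in kcal/mol (< 0), dS in cal/(mol K), Ct in mol/L.  Baselines are
    (intercept, slope-per-degC) of the single-strand and duplex states;
    the defaults give ~15% hyperchromicity with gently sloping baselines.
    Noise is i.i.d. Gaussian on absorbance (sigma = 0 by default so
    fixtures are deterministic).
    """
    if dH >= 0:
        raise ValueError("dH must be negative")
    if Ct <= 0:
        raise ValueError("Ct must be positive")
    if grid is None:
        grid = np.arange(0.0, 90.0 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    alpha = two_state_fraction(grid, dH, dS, Ct)
    ss = ss_baseline[0] + ss_baseline[1] * grid
    ds_ = ds_baseline[0] + ds_baseline[1] * grid
    absorbance = ss * (1.0 - alpha) + ds_ * alpha
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sigma, size=grid.shape)
    return MeltingCurve(
        temperature=grid,
        absorbance=absorbance,
        Ct=Ct,
        params=dict(
            dH=dH, dS=dS, Ct=Ct, ss_baseline=ss_baseline,
            ds_baseline=ds_baseline, noise_sigma=noise_sigma, seed=seed,
        ),
    )


def extract_tm(curve: MeltingCurve, baseline_span: float = 0.15) -> float:
    """Tm (degC) from a melting curve by the baseline/half-fraction method.

    Linear baselines are fitted over the lower and upper ``baseline_span``
    fractions of the temperature range; the baseline-normalized duplex
    fraction is interpolated to its 0.5 crossing.  Raises if the curve does
    not span the transition.
    """
    t = curve.temperature
    a = curve.absorbance
    span = t[-1] - t[0]
    lo = t <= t[0] + baseline_span * span
    hi = t >= t[-1] - baseline_span * span
    p_lo = np.polyfit(t[lo], a[lo], 1)  # duplex-side baseline (low T)
    p_hi = np.polyfit(t[hi], a[hi], 1)  # single-strand baseline (high T)
    base_lo = np.polyval(p_lo, t)
    base_hi = np.polyval(p_hi, t)
    denom = base_hi - base_lo
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("degenerate baselines: no hyperchromicity")
    alpha = (base_hi - a) / denom  # duplex fraction estimate
    crossing = np.nonzero((alpha[:-1] - 0.5) * (alpha[1:] - 0.5) <= 0)[0]
    crossing = [i for i in crossing if alpha[i] != alpha[i + 1]]
    if not crossing:
        raise ValueError("melting transition (alpha = 0.5) not within the grid")
    i = crossing[-1]  # last crossing: robust to baseline-edge noise
    frac = (0.5 - alpha[i]) / (alpha[i + 1] - alpha[i])
    tm = float(t[i] + frac * (t[i + 1] - t[i]))
    if not 20.0 <= tm <= 55.0:
        warnings.warn(
            f"Tm = {tm:.1f} degC is outside the 20-55 degC range where "
            "extrapolation of dH, dS to 37 degC is most reliable",
            stacklevel=2,
        )
    return tm


def simulate_melting_dataset(
    dH: float,
    dS: float,
    concentrations: Sequence[float],
    noise_sigma_tm: float = 0.0,
    seed: int | None = None,
) -> MeltingDataset:
    """(Ct, Tm) series straight from the closed-form Tm with optional
    Gaussian jitter on Tm (degC scale) -- a fast path that skips curve
    extraction for regression-level studies."""
    ct = np.asarray(concentrations, dtype=float)
    tm_c = np.array([predict_tm(dH, dS, c) for c in ct])
    if noise_sigma_tm > 0:
        rng = np.random.default_rng(seed)
        tm_c = tm_c + rng.normal(0.0, noise_sigma_tm, size=ct.shape)
    return MeltingDataset.from_celsius(ct, tm_c)


@dataclass(frozen=True)
class VantHoffResult:
    """(dH, dS) from the 1/Tm versus ln(Ct/4) regression with OLS errors.

    dH in kcal/mol, dS in cal/(mol K); sigma_dH, sigma_dS likewise.
    ``corr`` is the correlation of the (dH, dS) estimates implied by the
    slope/intercept covariance -- characteristically close to +1.
    """

    dH: float
    dS: float
    sigma_dH: float
    sigma_dS: float
    corr: float
    slope: float
    intercept: float
    n: int


def vant_hoff_fit(data: MeltingDataset) -> VantHoffResult:
    """Fit 1/Tm = slope * ln(Ct/4) + intercept and convert to (dH, dS).

    slope = R/dH and intercept = dS/dH (cal units), so dH = R/slope and
    dS = intercept * dH.  Standard errors and the dH-dS correlation follow
    from the regression covariance by the delta method.
    """
    x = np.log(data.ct / 4.0)
    y = 1.0 / data.tm_K
    if np.ptp(x) <= 0:
        raise ValueError("Ct values must span a range for the regression")
    X = np.column_stack([x, np.ones_like(x)])
    coeffs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    dof = len(x) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    if slope == 0:
        raise ValueError("zero slope: dH undefined")
    dh_cal = R_CAL / slope
    ds_cal = intercept * dh_cal
    # delta method: g(slope, intercept) = (R/slope, intercept*R/slope)
    J = np.array(
        [
            [-R_CAL / slope**2, 0.0],
            [-intercept * R_CAL / slope**2, R_CAL / slope],
        ]
    )
    C = J @ cov @ J.T
    var_dh = max(C[0, 0], 0.0)
    var_ds = max(C[1, 1], 0.0)
    denom = math.sqrt(var_dh * var_ds)
    corr = float(C[0, 1] / denom) if denom > 0 else 0.0
    return VantHoffResult(
        dH=dh_cal / 1000.0,
        dS=ds_cal,
        sigma_dH=math.sqrt(var_dh) / 1000.0,
        sigma_dS=math.sqrt(var_ds),
        corr=max(-1.0, min(1.0, corr)),
        slope=slope,
        intercept=intercept,
        n=len(x),
    )
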