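"""Initial-rate extraction and Eyring activation-parameter analysis.

The observed rate constant of a product time course is the
least-squares slope of the initial linear window divided by the enzyme
concentration.  Activation parameters come from the linearized Eyring
equation

    ln(k/T) = ln(k_B/h) + ΔS‡/R − ΔH‡/(R·T),

fit by (optionally weighted) linear regression of ln(k/T) on 1/T with
the transmission coefficient fixed at 1.  ΔH‡ is reported in kcal/mol
and ΔS‡ in cal/mol/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .constants import H_SI, K_B_SI, R_KCAL

__all__ = [
    "RateMeasurement",
    "EyringFit",
    "initial_rate",
    "eyring_fit",
    "eyring_rate",
]

#: k_B/h in s⁻¹/K — the Eyring prefactor per kelvin.
KB_OVER_H = K_B_SI / H_SI


@dataclass(frozen=True)
class RateMeasurement:
    """One observed rate constant at a temperature/pH/condition."""

    temperature: float  # K
    k_obs: float  # 1/s
    se: float = 0.0
    pH: Optional[float] = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.k_obs <= 0:
            raise ValueError("k_obs must be > 0")
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass
class EyringFit:
    delta_H: float  # kcal/mol
    delta_H_se: float
    delta_S: float  # cal/mol/K
    delta_S_se: float
    temperature_range: Tuple[float, float]
    n_points: int
    diagnostics: Dict = field(default_factory=dict)

    def delta_G(self, temperature: float) -> float:
        """ΔG‡(T) = ΔH‡ − T·ΔS‡ in kcal/mol."""
        return self.delta_H - temperature * self.delta_S / 1000.0


def _linear_window(times: np.ndarray, conc: np.ndarray, alpha: float = 0.05) -> int:
    """Largest prefix whose quadratic curvature is insignificant.

    Fits c = a + b·t + q·t² on growing prefixes and returns the length
    of the largest one whose q t-statistic has p ≥ alpha.  Used to trim
    saturating time courses down to their initial linear regime.
    """
    n = len(times)
    best = 3
    for m in range(4, n + 1):
        t, c = times[:m], conc[:m]
        X = np.column_stack([np.ones(m), t, t * t])
        beta, res, *_ = np.linalg.lstsq(X, c, rcond=None)
        dof = m - 3
        if dof <= 0:
            best = m
            continue
        resid = c - X @ beta
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        tstat = beta[2] / np.sqrt(cov[2, 2]) if cov[2, 2] > 0 else 0.0
        p = 2 * stats.t.sf(abs(tstat), dof)
        if p >= alpha:
            best = m
        else:
            break
    return best


def initial_rate(
    times: Sequence[float],
    product_conc: Sequence[float],
    enzyme_conc: float,
    alpha: float = 0.05,
) -> Tuple[float, float, Dict]:
    """Observed rate constant from a product build-up time course.

    Returns (k_obs, se, diagnostics): the least-squares slope of the
    initial linear window divided by the enzyme concentration, with the
    SE propagated from the regression slope SE.  If the curve saturates
    (significant curvature), the window is trimmed and reported.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(product_conc, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 time points")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")
    m = _linear_window(times, conc, alpha)
    trimmed = m < len(times)
    if trimmed:
        warnings.warn(
            f"time course is nonlinear; using initial window of {m}/{len(times)} points"
        )
    res = stats.linregress(times[:m], conc[:m])
    k = res.slope / enzyme_conc
    se = res.stderr / enzyme_conc if np.isfinite(res.stderr) else np.nan
    return float(k), float(se), {
        "window_points": m,
        "trimmed": trimmed,
        "r_squared": float(res.rvalue**2),
        "intercept": float(res.intercept),
    }


def eyring_fit(
    measurements: Sequence[RateMeasurement],
    weighted: bool = False,
) -> EyringFit:
    """ΔH‡ and ΔS‡ from ln(k/T) vs 1/T linear regression.

    Unweighted ordinary least squares by default; ``weighted=True``
    weights points by the inverse variance of ln(k/T) propagated from
    the measurement SEs.  Two points give the exact interpolating line
    with undefined (NaN) SEs, flagged in the diagnostics.
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 measurements")
    T = np.array([m.temperature for m in measurements])
    k = np.array([m.k_obs for m in measurements])
    if T.max() - T.min() <= 0:
        raise ValueError("measurements must span a nonzero temperature range")
    x = 1.0 / T
    y = np.log(k / T)
    if weighted:
        se_log = np.array([m.se / m.k_obs if m.se > 0 else np.nan for m in measurements])
        if np.any(~np.isfinite(se_log)):
            raise ValueError("weighted fit requires positive SEs on all points")
        w = 1.0 / se_log**2
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        cov = np.linalg.inv(X.T @ W @ X)
        beta = cov @ X.T @ W @ y
        intercept, slope = beta
        se_int, se_slope = np.sqrt(np.diag(cov))
        resid = y - X @ beta
        r2 = 1.0 - float(w @ resid**2) / float(w @ (y - np.average(y, weights=w)) ** 2)
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        se_slope, se_int = res.stderr, res.intercept_stderr
        resid = y - (intercept + slope * x)
        r2 = float(res.rvalue**2)

    exact_fit = len(measurements) == 2
    dH = -slope * R_KCAL
    dS = R_KCAL * (intercept - np.log(KB_OVER_H)) * 1000.0  # cal/mol/K
    dH_se = se_slope * R_KCAL if np.isfinite(se_slope) else np.nan
    dS_se = se_int * R_KCAL * 1000.0 if np.isfinite(se_int) else np.nan
    if exact_fit:
        dH_se, dS_se = np.nan, np.nan
    return EyringFit(
        delta_H=float(dH),
        delta_H_se=float(dH_se),
        delta_S=float(dS),
        delta_S_se=float(dS_se),
        temperature_range=(float(T.min()), float(T.max())),
        n_points=len(measurements),
        diagnostics={
            "r_squared": r2,
            "residuals": resid,
            "exact_fit": exact_fit,
            "weighted": weighted,
        },
    )


def eyring_rate(delta_H: float, delta_S: float, temperature) -> np.ndarray:
    """Forward Eyring evaluation, k = (k_B·T/h)·exp(−(ΔH‡ − T·ΔS‡)/RT).

    ΔH‡ in kcal/mol, ΔS‡ in cal/mol/K, temperature in K, k in 1/s.
    """
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0")
    dG = delta_H - T * delta_S / 1000.0
    out = KB_OVER_H * T * np.exp(-dG / (R_KCAL * T))
    return out if out.ndim else float(out)
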