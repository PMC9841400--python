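"""Densitometry: nuclear protein concentration from western-blot band
intensities via a recombinant-protein standard curve.

A linear calibration (ordinary least squares of intensity on
concentration) is inverted to estimate the concentration of a query
band.  Uncertainty uses the standard first-order inverse-prediction
formula: sd(c) = (s / |slope|) * sqrt(1 + 1/n + (c - c̄)² / Sxx), with s
the residual SD of the calibration.  Estimates outside the standards'
concentration span are returned as-is with a range flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .synthetic import DensitometryData


@dataclass
class LineFit:
    """OLS standard curve with the sufficient statistics for inverse prediction."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    conc_mean: float
    sxx: float
    conc_min: float
    conc_max: float


@dataclass
class ConcentrationEstimate:
    concentration_uM: float
    sd_uM: float
    ci95_lo: float
    ci95_hi: float
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(data: DensitometryData) -> LineFit:
    """Ordinary least squares of band intensity on concentration."""
    c = np.array([s[0] for s in data.standards], dtype=np.float64)
    y = np.array([s[1] for s in data.standards], dtype=np.float64)
    if len(np.unique(c)) < 2:
        raise ValueError("all standard concentrations equal; cannot fit a line")
    n = len(c)
    cbar, ybar = c.mean(), y.mean()
    sxx = float(np.sum((c - cbar) ** 2))
    slope = float(np.sum((c - cbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * cbar)
    resid = y - (slope * c + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0
    return LineFit(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        residual_sd=residual_sd,
        n=n,
        conc_mean=float(cbar),
        sxx=sxx,
        conc_min=float(c.min()),
        conc_max=float(c.max()),
    )


def estimate_concentration(fit: LineFit, intensity_AU: float) -> ConcentrationEstimate:
    """Invert the standard curve for one query band intensity."""
    if fit.slope == 0:
        raise ValueError("slope is zero; concentration is unidentifiable")
    c = (intensity_AU - fit.intercept) / fit.slope
    sd = (abs(fit.residual_sd / fit.slope)) * float(
        np.sqrt(1.0 + 1.0 / fit.n + (c - fit.conc_mean) ** 2 / fit.sxx)
    )
    df = max(fit.n - 2, 1)
    tcrit = float(stats.t.ppf(0.975, df=df))
    flags = []
    if c < 0:
        flags.append("below_range")
    elif not (fit.conc_min <= c <= fit.conc_max):
        flags.append("extrapolated")
    return ConcentrationEstimate(
        concentration_uM=float(c),
        sd_uM=float(sd),
        ci95_lo=float(c - tcrit * sd),
        ci95_hi=float(c + tcrit * sd),
        flags=flags,
    )
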