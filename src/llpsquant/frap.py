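"""FRAP recovery kinetics: normalization, single-exponential fitting,
population summaries.

A bleached-region trace B(t) is double-normalized against a simultaneously
acquired reference-region trace R(t):

    F_norm(t) = (B(t) / R(t)) / (mean pre-bleach B / mean pre-bleach R)

which cancels acquisition photobleaching (any common multiplicative decay)
and scales the pre-bleach level to 1.  Recovery after the bleach frame is
fit with the mono-exponential model

    F(t') = f_inf - (f_inf - f0) * exp(-k * t')

with t' measured from the bleach frame and f0 fixed to the observed first
post-bleach value.  Reported quantities follow the field's conventions:
half-time t_half = ln2 / k and mobile fraction
100 * (f_inf - f0) / (f_pre - f0) with f_pre = 1 after normalization.
The mobile fraction is deliberately not clamped to [0, 100]; out-of-range
estimates carry a quality flag instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats


@dataclass
class RecoveryTrace:
    """Bleached-ROI and reference-ROI mean intensities per frame."""

    times_s: np.ndarray
    bleached_intensity: np.ndarray
    reference_intensity: np.ndarray
    n_pre_frames: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.bleached_intensity = np.asarray(self.bleached_intensity, dtype=np.float64)
        self.reference_intensity = np.asarray(self.reference_intensity, dtype=np.float64)
        n = len(self.times_s)
        if len(self.bleached_intensity) != n or len(self.reference_intensity) != n:
            raise ValueError("times, bleached and reference must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly ascending")
        if self.n_pre_frames < 1:
            raise ValueError("n_pre_frames must be >= 1")
        if self.n_pre_frames >= n:
            raise ValueError("n_pre_frames must leave post-bleach frames")


@dataclass
class NormalizedTrace:
    times_s: np.ndarray
    f_norm: np.ndarray
    n_pre_frames: int


@dataclass
class FrapFit:
    """Mono-exponential recovery fit of one double-normalized trace."""

    t_half_s: float
    mobile_fraction_pct: float
    rate_k: float
    f_pre: float
    f0: float
    f_inf: float
    rss: float
    flags: list[str] = field(default_factory=list)


@dataclass
class PopulationSummary:
    n: int
    mean: float
    ci95_lo: float
    ci95_hi: float


def normalize_trace(trace: RecoveryTrace) -> NormalizedTrace:
    """Double normalization: reference ratio then pre-bleach scaling.

    Rejects traces whose reference channel is not strictly positive.
    """
    if np.any(trace.reference_intensity <= 0):
        raise ValueError("reference intensity must be positive at every frame")
    npre = trace.n_pre_frames
    ratio = trace.bleached_intensity / trace.reference_intensity
    pre_scale = (
        trace.bleached_intensity[:npre].mean()
        / trace.reference_intensity[:npre].mean()
    )
    if pre_scale <= 0:
        raise ValueError("pre-bleach bleached-ROI mean must be positive")
    return NormalizedTrace(
        times_s=trace.times_s.copy(), f_norm=ratio / pre_scale, n_pre_frames=npre
    )


def _model(t: np.ndarray, f_inf: float, k: float, f0: float) -> np.ndarray:
    return f_inf - (f_inf - f0) * np.exp(-k * t)


def fit_recovery(norm: NormalizedTrace, max_restarts: int = 5) -> FrapFit:
    """Least-squares mono-exponential fit of the post-bleach recovery.

    f0 is fixed to the first post-bleach sample (reduces the strong
    f0/k correlation on short acquisition windows); f_inf and k are free.
    Initial k comes from a log-linear estimate; on convergence failure the
    initial guess is jittered up to ``max_restarts`` times (fixed seed).
    """
    npre = norm.n_pre_frames
    t_post = norm.times_s[npre:] - norm.times_s[npre]
    f_post = norm.f_norm[npre:]
    if len(f_post) < 5:
        raise ValueError("need >= 5 post-bleach frames to fit")
    f_pre = 1.0  # by construction of the double normalization
    f0 = float(f_post[0])
    if f_pre <= f0:
        raise ValueError("no bleach detected: first post-bleach value >= pre-bleach level")

    # log-linear initialization: log(f_inf - f) ~ log(f_inf - f0) - k t
    f_inf0 = float(np.mean(f_post[-max(3, len(f_post) // 10) :]))
    f_inf0 = max(f_inf0, f0 + 1e-3)
    resid = f_inf0 - f_post
    pos = resid > 1e-9
    if pos.sum() >= 2:
        slope = np.polyfit(t_post[pos], np.log(resid[pos]), 1)[0]
        k0 = max(-slope, 1e-3)
    else:
        k0 = 1.0

    rng = np.random.default_rng(12345)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = (f_inf0, k0)
        else:
            p0 = (
                f_inf0 * float(rng.uniform(0.8, 1.2)),
                k0 * float(rng.uniform(0.3, 3.0)),
            )
        try:
            popt, _ = optimize.curve_fit(
                lambda t, f_inf, k: _model(t, f_inf, k, f0),
                t_post,
                f_post,
                p0=p0,
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                maxfev=10000,
            )
            f_inf, k = float(popt[0]), float(popt[1])
            break
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    else:  # pragma: no cover - rare
        raise RuntimeError(
            f"recovery fit failed after {max_restarts} jittered restarts: {last_err}"
        )

    flags = []
    # Degenerate regime: when k * window << 1 the exponential is
    # indistinguishable from a line and f_inf extrapolates without bound.
    # The model then reduces to a constant; estimate the plateau as the
    # post-bleach mean instead of trusting the extrapolation.
    if k * float(t_post[-1]) < 0.15:
        f_inf = float(np.mean(f_post))
        flags.append("no_recovery_detected")
    rss = float(np.sum((_model(t_post, f_inf, k, f0) - f_post) ** 2))
    mobile = 100.0 * (f_inf - f0) / (f_pre - f0)
    if not 0.0 <= mobile <= 100.0:
        flags.append("mobile_fraction_out_of_range")
    if f_inf < f0:
        flags.append("plateau_below_bleach_floor")
    return FrapFit(
        t_half_s=float(np.log(2.0) / k),
        mobile_fraction_pct=float(mobile),
        rate_k=k,
        f_pre=f_pre,
        f0=f0,
        f_inf=f_inf,
        rss=rss,
        flags=flags,
    )


def summarize_population(
    fits: Sequence[FrapFit],
    quantity: str = "t_half_s",
    confidence: float = 0.95,
) -> PopulationSummary:
    """Mean and Student-t confidence interval across foci.

    quantity is an attribute of FrapFit ("t_half_s" or
    "mobile_fraction_pct").  The interval uses n-1 degrees of freedom,
    matching the n-foci style of population reporting.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits for a population summary")
    values = np.array([getattr(f, quantity) for f in fits], dtype=np.float64)
    n = len(values)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    return PopulationSummary(
        n=n, mean=mean, ci95_lo=mean - tcrit * sem, ci95_hi=mean + tcrit * sem
    )
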