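"""In vitro droplet quantification: fixed-range thresholding, object
counts and areas, Manders colocalization, dose-response / saturation
concentration, and turbidity summaries.

Threshold ranges follow the 16-bit-scale convention of the assay
(defaults: 550-60000 for the green channel, 300-60000 for red,
100-60000 for gray), inclusive at both ends, which removes the dilute
background phase from the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .statsreport import star_label, t_test_two_tailed

GREEN_RANGE = (550.0, 60000.0)
RED_RANGE = (300.0, 60000.0)
GRAY_RANGE = (100.0, 60000.0)


@dataclass
class ThresholdRange:
    """Inclusive intensity window selecting droplet pixels in one channel."""

    lo: float
    hi: float
    channel_role: str = "green"

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError("require 0 <= lo < hi")


@dataclass
class DropletStats:
    n_objects: int
    total_area_um2: float
    object_areas_um2: list[float]
    mean_intensity: float


@dataclass
class ColocResult:
    """Manders split coefficients over threshold-passing pixels.

    m1: fraction of green intensity residing in pixels that also pass the
    red threshold; m2 symmetric for red.  A channel with no pixels passing
    its threshold yields 0 with a warning flag.
    """

    m1: float
    m2: float
    overlap_area_um2: float
    flags: list[str] = field(default_factory=list)


def threshold_in_range(image: np.ndarray, rng: ThresholdRange) -> np.ndarray:
    """Mask of pixels with lo <= intensity <= hi (both bounds inclusive)."""
    image = np.asarray(image)
    return (image >= rng.lo) & (image <= rng.hi)


def measure_droplets(
    mask: np.ndarray, pixel_size_um: float, image: Optional[np.ndarray] = None
) -> DropletStats:
    """8-connected components of the mask, with per-object areas in μm²."""
    mask = np.asarray(mask, dtype=bool)
    if image is not None and np.asarray(image).shape != mask.shape:
        raise ValueError("mask and image shapes must match")
    labels = measure.label(mask, connectivity=2)
    areas = [float(p.area) * pixel_size_um**2 for p in measure.regionprops(labels)]
    mean_int = float(np.asarray(image)[mask].mean()) if image is not None and mask.any() else 0.0
    return DropletStats(
        n_objects=len(areas),
        total_area_um2=float(sum(areas)),
        object_areas_um2=areas,
        mean_intensity=mean_int,
    )


def manders_coloc(
    img_green: np.ndarray,
    img_red: np.ndarray,
    range_green: ThresholdRange = ThresholdRange(*GREEN_RANGE, "green"),
    range_red: ThresholdRange = ThresholdRange(*RED_RANGE, "red"),
    pixel_size_um: float = 1.0,
) -> ColocResult:
    """Intensity-weighted Manders coefficients on thresholded channels."""
    g = np.asarray(img_green, dtype=np.float64)
    r = np.asarray(img_red, dtype=np.float64)
    if g.shape != r.shape:
        raise ValueError("channel images must share a shape")
    mg = threshold_in_range(g, range_green)
    mr = threshold_in_range(r, range_red)
    both = mg & mr
    flags = []
    g_total = g[mg].sum()
    r_total = r[mr].sum()
    if g_total > 0:
        m1 = float(g[both].sum() / g_total)
    else:
        m1, flags = 0.0, flags + ["no_green_pixels_above_threshold"]
    if r_total > 0:
        m2 = float(r[both].sum() / r_total)
    else:
        m2, flags = 0.0, flags + ["no_red_pixels_above_threshold"]
    return ColocResult(
        m1=m1,
        m2=m2,
        overlap_area_um2=float(both.sum()) * pixel_size_um**2,
        flags=flags,
    )


def dose_response(
    stats_by_concentration: pd.DataFrame,
    value_col: str = "n_objects",
    blank_concentration: float = 0.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-concentration summaries with t-tests against the blank.

    Input: one row per replicate with columns ``concentration_uM`` and
    ``value_col``.  The saturation-concentration estimate is operational:
    the lowest concentration whose replicate values differ from the blank
    with p < alpha AND whose mean exceeds the blank mean; None when no
    concentration qualifies.
    """
    df = stats_by_concentration
    concs = sorted(df["concentration_uM"].unique())
    if blank_concentration not in concs:
        raise ValueError(f"missing blank/control at concentration {blank_concentration}")
    if len(concs) < 2:
        raise ValueError("need >= 2 concentrations including the blank")
    blank_vals = df.loc[df["concentration_uM"] == blank_concentration, value_col].to_numpy()
    rows = []
    c_sat: Optional[float] = None
    for c in concs:
        vals = df.loc[df["concentration_uM"] == c, value_col].to_numpy()
        if len(vals) < 2 or len(blank_vals) < 2:
            raise ValueError("need >= 2 replicates per concentration")
        if c == blank_concentration:
            t = p = np.nan
        else:
            t, p = t_test_two_tailed(vals, blank_vals)
        rows.append(
            {
                "concentration_uM": c,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "t": t,
                "p_vs_blank": p,
                "stars": star_label(p).label if np.isfinite(p) else "",
            }
        )
        if (
            c_sat is None
            and c != blank_concentration
            and np.isfinite(p)
            and p < alpha
            and vals.mean() > blank_vals.mean()
        ):
            c_sat = float(c)
    table = pd.DataFrame(rows)
    table["monotone_trend"] = bool(np.all(np.diff(table["mean"].to_numpy()) > 0))
    return table, c_sat


def turbidity_summary(
    points: pd.DataFrame,
    control: Optional[str | float] = None,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-condition OD340 mean ± SD with pairwise tests vs a control.

    Input: one row per reading with columns ``condition`` and ``od340``.
    When the conditions are numeric, a breakpoint estimate is returned:
    the condition at the start of the largest consecutive increase in
    mean OD (an operational saturation-concentration locator).  With a
    single replicate per condition the tests are skipped with a warning.
    """
    conds = list(pd.unique(points["condition"]))
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions")
    numeric = all(isinstance(c, (int, float, np.integer, np.floating)) for c in conds)
    if numeric:
        conds = sorted(conds)
    groups = {c: points.loc[points["condition"] == c, "od340"].to_numpy() for c in conds}
    can_test = all(len(v) >= 2 for v in groups.values())
    if not can_test:
        warnings.warn("single replicate in some condition; tests skipped", stacklevel=2)
    if control is None:
        control = conds[0]
    rows = []
    for c in conds:
        v = groups[c]
        row = {
            "condition": c,
            "n": len(v),
            "mean_od340": float(v.mean()),
            "sd_od340": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
        }
        if can_test and c != control:
            t, p = t_test_two_tailed(v, groups[control])
            row.update(t=t, p_vs_control=p, stars=star_label(p).label)
        else:
            row.update(t=np.nan, p_vs_control=np.nan, stars="")
        rows.append(row)
    table = pd.DataFrame(rows)
    breakpoint_est: Optional[float] = None
    if numeric and len(conds) >= 3:
        means = table["mean_od340"].to_numpy()
        jumps = np.diff(means)
        breakpoint_est = float(conds[int(np.argmax(jumps))])
    return table, breakpoint_est
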