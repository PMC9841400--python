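"""Synthetic-data generators with known ground truth.

Every downstream stage of the condensate-quantification pipeline is
exercised against data produced here: confocal-like z-stacks of nuclei
containing diffraction-limited fluorescent foci, single-exponential FRAP
recovery traces with acquisition photobleaching, two-channel droplet
fields with controllable colocalization, sigmoidal turbidity series, and
linear densitometry standard curves.

All generators are deterministic for a given spec + seed (bit-identical
repeats).  Noise is applied last — Poisson shot noise on the noiseless
image (optional) followed by additive Gaussian read noise — and pixel
values are clipped at 0 so intensities stay non-negative.

Default acquisition geometry mirrors the quantification protocols this
package models: 0.067 μm/pixel with 0.21 μm z-steps for foci counting,
0.276 μm/pixel with 0.33 μm z-steps for percent-positive imaging,
256x256-pixel droplet frames, and a 30 s FRAP window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .foci import ImageStack
from .frap import RecoveryTrace


@dataclass
class GroundTruth:
    """Generator-side truth paired with a synthetic object.

    Only the fields relevant to the paired generator are populated.
    """

    foci_per_nucleus: Optional[list[int]] = None
    focus_centroids: Optional[list[list[tuple[float, float, float]]]] = None  # (z,y,x)
    nucleus_masks: Optional[np.ndarray] = None  # labeled 2D projection, 0 = bg
    t_half_s: Optional[float] = None
    mobile_fraction_pct: Optional[float] = None
    green_centroids: Optional[list[tuple[float, float]]] = None
    red_centroids: Optional[list[tuple[float, float]]] = None
    coloc_fraction: Optional[float] = None
    slope_AU_per_uM: Optional[float] = None
    intercept_AU: Optional[float] = None
    query_concentration_uM: Optional[float] = None
    c_sat_uM: Optional[float] = None


# ---------------------------------------------------------------------------
# Foci fields
# ---------------------------------------------------------------------------


@dataclass
class FociFieldSpec:
    """Parameters of a synthetic nuclear-foci field.

    foci_per_nucleus is the ground-truth count for each nucleus.
    Intensities are arbitrary units; focus_amplitude is the peak height of
    each 3D Gaussian spot added on top of the diffuse nucleoplasmic level.
    """

    field_shape_px: tuple[int, int] = (256, 256)
    n_z: int = 9
    pixel_size_um: float = 0.067
    z_step_um: float = 0.21
    n_nuclei: int = 3
    nucleus_radius_um: float = 3.0
    foci_per_nucleus: Sequence[int] = (5, 5, 5)
    focus_sigma_um: float = 0.1
    focus_amplitude: float = 1000.0
    nucleoplasm_level: float = 100.0
    background_level: float = 10.0
    read_noise_sd: float = 0.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_shape_px) <= 0 or self.n_z <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel geometry must be positive")
        if len(self.foci_per_nucleus) != self.n_nuclei:
            raise ValueError("foci_per_nucleus must have n_nuclei entries")
        if any(c < 0 for c in self.foci_per_nucleus):
            raise ValueError("foci counts must be non-negative")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place objects in the field."""


def _place_nuclei(spec: FociFieldSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    r_px = spec.nucleus_radius_um / spec.pixel_size_um
    h, w = spec.field_shape_px
    margin = r_px + 2
    if 2 * margin >= h or 2 * margin >= w:
        raise PlacementError("nucleus radius too large for the field")
    centers: list[tuple[float, float]] = []
    for _ in range(spec.n_nuclei):
        for _attempt in range(1000):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 > (2 * r_px + 4) ** 2 for cy, cx in centers):
                centers.append((y, x))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_nuclei} nuclei of radius "
                f"{spec.nucleus_radius_um} um after 1000 retries; field too dense"
            )
    return centers


def _place_foci_in_nucleus(
    center: tuple[float, float],
    r_px: float,
    n_foci: int,
    n_z: int,
    min_sep_px: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, float]]:
    cy, cx = center
    pts: list[tuple[float, float, float]] = []
    for _ in range(n_foci):
        for _attempt in range(2000):
            rho = 0.85 * r_px * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            y = cy + rho * np.sin(theta)
            x = cx + rho * np.cos(theta)
            z = rng.uniform(0.25 * (n_z - 1), 0.75 * (n_z - 1))
            if all((y - p[1]) ** 2 + (x - p[2]) ** 2 > min_sep_px**2 for p in pts):
                pts.append((z, y, x))
                break
        else:
            raise PlacementError(
                f"could not place {n_foci} separable foci inside a nucleus of "
                f"radius {r_px:.1f} px"
            )
    return pts


def make_foci_field(spec: FociFieldSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a 2-channel (nuclear stain, green) z-stack with known foci counts.

    Each nucleus is a non-overlapping ellipsoid (disc in projection) and
    contains exactly the requested number of 3D Gaussian spots (sigma_xy =
    focus_sigma_um, sigma_z = 2*sigma_xy, axial PSF elongation) on a
    diffuse nucleoplasmic green background.  Spots within a nucleus keep a
    minimum separation of 6 sigma_xy so their count is well defined.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_shape_px
    r_px = spec.nucleus_radius_um / spec.pixel_size_um
    sigma_xy = spec.focus_sigma_um / spec.pixel_size_um
    sigma_z = 2.0 * spec.focus_sigma_um / spec.z_step_um

    centers = _place_nuclei(spec, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    nucleus_labels = np.zeros((h, w), dtype=int)
    for i, (cy, cx) in enumerate(centers):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        nucleus_labels[disc] = i + 1

    # Nuclear-stain channel: bright discs over background, constant in z
    # across the central 80% of slices (ellipsoidal cap ignored).
    nuc2d = np.where(nucleus_labels > 0, 10.0 * spec.background_level + 100.0,
                     spec.background_level)
    nuc = np.broadcast_to(nuc2d, (spec.n_z, h, w)).copy()

    green = np.full((spec.n_z, h, w), spec.background_level, dtype=np.float64)
    green[:, nucleus_labels > 0] += spec.nucleoplasm_level - spec.background_level

    centroids: list[list[tuple[float, float, float]]] = []
    min_sep = max(6.0 * sigma_xy, 3.0)
    zz = np.arange(spec.n_z, dtype=np.float64)
    for i, (cy, cx) in enumerate(centers):
        pts = _place_foci_in_nucleus(
            (cy, cx), r_px, int(spec.foci_per_nucleus[i]), spec.n_z, min_sep, rng
        )
        centroids.append(pts)
        for (z0, y0, x0) in pts:
            # render in a local window to keep cost bounded
            half = int(np.ceil(4 * sigma_xy)) + 1
            ylo, yhi = max(0, int(y0) - half), min(h, int(y0) + half + 1)
            xlo, xhi = max(0, int(x0) - half), min(w, int(x0) + half + 1)
            ys = np.arange(ylo, yhi)[:, None]
            xs = np.arange(xlo, xhi)[None, :]
            g_xy = np.exp(
                -((ys - y0) ** 2 + (xs - x0) ** 2) / (2 * sigma_xy**2)
            )
            g_z = np.exp(-((zz - z0) ** 2) / (2 * sigma_z**2))
            green[:, ylo:yhi, xlo:xhi] += (
                spec.focus_amplitude * g_z[:, None, None] * g_xy[None, :, :]
            )

    stack = np.stack([nuc, green]).astype(np.float64)
    if spec.shot_noise:
        stack = rng.poisson(stack).astype(np.float64)
    if spec.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.read_noise_sd, size=stack.shape)
    stack = np.clip(stack, 0.0, None)

    truth = GroundTruth(
        foci_per_nucleus=[int(c) for c in spec.foci_per_nucleus],
        focus_centroids=centroids,
        nucleus_masks=nucleus_labels,
    )
    image = ImageStack(
        voxels=stack,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
        channel_names=["nuclei", "green"],
    )
    return image, truth


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


@dataclass
class FrapTraceSpec:
    """Single-exponential FRAP recovery with acquisition photobleaching.

    The bleach is instantaneous at frame n_pre_frames.  After the bleach,
    F(t') = F_inf - (F_inf - F0) * exp(-t' * ln2 / t_half_s) where
    F0 = pre_bleach_level * (1 - bleach_depth_fraction) and F_inf encodes
    the mobile fraction.  Both the bleached and reference traces decay by
    exp(-acquisition_decay_rate * t); multiplicative Gaussian noise of
    relative SD noise_sd is applied to every frame of both channels.
    """

    t_half_s: float = 3.8
    mobile_fraction_pct: float = 51.0
    pre_bleach_level: float = 1000.0
    bleach_depth_fraction: float = 0.7
    n_pre_frames: int = 5
    duration_s: float = 30.0
    frame_interval_s: float = 0.5
    acquisition_decay_rate: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half_s <= 0:
            raise ValueError("t_half_s must be positive")
        if not 0 <= self.mobile_fraction_pct <= 100:
            raise ValueError("mobile_fraction_pct must be in [0, 100]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_interval_s >= self.duration_s:
            raise ValueError("frame_interval_s must be smaller than duration_s")
        if not 0 < self.bleach_depth_fraction <= 1:
            raise ValueError("bleach_depth_fraction must be in (0, 1]")
        if self.n_pre_frames < 1:
            raise ValueError("n_pre_frames must be >= 1")


def make_frap_trace(spec: FrapTraceSpec) -> tuple[RecoveryTrace, GroundTruth]:
    """Generate one bleached-ROI + reference-ROI FRAP time series."""
    rng = np.random.default_rng(spec.seed)
    n_post = int(round(spec.duration_s / spec.frame_interval_s))
    n_frames = spec.n_pre_frames + n_post
    times = np.arange(n_frames) * spec.frame_interval_s

    f_pre = spec.pre_bleach_level
    f0 = f_pre * (1.0 - spec.bleach_depth_fraction)
    f_inf = f0 + (spec.mobile_fraction_pct / 100.0) * (f_pre - f0)
    k = np.log(2.0) / spec.t_half_s

    bleached = np.empty(n_frames)
    bleached[: spec.n_pre_frames] = f_pre
    t_post = times[spec.n_pre_frames :] - times[spec.n_pre_frames]
    bleached[spec.n_pre_frames :] = f_inf - (f_inf - f0) * np.exp(-k * t_post)
    reference = np.full(n_frames, f_pre)

    decay = np.exp(-spec.acquisition_decay_rate * times)
    bleached = bleached * decay
    reference = reference * decay

    if spec.noise_sd > 0:
        bleached = bleached * (1.0 + rng.normal(0.0, spec.noise_sd, n_frames))
        reference = reference * (1.0 + rng.normal(0.0, spec.noise_sd, n_frames))
    bleached = np.clip(bleached, 0.0, None)
    reference = np.clip(reference, 1e-12, None)

    trace = RecoveryTrace(
        times_s=times,
        bleached_intensity=bleached,
        reference_intensity=reference,
        n_pre_frames=spec.n_pre_frames,
    )
    truth = GroundTruth(
        t_half_s=spec.t_half_s, mobile_fraction_pct=spec.mobile_fraction_pct
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Droplet fields
# ---------------------------------------------------------------------------


@dataclass
class DropletFieldSpec:
    """Two-channel in vitro droplet field with controllable colocalization.

    A coloc_fraction share of the green droplets are co-centred on red
    droplets; the remainder are placed apart.  Default disc intensities sit
    above the standard analysis threshold ranges (green 550, red 300 on a
    16-bit-like scale).
    """

    frame_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.207
    n_green: int = 20
    n_red: int = 20
    droplet_radius_um: float | tuple[float, float] = 0.6
    coloc_fraction: float = 0.0
    intensity_green: float = 5000.0
    intensity_red: float = 3000.0
    background: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.n_green < 0 or self.n_red < 0:
            raise ValueError("droplet counts must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class DropletImage:
    """Two-channel 2D droplet image (channels: green, red)."""

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float


def _sample_radius(spec: DropletFieldSpec, rng: np.random.Generator) -> float:
    r = spec.droplet_radius_um
    if isinstance(r, tuple):
        return rng.uniform(r[0], r[1]) / spec.pixel_size_um
    return float(r) / spec.pixel_size_um


def make_droplet_image(spec: DropletFieldSpec) -> tuple[DropletImage, GroundTruth]:
    """Render green/red droplet discs; seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_px
    yy, xx = np.mgrid[0:h, 0:w]
    green = np.full((h, w), spec.background, dtype=np.float64)
    red = np.full((h, w), spec.background, dtype=np.float64)

    max_r = _max_radius_px(spec)
    margin = max_r + 2
    min_sep = 2 * max_r + 4

    def place(existing: list[tuple[float, float]], avoid: list[tuple[float, float]]) -> tuple[float, float]:
        for _attempt in range(2000):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - p[0]) ** 2 + (x - p[1]) ** 2 > min_sep**2 for p in existing + avoid):
                return (y, x)
        raise PlacementError("could not place droplets; field too dense")

    red_centers: list[tuple[float, float]] = []
    for _ in range(spec.n_red):
        red_centers.append(place(red_centers, []))

    n_coloc = int(round(spec.coloc_fraction * spec.n_green))
    n_coloc = min(n_coloc, spec.n_red, spec.n_green)
    coloc_hosts = list(rng.choice(len(red_centers), size=n_coloc, replace=False)) if n_coloc else []

    green_centers: list[tuple[float, float]] = [red_centers[i] for i in coloc_hosts]
    free_green: list[tuple[float, float]] = []
    for _ in range(spec.n_green - n_coloc):
        c = place(free_green, red_centers + green_centers)
        free_green.append(c)
    green_centers = green_centers + free_green

    def draw(img: np.ndarray, centers: list[tuple[float, float]], level: float) -> None:
        for (cy, cx) in centers:
            r = _sample_radius(spec, rng)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            img[disc] = level

    draw(red, red_centers, spec.intensity_red)
    draw(green, green_centers, spec.intensity_green)

    if spec.noise_sd > 0:
        green = green + rng.normal(0.0, spec.noise_sd, green.shape)
        red = red + rng.normal(0.0, spec.noise_sd, red.shape)
    green = np.clip(green, 0.0, None)
    red = np.clip(red, 0.0, None)

    truth = GroundTruth(
        green_centroids=green_centers,
        red_centroids=red_centers,
        coloc_fraction=(n_coloc / spec.n_green) if spec.n_green else 0.0,
    )
    return DropletImage(green=green, red=red, pixel_size_um=spec.pixel_size_um), truth


def _max_radius_px(spec: DropletFieldSpec) -> float:
    r = spec.droplet_radius_um
    r_um = r[1] if isinstance(r, tuple) else r
    return r_um / spec.pixel_size_um


# ---------------------------------------------------------------------------
# Turbidity series and densitometry standard curves
# ---------------------------------------------------------------------------


@dataclass
class TurbiditySeries:
    """OD340 readings along an ascending concentration grid (one replicate set)."""

    concentrations_uM: np.ndarray
    od340: np.ndarray


def make_turbidity_series(
    c_grid_uM: Sequence[float],
    c_sat_uM: float,
    plateau_od: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_od: float = 0.02,
    rise_scale_uM: Optional[float] = None,
) -> tuple[TurbiditySeries, GroundTruth]:
    """Turbidity (OD at 340 nm) versus concentration around a saturation point.

    OD stays at baseline below c_sat and rises exponentially toward the
    plateau above it; the noiseless construction is non-decreasing in c.
    The rise scale defaults to c_sat itself (one concentration scale past
    saturation reaches ~63% of the plateau), matching the step-like onset
    of droplet formation on a log-spaced dilution series.
    """
    c = np.asarray(c_grid_uM, dtype=np.float64)
    if c.ndim != 1 or len(c) < 2 or np.any(np.diff(c) <= 0):
        raise ValueError("c_grid_uM must be ascending with >= 2 points")
    if not (c[0] <= c_sat_uM <= c[-1]):
        raise ValueError("c_sat_uM must lie within the grid span")
    rng = np.random.default_rng(seed)
    if rise_scale_uM is None:
        rise_scale_uM = c_sat_uM if c_sat_uM > 0 else float(c[1] - c[0])
    rise_scale = max(rise_scale_uM, 1e-9)
    od = np.where(
        c < c_sat_uM,
        baseline_od,
        baseline_od + (plateau_od - baseline_od) * (1.0 - np.exp(-(c - c_sat_uM) / rise_scale)),
    )
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return TurbiditySeries(concentrations_uM=c, od340=od), GroundTruth(c_sat_uM=c_sat_uM)


@dataclass
class DensitometryData:
    """Western-blot band intensities: calibration standards plus query bands."""

    standards: list[tuple[float, float]]  # (concentration_uM, intensity_AU)
    query_bands: list[float]

    def __post_init__(self) -> None:
        concs = {c for c, _ in self.standards}
        if len(concs) < 2:
            raise ValueError("need >= 2 distinct standard concentrations")
        if any(i < 0 for _, i in self.standards) or any(i < 0 for i in self.query_bands):
            raise ValueError("intensities must be non-negative")


def make_standard_curve(
    slope_AU_per_uM: float,
    intercept_AU: float,
    conc_points_uM: Sequence[float],
    noise_rel: float = 0.0,
    seed: int = 0,
    query_concentration_uM: Optional[float] = None,
) -> tuple[DensitometryData, GroundTruth]:
    """Linear densitometry standards with a held-out query band.

    Standard intensities are slope*c + intercept with relative Gaussian
    noise; the query band is generated at query_concentration_uM (default:
    midpoint of the standards' span) and recorded in GroundTruth.
    """
    c = np.asarray(conc_points_uM, dtype=np.float64)
    if len(np.unique(c)) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    rng = np.random.default_rng(seed)
    clean = slope_AU_per_uM * c + intercept_AU
    noisy = clean * (1.0 + rng.normal(0.0, noise_rel, size=c.shape)) if noise_rel > 0 else clean
    if query_concentration_uM is None:
        query_concentration_uM = float((c.min() + c.max()) / 2.0)
    q_clean = slope_AU_per_uM * query_concentration_uM + intercept_AU
    q = q_clean * (1.0 + rng.normal(0.0, noise_rel)) if noise_rel > 0 else q_clean
    data = DensitometryData(
        standards=[(float(ci), float(max(ii, 0.0))) for ci, ii in zip(c, noisy)],
        query_bands=[float(max(q, 0.0))],
    )
    truth = GroundTruth(
        slope_AU_per_uM=slope_AU_per_uM,
        intercept_AU=intercept_AU,
        query_concentration_uM=query_concentration_uM,
    )
    return data, truth
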