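# Methods

This note documents the models, estimators and design choices behind
llpsquant, and what the synthetic-data studies do and do not demonstrate
about real data.

## Foci detection and per-nucleus counting

Analysis is two-dimensional on the maximum-intensity z-projection of the
fluorophore channel, mirroring the macro-style workflows used with
commercial confocal software; no 3D segmentation or deconvolution is
attempted.  Since commercial "adaptive threshold" implementations are
proprietary, segmentation uses the standard local-statistics rule: a
pixel is foreground iff its intensity exceeds the local mean plus
`k` local standard deviations, computed over a square window with
reflective padding.  Defaults: window 15 px (≈1 μm at the 0.067 μm/px
counting geometry, comfortably wider than a diffraction-limited focus)
and `k = 3`.  A contrast floor of 1e−9 of the dynamic range guards
locally constant regions against round-off in the running moments.
Absolute foci counts on real images depend on these parameters, which
the original acquisition software does not expose; both are
configuration fields, and correctness is assessed by ground-truth
recovery rather than by matching any particular absolute count.

Foci are 8-connected components with no minimum-area filter by default
(area filter set to zero so single-pixel detections count).  Nuclei are
segmented on the nuclear-stain projection by a global threshold (a fixed
value, or Otsu when unattended), hole-filled, 4-connected (reduces
chain-merging of adjacent nuclei), with border-touching components
removed by default because counts in clipped nuclei are biased low.
Each focus is assigned to the nucleus whose mask contains its centroid
rounded to the nearest pixel; foci outside every nucleus stay
unassigned and never enter nuclear counts, so the conservation identity
(assigned + unassigned = detected) holds exactly.  A nucleus is
foci-positive iff it contains at least the cutoff number of foci
(default 20, inclusive).

## FRAP model

Recovery is modelled as a single exponential.  The reported quantities
(half-time, mobile fraction) are exactly that model's parameters, and
mono-exponential fitting is the default of the commercial FRAP modules
this pipeline emulates; no diffusion-geometry (Soumpasis-type) model is
fit.  Double normalization divides the bleached-ROI trace by the
simultaneously acquired reference-ROI trace — removing any common
multiplicative acquisition decay identically, which the tests verify to
1e−9 — and scales by the ratio of pre-bleach means so the pre-bleach
level is 1 by construction.

The fit fixes `f0` to the observed first post-bleach frame rather than
fitting it: on short (30 s) windows the `f0`–`k` correlation otherwise
inflates variance.  `f_inf` and `k` are free; `k` is initialized from a
log-linear regression of `log(f_inf0 − F)` on time and refined by
Levenberg–Marquardt, with up to five jittered restarts from a fixed
restart seed on convergence failure.  The mobile fraction
`100·(f_inf − f0)/(1 − f0)` is not clamped; values outside [0, 100] are
returned with a quality flag.

When essentially no recovery occurs within the window
(`k·T_window < 0.15`), the exponential degenerates into a line and
`f_inf` extrapolates without bound.  The model then reduces to a
constant, so the plateau is estimated as the post-bleach mean and the
fit is flagged `no_recovery_detected`.  This keeps the immobile limit
unbiased (fitted mobile fraction within ±3 percentage points of 0 at 2%
noise) at the cost of an uninformative half-time in that regime.

Population summaries use the mean with a Student-t interval on n−1
degrees of freedom across foci, matching the "n foci from m cells" style
of reporting; per-fit covariance is not propagated into the population
interval.  Traces that never recover are included in population
averages by default (the filter is a flag), since the study-level
immobile fraction is part of the biology being summarized.

## Droplet quantification

Threshold ranges are inclusive at both ends (the assay convention writes
ranges without stating inclusivity; inclusive is assumed and tested at
the exact boundary values 550 and 60 000).  Intensities are treated as
16-bit-scale arbitrary units and never rescaled.  The colocalization
coefficient is implemented as intensity-weighted Manders split
coefficients restricted to threshold-passing pixels — the standard
choice in confocal colocalization once background is range-gated — with
the dual-passing pixel count also reported as an overlap area for an
area-based reading.  A channel with no pixels above threshold yields a
coefficient of 0 with a warning flag rather than a division error.

The saturation concentration is defined operationally: the lowest
concentration whose replicate droplet counts are significantly above
the blank (two-tailed Student's t, α = 0.05) with a higher mean.  The
turbidity breakpoint locator returns the condition at the start of the
largest consecutive increase in mean OD340 on an ordered numeric grid;
on the generator's series it recovers the true saturation point within
one grid step.

## Densitometry

Calibration is linear (ordinary least squares of band intensity on
loaded concentration); a log-log option was considered unnecessary
because blot densitometry is used within its linear response range.
Inverse prediction uses the first-order formula
`sd(c) = (s/|slope|)·sqrt(1 + 1/n + (c − c̄)²/Sxx)` with a t-based 95%
interval; 500-seed simulations at 2% noise show coverage consistent
with 0.95.  Estimates below zero or beyond the standards' span carry
`below_range`/`extrapolated` flags but are returned unmodified.

## Statistics

One-way ANOVA and pooled-variance Student's t-tests (Welch behind a
flag) delegate to scipy; tests validate them against independently coded
sum-of-squares and pooled-variance oracles, the F = t² identity for two
groups, and a 1000-run null simulation of the type-I error rate.  Star
bins are half-open, `[lo, hi)`, consistent with "ns ≥ 0.05" anchoring
the top bin; the boundary p = 0.05 is therefore "ns" and p = 0.01 earns
a single star.  No multiple-testing correction is applied by default
(a Bonferroni helper exists) since none is used in the reporting style
being reproduced.

## Synthetic data: what it emulates and what it does not

Generators default to the study acquisition geometries: 0.067 μm/px with
0.21 μm z-steps (counting), 0.276 μm/px with 0.33 μm z-steps
(percent-positive imaging), 256×256 droplet frames, 30 s FRAP windows at
0.5 s sampling with 5 pre-bleach frames.  Nuclei are non-overlapping
ellipsoids placed by rejection sampling (bounded retries, explicit
failure when the field is too dense); foci are 3D Gaussians with
σ_xy = 0.1 μm and σ_z = 2σ_xy (axial PSF elongation), kept ≥ 6σ_xy
apart inside a nucleus so the ground-truth count is well defined.
Noise is Poisson shot noise on the noiseless image followed by additive
Gaussian read noise, clipped at zero; FRAP traces carry multiplicative
Gaussian noise (default σ = 0.03, a typical confocal ROI-mean noise
level — the source imaging reports no SNR, so this is a calibration
choice) on both channels plus an optional shared acquisition-decay
exponential.  The FRAP bleach is instantaneous at the bleach frame; the
real ~16 ms bleach pulse is negligible against 0.5 s frame intervals.
Turbidity series rise exponentially above the saturation concentration
with a rise scale defaulting to c_sat itself, giving the step-like onset
seen on log-spaced dilution series.

These simulations validate the estimators, not the optics: there is no
real PSF, no focal drift, no nuclear heterogeneity, no out-of-focus
haze, and droplets are hard discs.  Passing recovery tests therefore
shows that the measurement chain is unbiased and consistent under the
stated noise model, not that any particular biological image will yield
the same absolute counts.

## Problem sizes

Test and analysis runs use field sizes of 256–512 px, 5–9 z-slices,
2–5 nuclei per field, FRAP cohorts of 10–100 traces, 50-seed
colocalization and 500-seed coverage studies — sizes chosen so a full
desk run of the suite completes in well under a minute per module while
leaving the statistical assertions well powered.
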