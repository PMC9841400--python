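# llpsquant

Quantification toolkit for liquid-like biomolecular condensates, built
around the measurements used to characterize nuclear foci formed by the
androgen receptor (AR) and its coactivator MED1 in prostate-cancer cell
models: per-nucleus foci counting on confocal z-stacks, foci-positive
cell classification, FRAP recovery kinetics, in vitro droplet and
turbidity assays, densitometry-based concentration estimation, and the
accompanying statistical reporting.  Every stage can be exercised on
synthetic data with known ground truth, so the whole pipeline is testable
without microscope access.

## What it computes

**Foci counting.** A multi-channel z-stack is reduced by
maximum-intensity projection of the fluorophore channel; diffraction-
limited puncta are segmented by adaptive local thresholding (foreground
iff `I > mean_w + k*sd_w` over a window w, default 15 px at
0.067 μm/px), labelled 8-connected with no minimum-area filter, and
assigned to globally-thresholded nuclear ROIs by centroid containment.
A nucleus with at least 20 foci is classified foci-positive; fields are
summarized as percent-positive and mean foci per nucleus.

**FRAP kinetics.** Bleached-ROI traces are double-normalized against a
reference region, `F(t) = (B(t)/R(t)) / (B̄_pre/R̄_pre)`, cancelling
acquisition photobleaching and scaling the pre-bleach level to 1.
Recovery is fit with the mono-exponential model
`F(t′) = f_∞ − (f_∞ − f₀)·e^(−k t′)` (f₀ fixed to the first post-bleach
frame), reporting half-time `t_half = ln2/k` and mobile fraction
`100·(f_∞ − f₀)/(1 − f₀)`.  Populations of foci are summarized with
Student-t 95% confidence intervals.

**Droplets, colocalization, turbidity.** In vitro droplet images are
thresholded with inclusive intensity ranges (green 550–60 000, red
300–60 000, gray 100–60 000), measured as 8-connected objects with areas
in μm², and compared across channels with intensity-weighted Manders
coefficients M1/M2.  Dose-response tables estimate the saturation
concentration as the lowest concentration significantly above the blank;
turbidity (OD 340 nm) series are summarized per condition with a
breakpoint locator.

**Densitometry.** Band intensities of a recombinant-protein dilution
series are fit by OLS; query-band concentrations come from inverting the
standard curve with first-order inverse-prediction uncertainty.

**Statistics.** One-way ANOVA and two-tailed unpaired Student's t-tests
with the conventional star annotation (ns ≥ 0.05, * 0.01–0.05,
** 0.001–0.01, *** 0.0001–0.001, **** < 0.0001).

## Worked example

Simulate a cohort of 21 noisy FRAP traces at known kinetics
(t_half = 3.80 s, mobile fraction = 51.01%) and recover the population
parameters:

```python
from llpsquant.protocols import frap_cohort

res = frap_cohort(21, 3.80, 51.01, seed=2026, noise_sd=0.03)
print(f"t_half {res.t_half.mean:.2f} s [{res.t_half.ci95_lo:.2f}, {res.t_half.ci95_hi:.2f}]")
print(f"mobile {res.mobile.mean:.2f}% [{res.mobile.ci95_lo:.2f}, {res.mobile.ci95_hi:.2f}]")
```

prints

```
t_half 3.96 s [3.80, 4.12]
mobile 51.09% [50.28, 51.90]
```

i.e. the fitted population mean half-time and mobile fraction recover the
generating kinetics to within a few percent, with the 95% CI quantifying
the cohort's sampling spread.  The numbered drivers under `analysis/`
run the same kind of study for every stage (foci counting, FRAP,
droplets/turbidity, densitometry, statistics) and write their tables
under `results/`:

```bash
python analysis/01_foci_counting.py
python analysis/02_frap_kinetics.py
...
```

A thin CLI mirrors the library for shell use, e.g.
`llpsquant simulate frap --out-dir traces --n-traces 3` followed by
`llpsquant frap fit --in traces --out fits`.

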