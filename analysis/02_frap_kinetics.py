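#!/usr/bin/env python
"""FRAP parameter recovery at the three study kinetic regimes.

Simulates noisy bleach-trace cohorts at the population kinetics measured
for AR foci (t_half 3.80 s, mobile 51.01%, n = 21), MED1 foci (3.08 s,
96.26%, n = 24) and in vitro AR droplets (4 s, 55%, 50-frame records),
double-normalizes each trace, fits the mono-exponential recovery, and
summarizes each cohort with Student-t 95% CIs.  Writes
results/frap_populations.csv.
"""

from pathlib import Path

import pandas as pd

from llpsquant.protocols import frap_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

COHORTS = {
    "AR_foci": dict(n=21, t_half=3.80, mobile=51.01, duration=30.0),
    "MED1_foci": dict(n=24, t_half=3.08, mobile=96.26, duration=30.0),
    "in_vitro_droplets": dict(n=10, t_half=4.0, mobile=55.0, duration=22.5),
}

rows = []
for name, c in COHORTS.items():
    res = frap_cohort(
        c["n"], c["t_half"], c["mobile"], seed=2026, duration_s=c["duration"],
        noise_sd=0.03,
    )
    rows.append(
        {"cohort": name, "n": c["n"],
         "true_t_half_s": c["t_half"], "fit_t_half_s": res.t_half.mean,
         "t_half_ci_lo": res.t_half.ci95_lo, "t_half_ci_hi": res.t_half.ci95_hi,
         "true_mobile_pct": c["mobile"], "fit_mobile_pct": res.mobile.mean,
         "mobile_ci_lo": res.mobile.ci95_lo, "mobile_ci_hi": res.mobile.ci95_hi}
    )
    print(
        f"{name}: t_half {res.t_half.mean:.2f} s "
        f"[{res.t_half.ci95_lo:.2f}, {res.t_half.ci95_hi:.2f}] (truth {c['t_half']}); "
        f"mobile {res.mobile.mean:.2f}% "
        f"[{res.mobile.ci95_lo:.2f}, {res.mobile.ci95_hi:.2f}] (truth {c['mobile']})"
    )

pd.DataFrame(rows).to_csv(OUT / "frap_populations.csv", index=False)
print(f"table written to {OUT / 'frap_populations.csv'}")
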