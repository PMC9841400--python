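#!/usr/bin/env python
"""Per-nucleus foci counting and percent-positive classification on
synthetic confocal fields.

Simulates z-stack fields of nuclei holding known numbers of
diffraction-limited green foci at the counting acquisition geometry
(0.067 um/px, 0.21 um z-step), runs the projection / adaptive-threshold /
per-nucleus counting pipeline, and compares measured counts against the
generator's ground truth.  Writes results/foci_nuclei.csv and
results/foci_fields.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from llpsquant.foci import analyze_stack
from llpsquant.synthetic import FociFieldSpec, make_foci_field

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

nuc_rows, field_rows = [], []
rng = np.random.default_rng(20260930)
for field_id in range(10):
    counts = tuple(int(c) for c in rng.integers(0, 31, size=3))
    spec = FociFieldSpec(
        field_shape_px=(512, 512), n_z=9, n_nuclei=3,
        foci_per_nucleus=counts, nucleus_radius_um=4.0, seed=field_id,
    )
    stack, truth = make_foci_field(spec)
    _, records, summary = analyze_stack(stack)
    measured = sorted(r.foci_count for r in records)
    expected = sorted(truth.foci_per_nucleus)
    for r, t in zip(measured, expected):
        nuc_rows.append(
            {"field": field_id, "true_count": t, "measured_count": r,
             "exact": r == t, "positive": r >= 20}
        )
    field_rows.append(
        {"field": field_id, "n_nuclei": summary.n_nuclei,
         "percent_positive": summary.percent_positive,
         "true_percent_positive": 100.0 * sum(c >= 20 for c in counts) / len(counts),
         "mean_foci_per_nucleus": summary.mean_foci_per_nucleus}
    )

nuclei = pd.DataFrame(nuc_rows)
fields = pd.DataFrame(field_rows)
nuclei.to_csv(OUT / "foci_nuclei.csv", index=False)
fields.to_csv(OUT / "foci_fields.csv", index=False)

exact_rate = nuclei["exact"].mean()
agree = (fields["percent_positive"] == fields["true_percent_positive"]).mean()
print(f"nuclei analysed: {len(nuclei)} across {len(fields)} fields")
print(f"exact per-nucleus count recovery: {100 * exact_rate:.1f}%")
print(f"fields with percent-positive matching ground truth: {100 * agree:.1f}%")
print(f"tables written to {OUT}")
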