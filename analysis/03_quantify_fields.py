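#!/usr/bin/env python
"""Benchmark the field quantifier against rendered ground truth.

Renders 100 non-overlapping high-SNR fields (25 cells, 40% aggregate
fraction), counts nuclei and aggregates, and tabulates how many fields are
recovered exactly. Writes per-field results to results/analysis/.
"""

from pathlib import Path

import pandas as pd

from polyqscreen.config import FieldSimConfig
from polyqscreen.image_quant import count_nuclei, detect_aggregates
from polyqscreen.simulate import render_field

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for seed in range(100):
    field = render_field(FieldSimConfig(n_cells=25, aggregate_fraction=0.4,
                                        seed=seed))
    n, _, _ = count_nuclei(field.nuclei_channel)
    a, _, _ = detect_aggregates(field.gfp_channel)
    rows.append({"seed": seed, "true_nuclei": field.n_cells, "found_nuclei": n,
                 "true_aggregates": field.n_aggregates, "found_aggregates": a,
                 "exact": n == field.n_cells and a == field.n_aggregates})
df = pd.DataFrame(rows)
df.to_csv(OUT / "field_quantification.csv", index=False)

n_exact = int(df["exact"].sum())
print(f"{n_exact}/100 fields recovered with exactly correct nucleus and "
      f"aggregate counts")
print(f"nucleus count error: mean {abs(df.found_nuclei - df.true_nuclei).mean():.3f}; "
      f"aggregate count error: mean "
      f"{abs(df.found_aggregates - df.true_aggregates).mean():.3f}")
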