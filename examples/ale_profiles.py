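"""Accumulated-local-effects profiles for a published equation.

Evaluates the top-binder ERalpha model over a synthetic descriptor cloud
whose per-descriptor spreads equal the SDs implied by the published
normalized/raw coefficient ratios, and ranks descriptors by the span of
their ALE curve (Delta predicted pIC50 across the observed range).
"""

import pandas as pd

from pfaser import ale_summary, load_published_model, pfas_like_spec
from pfaser.synthetic import generate_descriptors

model = load_published_model("TB-ERalpha")

base = generate_descriptors(pfas_like_spec(n_ligands=2000, seed=3))
base = base / base.std(ddof=1)
implied_sd = pd.Series(model.descriptor_sds, index=model.descriptor_names)
table = base[model.descriptor_names] * implied_sd

profiles = ale_summary(model, table, grid_size=20)
print("descriptor                            ALE width (Delta pIC50)")
for p in profiles:
    lo, hi = p.delta_range
    print(f"  {p.descriptor:36s} {p.width:7.3f}  [{lo:+.2f}, {hi:+.2f}]")
print("\nThe width is the full swing in predicted pIC50 as one descriptor")
print("sweeps its observed range while the others stay at realistic values;")
print("for a linear model it equals |coefficient| x descriptor range, so the")
print("ranking mirrors the normalized-coefficient magnitudes.")
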