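"""Fit a descriptor -> pIC50 regression and check its applicability domain.

Generates the default synthetic study conditions (69 ligands, 11 correlated
descriptors, noise 0.35 pIC50), fits OLS, reports fit and leave-one-out
metrics, and classifies every ligand on the Williams plane.
"""

from pfaser import (
    applicability_domain,
    cross_validate_q2,
    fit_ols,
    pfas_like_spec,
)
from pfaser.synthetic import generate_dataset

dataset = generate_dataset(pfas_like_spec(n_ligands=69, seed=11))
X, y = dataset.descriptor_table, dataset.observed_pic50

model = fit_ols(X, y)
q2 = cross_validate_q2(X, y)
m = model.metrics
print(f"training fit: R2 {m.r2:.3f}, RMSE {m.rmse:.3f}, MAE {m.mae:.3f} (pIC50)")
print(f"leave-one-out Q2 {q2:.3f} (predictive ability under cross-validation)")

ad = applicability_domain(model, X, y)
print(f"\ncritical leverage h* = 3(M+1)/N = {ad.h_star:.3f} "
      f"(M={X.shape[1]} descriptors, N={len(X)} compounds)")
print("domain classification counts:", ad.counts)
print("\nLigands beyond |standardized residual| > 3 are poorly predicted;")
print("ligands beyond h* sit outside the training chemistry, so their")
print("predictions are low-confidence even when the residual is small.")
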