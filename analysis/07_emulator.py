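"""Cross-validated skill of the PLS+CCA emulator on the flood model."""

import numpy as np
import pandas as pd
from common import RESULTS, SEED, N_UNIONS

from deltasim.flood import fit_emulator, predict_emulator, simulate_flood
from deltasim.synthregion import make_region

rng = np.random.default_rng(SEED)
cells = make_region(SEED, N_UNIONS)

n = 200
X = np.column_stack(
    [
        rng.uniform(0.0, 100.0, n),      # sea level (cm)
        rng.uniform(0.5, 1.5, n),        # discharge index
        rng.uniform(1500.0, 3000.0, n),  # annual precipitation (mm)
    ]
)
Y = []
for x in X:
    r = simulate_flood(cells, x[0], x[1], x[2], [])
    Y.append(
        [
            r.inundated_area_km2,
            float(r.mean_depth_m.mean()),
            float(np.average(r.floodwater_salinity_dS_m, weights=r.areas_km2)),
        ]
    )
Y = np.array(Y)

rows = []
folds = np.arange(n) % 5
for k in (0, 1, 2, 3):
    ss_res = ss_tot = 0.0
    for f in range(5):
        tr, te = folds != f, folds == f
        em = fit_emulator(X[tr], Y[tr], n_components=k)
        pred = predict_emulator(em, X[te])
        ss_res += np.sum((Y[te] - pred) ** 2)
        ss_tot += np.sum((Y[te] - Y[tr].mean(0)) ** 2)
    rows.append({"n_components": k, "cv_r2": 1.0 - ss_res / ss_tot})

out = pd.DataFrame(rows)
out.to_csv(RESULTS / "emulator_cv.csv", index=False)
print(out.round(4).to_string(index=False))
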