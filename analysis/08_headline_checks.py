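"""Soft sanity checks of headline outcomes against published-scale expectations.

These are logged for inspection only; nothing is asserted.  The synthetic
region is not calibrated to reproduce any particular study, so magnitudes
are expected to differ while signs and orderings should be plausible.
"""

import json

import pandas as pd
from common import RESULTS, SEED

from deltasim.scenario import enumerate_runs, parent_run_id
from deltasim.sensitivity import ANALYSIS_DECADE_2050

per_run = pd.read_csv(RESULTS / "indicators.csv")
attribution = pd.read_csv(RESULTS / "attribution.csv")
runs = {r.run_id: r for r in enumerate_runs(master_seed=SEED)}

lo, hi = ANALYSIS_DECADE_2050
checks = {}
for world in ("positive", "negative"):
    rid = parent_run_id(world)
    t = per_run[per_run["run_id"] == rid].set_index("year")
    base = t.loc[2005:2014]
    end = t.loc[lo:hi]
    checks[world] = {
        "poverty_pct_2005_14": round(float(base["poverty_rate_pct"].mean()), 2),
        "poverty_pct_2041_50": round(float(end["poverty_rate_pct"].mean()), 2),
        "soil_salinity_dS_m_2005_14": round(float(base["mean_soil_salinity_dS_m"].mean()), 2),
        "soil_salinity_dS_m_2041_50": round(float(end["mean_soil_salinity_dS_m"].mean()), 2),
        "inundated_area_km2_2005_14": round(float(base["inundated_area_km2"].mean()), 1),
        "inundated_area_km2_2041_50": round(float(end["inundated_area_km2"].mean()), 1),
    }

clim = attribution.dropna(subset=["climatic_share"])
checks["climatic_share_of_poverty_change"] = {
    w: round(float(clim[clim["world"] == w]["climatic_share"].mean()), 3)
    for w in ("positive", "negative")
}
checks["orderings"] = {
    "negative_2050_poverty_gt_positive": checks["negative"]["poverty_pct_2041_50"]
    > checks["positive"]["poverty_pct_2041_50"],
    "negative_2050_area_gt_positive": checks["negative"]["inundated_area_km2_2041_50"]
    > checks["positive"]["inundated_area_km2_2041_50"],
}

(RESULTS / "headline_checks.json").write_text(json.dumps(checks, indent=2) + "\n")
print(json.dumps(checks, indent=2))
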