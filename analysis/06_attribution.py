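"""Climatic vs non-climatic attribution of household poverty changes."""

import pandas as pd
from common import RESULTS, SEED

from deltasim.scenario import enumerate_runs
from deltasim.sensitivity import attribution_table

per_run = pd.read_csv(RESULTS / "indicators.csv")
tables = {
    rid: grp.drop(columns="run_id").set_index("year")
    for rid, grp in per_run.groupby("run_id")
}
runs = enumerate_runs(master_seed=SEED)
out = attribution_table(tables, runs)
out.to_csv(RESULTS / "attribution.csv", index=False)
print(out.to_string(index=False))
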