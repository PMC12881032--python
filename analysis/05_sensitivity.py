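"""Driver sensitivity ranges per indicator and world (from stored runs)."""

import pandas as pd
from common import RESULTS, SEED

from deltasim.scenario import enumerate_runs
from deltasim.sensitivity import sensitivity_table

per_run = pd.read_csv(RESULTS / "indicators.csv")
tables = {
    rid: grp.drop(columns="run_id").set_index("year")
    for rid, grp in per_run.groupby("run_id")
}
runs = enumerate_runs(master_seed=SEED)
out = sensitivity_table(tables, runs)
out.to_csv(RESULTS / "sensitivity.csv", index=False)
print(
    out.pivot_table(index="driver", columns=["world", "indicator"], values="normalised")
    .round(2)
    .to_string()
)
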