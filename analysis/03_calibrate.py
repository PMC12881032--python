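"""Calibrate the uniform income scale to the baseline poverty target."""

import json

from common import N_UNIONS, RESULTS, SEED

from deltasim.synthregion import (
    calibrate_baseline,
    make_archetypes,
    make_region,
    region_baseline,
)

region = make_region(SEED, N_UNIONS)
archetypes = make_archetypes(SEED, region_baseline(region))
scale, report = calibrate_baseline(region, archetypes)
(RESULTS / "calibration.json").write_text(json.dumps(report, indent=2) + "\n")
print(report)
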