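"""Generate the synthetic study region, archetypes and climatology."""

from common import N_UNIONS, RESULTS, SEED

from deltasim.synthregion import (
    archetype_frame,
    make_archetypes,
    make_climatology,
    make_region,
    region_baseline,
    region_frame,
)

region = make_region(SEED, N_UNIONS)
region_frame(region).to_csv(RESULTS / "region.csv", index=False)

archetypes = make_archetypes(SEED, region_baseline(region))
archetype_frame(archetypes).to_csv(RESULTS / "archetypes.csv", index=False)

make_climatology().to_csv(RESULTS / "climatology.csv")
print(f"wrote region ({N_UNIONS} unions), 36 archetypes and climatology to {RESULTS}")
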