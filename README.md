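# equiscreen

Analysis pipeline for studying equitable geographic access to screening
mammography on synthetic tract geographies. Five stages, each usable on
its own:

1. **`equiscreen.synthetic`** — seeded generation of a two-county study
   region: tracts with demographics, population blocks (for
   population-weighted centroids), a connected jittered-lattice road
   network, and a facility inventory with unit counts and BICOE quality
   flags. Also generates Poisson counts with planted coefficients for
   regression-recovery experiments.
2. **`equiscreen.travel`** — exact shortest-path drive times
   (minutes = 60·length/speed) between tract centroids and sites, and
   classification of tracts into within-15 / within-30 / over-30 minute
   catchment bands.
3. **`equiscreen.demand`** — annual screening demand per tract under
   three guideline rules (`uspstf`: biennial 50–74; `race`: plus
   biennial Black women 40–49; `acr`: annual 40+), and facility
   capacity (4,500 screenings per unit per year).
4. **`equiscreen.regression`** — Poisson rate models of per-tract
   facility/unit/BICOE counts on standardized covariates with a
   log-population offset; rate ratios per SD with 95% Wald CIs,
   statewide and by county, with sparse strata suppressed.
5. **`equiscreen.allocation`** — capacitated maximal-covering site
   selection: fishnet candidate grid snapped to the network, greedy
   construction + interchange local search under a 20-minute cutoff,
   cumulative (nested) solutions for adding 1/3/5 sites, drive-time
   improvement metrics, and a BICOE-conversion variant.

`equiscreen.pipeline` orchestrates everything into one reproducible,
manifest-checked run; `equiscreen.report` produces inventory share
tables with half-up integer percentages.

## CLI

```sh
equiscreen simulate --seed 17 --out out/                 # synthetic region
equiscreen catchment --tracts out/tracts.csv --facilities out/facilities.csv \
    --nodes out/nodes.csv --edges out/edges.csv --bands 15,30 --out catchment.csv
equiscreen demand   --tracts out/tracts.csv --spec uspstf --out demand.csv
equiscreen regress  --tracts out/tracts.csv --facilities out/facilities.csv --out rr.csv
equiscreen allocate --tracts out/tracts.csv --facilities out/facilities.csv \
    --nodes out/nodes.csv --edges out/edges.csv --spec uspstf --add 1,3,5 \
    --cutoff 20 --out alloc.json
equiscreen allocate ... --bicoe-conversion --out bicoe.json
equiscreen report   --tracts out/tracts.csv --facilities out/facilities.csv --out inv.csv
equiscreen run      --seed 17 --out run/                 # full pipeline + manifest
```

`simulate` and `run` accept `--config <json>`; the JSON schema is the
field set of `ScenarioConfig` / `RunConfig` (see their docstrings).

## Reproducibility

Every source of randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configs yield byte-identical
outputs, which `tests/test_synthetic.py` and `tests/test_pipeline.py`
verify by content digest. The allocation solver's tie-breaks are
total-ordered, and its solutions are certified against an
exhaustive-enumeration oracle on small instances in
`tests/test_acceptance.py`.
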