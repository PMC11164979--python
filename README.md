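# agroemf

Ecological and economic ecosystem-multifunctionality analysis for a
two-factor (climate x land-use) split-plot agro-experiment, built as a
tested, reusable pipeline with a synthetic data generator so every stage is
verifiable without field data.

The package covers:

- **`agroemf.synthetic`** — balanced split-plot design tables (climate on
  mainplots, five land-use types on subplots), multi-year ecosystem-function
  panels with multiplicative climate/management effects, lognormal annual
  yields whose coefficient of variation depends on latent soil-biodiversity
  and soil-health traits, and raster images with exact known flower-pixel
  fractions.
- **`agroemf.functions`** — panel aggregation, min-max normalization
  (with direction inversion for the nitrogen-surplus dis-service), Shannon
  diversity, soil multidiversity, hierarchical soil health, bait-lamina and
  litterbag rates, microbial biomass from the respiratory response
  (38 x MIRR), nitrogen surplus (literal and mass-balance variants), unit
  conversions and soil carbon stocks/fluxes.
- **`agroemf.flowers`** — RGB-threshold flower-pixel classification
  (red/orange/blue/violet/white/yellow rules with strict inequalities and
  first-match precedence; the literal violet rule is provably unsatisfiable
  and matches zero pixels), with optional blackout masks.
- **`agroemf.weighting`** — stakeholder, equal-function and equal-service
  weighting schemes, the survey-preference transfer procedure, and the
  ecological multifunctionality index (weighted average of normalized
  function levels).
- **`agroemf.economic`** — monetization of food production, climate
  regulation (CO2 accounting price on soil carbon flux), water quality
  (social cost of nitrogen surplus), and the natural-insurance values of
  biodiversity and soil health via risk premia on a fitted quadratic
  response surface; five price scenarios for sensitivity analysis.
- **`agroemf.stats`** — balanced split-plot ANOVA with correct error
  strata, Tukey post-hoc comparisons, biodiversity–multifunctionality
  regressions with climate interaction, and Pearson correlation matrices.
- **`agroemf.pipeline` / `agroemf.cli`** — end-to-end orchestration with
  YAML configuration, reproducibility metadata (seed + config hash in every
  output) and a constants-provenance run log.

## CLI

```bash
agroemf run --seed 1 --outdir out/            # full pipeline, default config
agroemf init-config --out config.yaml         # write an editable config
agroemf run --config config.yaml --outdir out/

# stage by stage on intermediate CSVs
agroemf simulate --seed 1 --outdir sim/
agroemf functions --panel sim/panel.csv --outdir fn/
agroemf emf --normalized fn/normalized.csv --scheme farmers --out eg.csv
agroemf econ --panel sim/panel.csv --scenario default --out econ.csv
agroemf flowers --images photos/ --out flowers.csv
agroemf stats --panel sim/panel.csv --design sim/design.csv --outdir stats/
```

`run` writes per-plot ecological multifunctionality for six weighting
schemes (four stakeholder groups plus equal-function and equal-service),
economic multifunctionality and farmer value per price scenario, ANOVA /
post-hoc / regression / correlation tables, and `run.log` with every
constant used.

## Notes on fidelity

- The published preference-transfer worked example is not reproducible from
  its stated steps; the procedure is implemented as stated and the printed
  final preference vectors ship as fixtures (the farmers vector sums to
  102% and is renormalized on use). See `agroemf.weighting`.
- The nitrogen-surplus formula defaults to the literal printed sign
  (`+ nmin_x1`); a mass-balance variant is available
  (`nitrogen_surplus(..., variant="balance")`).
- The violet pixel rule is implemented literally and therefore matches
  nothing; this is proven exhaustively in the test suite.
- Producer prices and the non-farmer stakeholder preference vectors are
  documented, non-authoritative placeholder defaults (the originals are
  supplementary material), and are fully configurable.
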