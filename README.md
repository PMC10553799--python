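# deprindex

Construction and agreement analysis of two widely used U.S. area-level
socioeconomic deprivation indices: the **Area Deprivation Index (ADI)** and
the CDC **Social Vulnerability Index (SVI)**.

Both indices are routinely used — often interchangeably — to target public
health resources at deprived neighbourhoods. They are not interchangeable:
they weight different indicators, at different census scales, with different
scoring rules. This package builds both indices from raw indicator tables,
ranks census tracts into deciles under each, quantifies how often and how
badly the two rankings disagree, and attributes the disagreement to specific
indicator items. Because the real Census/ACS products are large managed
downloads, the package ships a synthetic census-geography generator whose
latent-factor structure mirrors the statistical skeleton of the real inputs,
including a tunable *urban housing-cost confound* — the mechanism by which
expensive urban tracts can look prosperous to the ADI while remaining highly
vulnerable under the SVI.

## The two indices

**ADI** (block-group level, 17 items). Each indicator $x_k$ is multiplied by
its factor score coefficient $w_k$ and summed,
$s_i=\sum_k w_k x_{ik}$; sums are standardized to mean 100, SD 20, and
converted to national percentile ranks in $[0,100]$ (100 = most deprived).
Block groups with fewer than 30 housing units, fewer than 100 people, more
than one third of the population in group quarters, or a Census-acknowledged
error are excluded. Percentiles are aggregated to tracts by
population-weighted means.

**SVI** (tract level, 15 items in four themes). Every item is percentile
ranked in $[0,1]$ with average ranks for ties, oriented so larger = more
vulnerable (per capita income rank-reversed). Item percentiles are summed
within themes, theme sums are ranked, and the overall score is the
percentile rank of the total (1 = most vulnerable).

**Agreement.** Both tract-level scores are decile-ranked (decile 10 = most
deprived). A tract has *good* agreement when its ADI and SVI deciles differ
by at most 1, *poor* agreement when they differ by 6 or more. The analysis
reports Spearman correlations (continuous and decile), the 10×10 decile
cross-tabulation, eight extreme-decile comparison groups (top/bottom decile
of each index × good/poor agreement), Welch *t*-tests and Cohen's D for every
item between poor- and good-agreement tracts (drivers: *p* < 0.05 and
|D| ≥ 0.8), and urban shares via RUCA codes.

## Worked example

```python
from deprindex import SyntheticParams, generate_geography, write_fixture
from deprindex import RunConfig, run_pipeline
from deprindex.cli_io import confound_study

params = SyntheticParams(n_states=2, tracts_per_state=500,
                         urban_probability=0.3, seed=7)
bgs, tracts = generate_geography(params)
write_fixture(bgs, tracts, "demo")

bundle = run_pipeline(RunConfig(blockgroup_csv="demo/blockgroups.csv",
                                tract_csv="demo/tracts.csv",
                                output_dir="demo/out"))
print(bundle["summary"])
```

On this run 60 of 3,008 block groups are excluded (20 per threshold rule,
from the generator's built-in edge cases), 995 of 1,000 tracts carry both
indices, and the default (mild-confound) geography gives

```
rho_continuous = 0.982   rho_decile = 0.973   share_good = 0.978
```

— the two indices nearly coincide when nothing but the shared deprivation
factor drives the items. Turning the urban housing-cost confound up, with
ADI coefficients frozen from a confound-free reference geography (how a
released index meets new data):

```python
res = confound_study(params, strengths=(0.0, 2.0))
```

```
strength 0.0: rho_decile = 0.822  share_good = 0.655  share_poor = 0.002
strength 2.0: rho_decile = 0.712  share_good = 0.574  share_poor = 0.031
group 2b: 2 tracts, 100% urban
```

Agreement degrades, and a high-SVI / low-ADI mismatch group ("2b") appears:
urban tracts whose median home values, mortgages, and rents — items the ADI
weights negatively and the SVI omits — mask their deprivation. The driver
tables (`demo/out/drivers.csv`) flag exactly those three items with large
effect sizes.

The same pipeline is available from the shell:

```
deprindex simulate --seed 7 --out demo
deprindex run --config run.json
```

Outputs per run: per-unit score CSVs, the decile cross-tab with margins, the
8-row comparison table, item driver tables on native and percentile scales,
state and urban summaries, a GeoJSON map export, and a JSON manifest.

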