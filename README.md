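# landfrag

Landscape fragmentation analysis for categorical land-use/land-cover
(LULC) rasters, built for studies that track forest fragmentation
through time and compare how different map sources represent it — for
example, an official government LULC series against a
satellite-archive product covering the same territory.

`landfrag` takes integer-coded rasters (GeoTIFF or ESRI ASCII grid),
collapses their legends into three analysis classes (natural cover,
anthropic use, water), clips them to study-zone masks, and then runs
two complementary fragmentation analyses plus a statistical source
comparison:

**Class-level patch metrics.** Natural-cover patches are delineated
under the 8-neighbor rule and six standard class metrics are computed,
with patch areas *aᵢⱼ* (m²), landscape area *A* (all non-nodata cells,
m²), and patch count *nᵢ*:

| metric | definition | units |
|---|---|---|
| PA_MN | (Σ aᵢⱼ / nᵢ) / 10⁴ | ha |
| NP | nᵢ | count |
| PD | (nᵢ / A) · 10⁴ · 100 | patches / 100 ha |
| LPI | (max aᵢⱼ / A) · 100 | % |
| ENN_MN | mean over patches of the nearest-neighbor center-to-center distance | m |
| MESH | (Σ aᵢⱼ² / A) / 10⁴ | ha |

**Multiscale forest-area-density (FAD) mapping.** Every natural pixel
is scored with the percentage of natural pixels in a square moving
window (windows 7, 13, 27, 81, 243 by default; clipped at borders and
at nodata), the five continuous values are averaged per pixel, and the
result is banded into six fragmentation classes — rare [0,10), patchy
[10,40), transitional [40,60), dominant [60,90), interior [90,100),
intact = 100. Change between two dates is summarized by a 7×7 class
transition matrix (plus the non-natural state), by natural-cover loss
in hectares, and by per-scale class-composition profiles.

**Paired source comparison.** For each metric and zone, the yearly
values of two sources are compared with a two-sided Wilcoxon
signed-rank test (exact enumeration for ≤ 25 untied pairs, normal
approximation otherwise) and the effect size r = |Z|/√n. With eight
map years and consistently one-sided differences — the typical outcome
when one source systematically resolves more small clearings — the
exact p-value is 2/2⁸ = 0.0078 and r = 0.891.

A seeded synthetic-landscape module generates paired two-source time
series with exactly this structure (road-corridor frontier
deforestation observed by a generalizing "coarse" source and a noisy
"fine" source), so the whole pipeline can be exercised and tested
without proprietary map data.

## Worked example

Simulate a paired dataset and run the full pipeline:

```
landfrag simulate --seed 1 --out demo
landfrag run --config demo/config.yaml
```

`demo/results/metrics.csv` then holds one row per source × year
(source A = coarse, B = fine; 200×200 cells of 30 m, zone "full"):

```
source,zone,year,pa_mn_ha,np,pd_per100ha,lpi_pct,enn_mn_m,mesh_ha,total_class_area_ha,landscape_area_ha
A,full,1990,1758.42,2,0.055556,50.57,120.0,1719.942948,3516.84,3600.0
...
B,full,2022,5.867749,431,11.972222,34.0275,63.120016,809.02255,2529.0,3600.0
```

Reading these rows: in 1990 the coarse source sees the landscape as
two large forest blocks (NP = 2, mean patch area 1 758 ha) split by the
road corridor; by 2022 the fine source resolves 431 patches of 5.9 ha
mean area — fragmentation has increased and the fine source reports it
far more strongly. `demo/results/comparison.csv` quantifies the
source disagreement per metric:

```
metric,zone,n_pairs,w_plus,p_value,r_effect,significant,method
pa_mn_ha,full,8,36.0,0.0078,0.891,True,exact
np,full,8,0.0,0.0116,0.891,True,approx
...
```

PA_MN differs with the exact signed-rank p = 0.0078 and effect size
r = 0.891: all eight yearly differences have the same sign. The run
also writes per-scale and average fragmentation class rasters
(`fragclass_*.tif`), the class transition matrix between the first and
last year (`transitions_full_A.csv`), change profiles, natural-cover
loss in hectares (in `manifest.yaml`), and a `run.log`.

Single-stage subcommands (`reclassify`, `metrics`, `fad`, `change`,
`compare`) expose the same functionality for individual rasters; e.g.
`landfrag metrics --input map.asc` prints one metrics row.

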