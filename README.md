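# spatialniche

Spatial tumor–immune neighborhood analysis for multiplexed-immunofluorescence
cell tables, built around the NOS2/COX2/CD8 axis in ER-negative breast
cancer.

Tumors that resist cytotoxic immunity show characteristic spatial
architectures: COX2⁺ immune-desert cores devoid of CD8⁺ T cells, and
inflamed margins where NOS2⁺COX2⁺ tumor satellites bud into stroma while
CD8⁺ T cells are held off the tumor edge by a ~50 μm gap.  `spatialniche`
quantifies these architectures from segmented single-cell tables
(coordinates in μm plus marker intensities) and relates them to patient
outcome:

1. **Phenotyping** — marker intensities are quantized into
   negative/weak/moderate/strong levels and collapsed into eight
   CD8±NOS2±COX2± phenotype codes (`code = 4·CD8 + 2·NOS2 + COX2`).
2. **Neighborhood census** — for every cell, the density (cells/mm²) of
   each phenotype is computed in five annuli (0–25, 25–50, 50–100, 100–150,
   150–200 μm), giving a 40-value neighborhood profile
   d<sub>p,b</sub> = n<sub>p,b</sub> / π(r<sub>b+1</sub>² − r<sub>b</sub>²).
3. **Niche discovery** — profiles are UMAP-embedded in 2D; deceased- and
   alive-group cells are binned into normalized 2D histograms on a shared
   grid and contrasted bin-wise as log₁₀((f_D + ε)/(f_A + ε)).  Cells in
   bins beyond the ±0.01 thresholds form group-enriched sets, which are
   clustered by k-means with the cluster number chosen by minimizing the
   Davies–Bouldin index.  Clusters (D1…Dk / A1…Ak by size) are
   characterized by mean ± SEM profiles, prevalence fractions, and
   per-phenotype ratio profiles between clusters.
4. **Survival** — per-sample NOS2s/CD8 and COX2/CD8 ratios (cell counts, or
   NOS2/CD8A and COX2/CD8A expression for transcriptomic cohorts) are
   dichotomized at the median and compared by Kaplan–Meier curves, the
   log-rank (Mantel–Cox) test, and the Mantel–Haenszel hazard ratio
   HR = (O_h/E_h)/(O_l/E_l) with events censored at a 5-year horizon.
5. **Descriptive spatial statistics** — density grids, per-region
   composition percentages, immune-desert calls (CD8⁺ density
   < 100 cells/mm²), cross-type nearest-neighbor gap distances, Pearson
   correlation, and the caliper tumor-volume formula short²·long/2.

Because raw clinical mIF data of this kind are rarely shareable, the
package ships a ground-truthed tissue simulator (`synthetic_data`): marked
point patterns with a disk tumor core, margin annulus and stroma, Poisson
cell placement at configurable per-region intensities, Thomas-type
satellite clusters on the tumor edge, a stroma-restricted CD8⁺ band at a
configurable gap, and distal lymphoid aggregates.  Every downstream stage
is tested against its recorded ground truth.

## Worked example

```python
from spatialniche import io

cfg = io.PipelineConfig(out_dir="run", seed=1, n_deceased=5, n_alive=5)
res = io.run_pipeline(cfg)          # simulate -> phenotype -> census ->
                                    # UMAP/log-ratio -> k-means -> survival

dec = res["clusters"]["deceased"]
print(dec.k, dec.names)             # 10 ['D1', ..., 'D10']
import numpy as np
from spatialniche import sumap, neighborhoods as nb
X = res["profiles"][nb.profile_columns()].to_numpy(float)
alive_mean = X[res["clusters"]["alive"].cell_index].mean(axis=0)
i = int(np.argmax(dec.mean_profiles[:, 15]))      # satellite-niche cluster
ratio = sumap.cluster_ratio_profile(dec.mean_profiles[i], alive_mean)
print(round(ratio[15], 2))          # 11.35
```

The printed `11.35` is the density ratio of the CD8⁻NOS2⁺COX2⁺ phenotype
in the 0–25 μm bin between the discovered deceased niche cluster and the
average alive neighborhood: the clustering recovered the ~10× satellite
niche planted by the simulator (ground-truth enrichment ≈ 10.3×).
`run/report.json` holds the full cluster report (selected k, DB index per
k, prevalence, mean ± SEM profiles) and the ratio-survival results;
`run/manifest.json` records every seed and parameter needed to reproduce
the run byte-for-byte.

The same stages are available from the shell:

```sh
spatialniche simulate --out sim/ --seed 1 --n-deceased 5 --n-alive 5
spatialniche phenotype --cells sim/cells.csv --out sim/cells_phenotyped.csv
spatialniche profile --cells sim/cells_phenotyped.csv --out sim/profiles.csv
spatialniche sumap --profiles sim/profiles.csv --meta sim/samples.csv --out sim/sumap/
spatialniche run --out run/ --seed 1
```

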