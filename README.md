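# arrayquant

Automated quantification of membrane antibody array scans (cytokine /
chemokine "dot blot" profilers), with the downstream statistics used to
call differentially abundant analytes and to test agreement with
transcriptomics.

Membrane arrays such as the Proteome Profiler Human XL report up to 105
secreted proteins as duplicate antibody spots on a nitrocellulose
membrane, read out by chemiluminescent or near-infrared imaging.  The
readout is semi-quantitative and the bottleneck is image analysis:
finding the spots, reconstructing the printed grid, registering a stored
layout onto each scan, and turning pixel intensities into comparable
per-analyte values.  `arrayquant` automates that workflow end to end and
is aimed at lab scientists and analysts who scan membranes and want
reproducible numbers instead of manual densitometry.

## The pipeline

Four stages, each available as a library call and a CLI subcommand:

1. **Spot detection** — percentile contrast rescaling, multi-scale
   Laplacian-of-Gaussian filtering over a configurable σ range with
   sub-pixel (quadratic) peak refinement and a noise-adaptive response
   floor, radius-based de-duplication, and DBSCAN outlier removal.
2. **Grid reconstruction** — rotation correction by a ±30° (0.1° step)
   variance-minimization search (applied when confidence > 0.3), 1-D
   density clustering of centroids into rows/columns, least-squares row
   and column lines, and their intersections as well positions; stored
   as a reusable, plain-text `GridTemplate` with microplate labels
   (A1, B2, …).
3. **Template alignment** — differential evolution over a bounded
   similarity transform (θ ± 15°, translation ± 50 px, scale ± 10%)
   maximizing centroid overlap without penalizing missing spots,
   L-BFGS-B refinement when the objective falls below 0.5, and a
   thin-plate-spline warp (kernel U(r) = r² log r, ≥ 10 correspondences)
   for membrane distortion.
4. **Intensity measurement** — mean intensity over a disk at every
   aligned well (spurious detections contribute nothing; faint analytes
   are still measured), two-point control normalization

       normalized = (raw − μ_neg) / (μ_pos − μ_neg),

   log₂ transform, duplicate-spot averaging to one value per analyte,
   and CSV/XLSX export with QC overlay figures.

Downstream statistics: per-analyte log₂ fold-change of replicate means
(log2FC = log₂(v̄_A / v̄_B)), the Z-factor assay-quality score
Z = 1 − 3(σ_a + σ_b)/|μ_a − μ_b| with a four-band quality call
(ideal / excellent / marginal / inconclusive), a Welch *t*-test
(*p* < 0.01 / 0.001 / 0.0001 bands), and the joint significance gate
|log2FC| > 1 **and** Z > 0.5.  For protein-vs-transcript concordance:
gene-symbol matching (a mapping for the 105-analyte panel ships with the
package), a directional 2×2 overlap table, a one-sided Fisher's exact
test (alternative "greater"), and Pearson correlation of fold-changes.

A synthetic-array module renders fully ground-truthed scans (known
centroids, amplitudes, transforms, injected fold-changes), so the whole
pipeline is testable with no external data.  The packaged 105-analyte
map is a synthetic-but-consistent reconstruction of a Human XL-style
layout (the vendor publishes no machine-readable coordinates); every
analyte name and gene symbol is real.

## Worked example

Render a two-condition synthetic experiment, run the pipeline, and call
differential analytes:

```python
import numpy as np
from arrayquant.diff_stats import condition_group, differential_table
from arrayquant.intensity_measurement import human_xl_map
from arrayquant.pipeline import run_pipeline
from arrayquant.synthetic_array import SyntheticArraySpec, render_experiment

amap = human_xl_map()
effects = {"ENA-78": 2.0, "DPPIV": -1.5}          # injected log2 fold-changes
base = SyntheticArraySpec(n_rows=10, n_cols=24, pitch=24.0, margin=45)
conds, truth = render_experiment(base, amap, effects, n_replicates=4,
                                 cv=0.10, seed=5)
images = [im for im, _ in conds["treated"]] + [im for im, _ in conds["reference"]]
results, template = run_pipeline(images, amap, seed=3)

treated = condition_group([r.analytes for r in results[:4]])
reference = condition_group([r.analytes for r in results[4:]])
table = differential_table(treated, reference)
print(table[table.significant][["analyte", "log2FC", "z_factor", "p", "category"]])
```

Output:

```
  analyte    log2FC  z_factor         p   category
0  ENA-78  1.923579  0.602365  0.000464  excellent
1   DPPIV -1.555849  0.581535  0.000396  excellent
```

Both injected effects are recovered within ±0.08 log₂ units, pass the
joint |log2FC| > 1 & Z > 0.5 gate, and land in the "excellent"
Z-factor band; the remaining 103 analytes are reported non-significant.

The same flow from the shell:

```sh
arrayquant run scan1.tif scan2.tif ... --map map.csv --out results/
arrayquant diff --manifest manifest.csv --contrast lps water --out diff.csv
arrayquant concord --cyt diff.csv --rna rna_de.csv --out concord.json
```

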