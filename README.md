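# spherotype

Spheroid drug-sensitivity analysis: extract viability-staining profile
metrics from 3-channel (calcein AM / propidium iodide / transmitted light)
z-stack images, score treatment response as a PCA distance-from-control
statistic with quartile classes, and quantify growth inhibition (absolute
GI50, Emax) over a two-cycle treatment schedule. A synthetic-data module
generates spheroid image stacks, growth time courses and dose-response
tables with ground-truth records, so the whole pipeline is testable without
any microscopy data.

## Modules

| module | purpose |
|---|---|
| `spherotype.synthetic` | cell-line specs, treatment schedule, growth simulation, spheroid stack rendering, full-cohort generation |
| `spherotype.profiles` | stack plot-profile extraction (short-axis mean, z-sum), rolling-average smoothing, lower-quartile baseline + trapezoidal AUC, TIFF/CSV I/O |
| `spherotype.vmetrics` | peak detection (prominence/width at half prominence) and the 14-variable viability feature vector per spheroid |
| `spherotype.response` | pooled standardization, loading-filtered 2-component PCA (threshold 0.5 on correlation-scaled loadings), Euclidean distance from same-line/same-day control, quartile response classes |
| `spherotype.growth` | brightfield area segmentation (Otsu + fill + largest component), `d = 2000*sqrt(A/pi)`, percent of control, absolute-GI50 4PL fits, Pearson correlations |
| `spherotype.pipeline` / `spherotype.cli` | end-to-end orchestration and the `spherotype` command |
| `spherotype.datasets` | bundled 40-value reference distance table used to calibrate the quantile classification convention (q25 = 0.432, q75 = 1.365) |

## CLI

```sh
# full synthetic run: simulate -> profile -> metrics -> pca -> gi50 -> report
spherotype all --outdir out --seed 7

# individual stages operate on the previous stage's files
spherotype simulate --outdir out --seed 7
spherotype profile  --stacks out/stacks --outdir out/profiles
spherotype metrics  --stacks out/stacks --out out/metrics.csv
spherotype pca      --metrics out/metrics.csv --outdir out
spherotype gi50     --input out/growth.csv --day 18 --culture 3D --out out/gi50.csv
spherotype report   --outdir out
```

Identical seed + options give byte-identical outputs. Every stage writes an
`*_audit.json` with the resolved configuration and package version.

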