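# darklung

Grating-based X-ray dark-field analysis of pulmonary emphysema on
projection images: phantom simulation, phase-stepping signal retrieval,
the thickness-invariant *normalized scatter* statistic, ROC / DeLong
discrimination analysis, and color-coded parametric emphysema maps.

## The problem

Emphysema destroys alveolar walls. Alveoli are far below the resolution
of a radiograph, but they scatter X-rays at small angles, and a Talbot
(grating) interferometer measures that scattering: stepping one grating
across a period makes each detector pixel trace a sinusoid whose mean
encodes transmission (`T`), whose phase encodes refraction, and whose
relative modulation depth — the *dark-field* signal (`V`) — encodes
sub-resolution scattering. Emphysematous tissue transmits slightly more
and scatters less per unit thickness, but both log-signals scale with
the path length through the lung, so neither channel alone maps disease
on a projection. Their ratio does: the **normalized scatter**

```
S = −ln(V) / (ln(T) − c)
```

is independent of sample thickness (`c` is a small log-transmission
offset of the formalin-filled specimen container relative to the water
bath both signals are normalized against). Healthy lung has high `S`
(many scattering interfaces per unit of attenuating tissue);
emphysematous lung has low `S`.

This package reimplements that analysis as a tested pipeline operating
on synthetic ex-vivo mouse-lung cohorts (3 emphysema + 3 control
specimens, 11 projections each, 16 phase steps per scan) whose
per-pixel signal distributions are calibrated to published group
quantiles — transmission 1.11 [1.07–1.17] vs 1.06 [1.04–1.10],
dark-field 0.66 vs 0.66, normalized scatter 4.9 [4.1–5.8] vs 10.8
[7.5–14.7] — and on any externally supplied phase-stepping stacks in
the same multi-frame TIFF + JSON sidecar format.

## Worked example

```python
from darklung import RunConfig, analyze_cohort

analysis = analyze_cohort(RunConfig())   # default cohort, seed 0
print(analysis.summary_per_pixel.table[["group", "parameter", "median", "q1", "q3"]])
print({p: round(c.auc, 3) for p, c in analysis.roc_per_pixel.items()})
print(round(analysis.correction_mean, 4))
```

prints (a few seconds on one CPU):

```
       group           parameter     median        q1         q3
0    control        transmission   1.065128  1.044659   1.107589
1  emphysema        transmission   1.115680  1.077150   1.175501
2    control          dark_field   0.625417  0.390320   0.781189
3  emphysema          dark_field   0.642041  0.486959   0.766395
4    control  normalized_scatter  10.915118  7.757019  15.395701
5  emphysema  normalized_scatter   4.956428  4.198377   5.945507
{'transmission': 0.723, 'dark_field': 0.53, 'normalized_scatter': 0.937}
0.02
```

Reading this: the pipeline-recovered per-pixel medians reproduce the
calibrated transmission and normalized-scatter targets to about 1%,
and the estimated container correction is 0.020. The dark-field
medians sit a few percent below their 0.66 calibration because the
dark-field segmentation threshold necessarily removes the
highest-visibility lung pixels (see `docs/methods.md`). Per-pixel
discrimination between emphysematous and healthy lung is chance-level
for the dark-field signal alone, moderate for transmission, and best
for normalized scatter — the ordering that motivates the combined
statistic. The paired DeLong comparison of the S and T AUCs is in
`analysis.delong["normalized_scatter_vs_transmission"]`.

The same run from the shell, with all artifacts (retrieved maps,
segmentation masks, CSV summaries, ROC tables, PNG overlay maps and a
`report.json` with checksums) written to a directory:

```
darklung all --config run.yaml --out results/
```

`run.yaml` mirrors the `RunConfig` blocks (`phantom:`, `retrieval:`,
`segmentation:`, `statistic:`, `roc:`, `mapping:`, `seed:`); every key
is optional and defaults to the study conditions above. The
subcommands `simulate`, `retrieve`, `analyze` and `map` run the same
stages one at a time against the same output directory and produce an
identical final report.

## Parametric emphysema maps

For a chosen channel and cutoff (Youden-optimal from the ROC by
default, or the reference presets `1.087 / 0.715 / 7.00`), each lung
pixel's deviation *toward the emphysematous direction* is divided by
the control-group interquartile range of that channel and clipped to
[0, 1], then blended as a yellow-to-red overlay on the grayscale
transmission image. On the default cohort the scatter-based maps color
~88% of emphysematous lung and ~16% of control lung, and classify
pixels against the ground-truth label better than transmission- or
dark-field-based maps.

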