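# icscore3d

Computer-assisted 3D quantification of PD-L1 expression on tumor-infiltrating
immune cells (the SP142-style "IC score") in multichannel fluorescence
z-stacks of cleared tumor tissue.

The pipeline mirrors a two-stage detection scheme: a tumor-cell segmenter
followed by an immune-cell segmenter operating on the two counterstain
channels (nuclei, membrane), then per-layer scoring — merged tumor-area mask,
intratumoral immune mask, marker-positive immune mask — with

```
IC score (%) = 100 · area(marker⁺ intratumoral immune cells) / area(tumor)
```

categorized at the clinical cut-offs (0% negative, >0–1% borderline, ≥1%
positive). Per-layer scores are assembled into depth profiles: 3D average,
min/max/range, 1%-threshold crossing, heterogeneity pattern, and a
categorical 2D-vs-3D discordance against a single-layer reference. Cohort
agreement tables (confusion matrix + overall percent agreement) round out the
analysis.

Because no study data are available, the `phantom` module generates seeded
synthetic 3-channel stacks with exact voxel-level ground truth and designed
per-layer marker-positive fractions, so every stage is testable end to end.

## Modules

| module | role |
| --- | --- |
| `icscore3d.phantom` | seeded synthetic z-stacks + exact ground truth (`PhantomParams`, `generate_case`, `gradient_profile`) |
| `icscore3d.stack_io` | OME-TIFF/mask I/O, `ChannelStack`, the `run_case` orchestrator, `CaseReport` |
| `icscore3d.segmentation` | patch sets (8:1:1 split), random-forest pixel classifier, deterministic classical segmenter, pixelwise evaluation |
| `icscore3d.scoring` | merged tumor area, immune split, marker positivity, per-layer IC score and category |
| `icscore3d.profile3d` | layer selection, depth profiles, patterns, discordance, agreement tables |
| `icscore3d.pseudostain` | Beer–Lambert pseudo-H&E / pseudo-IHC rendering for visual QC |

The trainable segmenter is a multiscale-feature random-forest pixel
classifier (no GPU or deep-learning runtime needed); a threshold+morphology
classical segmenter provides a deterministic, training-free route through the
same pipeline.

## CLI

```bash
# generate a synthetic case (stack + ground-truth masks + JSON sidecar)
phantom generate --config phantom.yaml --seed 1 --out case1/

# train a segmenter on a generated case
score train --target tumor --patches case1/ --seed 0 --out models/
score train --target immune --patches case1/ --seed 0 --out models/

# score a stack (trained models, or ground-truth oracle mode)
score run --input case1/stack.ome.tif --model-dir models/ --out report1/
score run --input case1/stack.ome.tif --oracle case1/ --out report1/

# cohort table + agreement matrix from per-case reports
score report --merge report1/ --merge report2/ --out cohort.csv

# pseudo-stain rendering of one layer
score pseudostain --input case1/stack.ome.tif --mode he --layer 0 --out he.png
```

`phantom.yaml` may override any `PhantomParams` field, e.g.:

```yaml
image_shape: [16, 256, 256]
pdl1_fraction_profile: 0.02
tumor_nest_count: 3
```

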