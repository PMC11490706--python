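# tjmorph — tight-junction morphometry

`tjmorph` quantifies tight-junction (TJ) morphology from junction-marker
immunofluorescence (typically ZO1 in epithelial monolayers). Functional,
claudin-polymerizing TJs appear as ruffled, zigzagging lines between cells,
while claudin-deficient, leaky junctions run straight — and the package turns
that qualitative difference into numbers:

* **Zigzag (ruffling) index** — for each cell-cell contact spanning two
  tricellular junctions, the index is α/β: the geodesic length α of the
  junction path over the straight-line distance β between its two ends.
  Straight contacts give 1; ruffled contacts give more. Per image, the
  unweighted mean over all contacts ≥ 2 μm is reported.
* **TJ-band intensity** — mean marker intensity inside a band rebuilt from
  the junction mask itself (small-object removal < 4 μm², skeletonization,
  6 × 3×3 re-dilation), normalized per staining experiment so that each
  experiment's images average 1.
* **Colocalization** — Pearson correlation of two channels over complete
  z-stacks with Costes threshold regression (orthogonal fit, thresholds
  stepped down until the below-threshold correlation reaches ≤ 0) and Costes
  block-randomization significance.

Because the original microscopy data cannot be redistributed, the package
ships a **synthetic scene generator** with analytically known ground truth:
bounded Voronoi monolayers whose edges are taper-windowed sinusoidal ruffles
of known arc/chord ratio, rasterized with PSF blur and Poisson/Gaussian
noise. Every downstream stage is validated by parameter recovery against
that truth.

## Pipeline

```
z-stack ─ max projection ─ Triangle("Dark") threshold ─ dilation ─ median
  ─ skeletonization (1 px) ─ skeleton graph (nodes + branches, α and β)
  ─ branch filter (α < 2 μm removed, loops removed) ─ α/β per contact
  ─ per-image mean zigzag index
```

## Worked example

Generate a ruffled synthetic monolayer and measure it:

```bash
cat > scene.json <<'EOF'
{"field_size_px": [768, 768], "pixel_size_um": 0.04, "n_cells": 8,
 "ruffle_amplitude_um": 0.65, "ruffle_wavelength_um": 2.0,
 "noise_model": "poisson", "seed": 42}
EOF
tjmorph synth --config scene.json --out scene.tif --truth truth.json
tjmorph zigzag --in scene.tif --out report.csv \
    --dilate 0 --median-radius 2 --require-junction-ends
```

prints

```
{"image_mean_zigzag": 1.3652709527543436, "n_contacts": 4}
```

i.e. four tricellular-to-tricellular contacts with a mean zigzag index of
1.365; the ground truth written alongside (`truth.json`) holds a true mean
tortuosity of 1.317 for those edges, so the measurement recovers the ruffling
within ~4% (pixel-step discretization inflates α slightly). `report.csv`
lists α, β and the index per contact plus an `image_mean` summary row.

The same library is available programmatically:

```python
from tjmorph import SceneParams, generate_junction_scene, run_zigzag_pipeline
from tjmorph.validation import SYNTHETIC_ZIGZAG_CONFIG

scene = generate_junction_scene(SceneParams(seed=42, ruffle_amplitude_um=0.65))
report = run_zigzag_pipeline(scene.image, SYNTHETIC_ZIGZAG_CONFIG)
print(report.image_mean_zigzag, report.n_contacts)
```

Other commands: `tjmorph mask` (junction mask with provenance sidecar),
`tjmorph tj-intensity --manifest images.csv` (per-image band intensity,
normalized per experiment; manifest columns `path,image_id,experiment_id,
pixel_size_um`), and `tjmorph coloc --a a.tif --b b.tif` (Pearson + Costes).

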