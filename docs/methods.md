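# Methods

## The measurement model

A tight-junction marker channel (ZO1) images the junction network of an
epithelial monolayer as bright, 0.1–0.6 μm wide lines over a dim cytoplasmic
background. The morphometric of interest is the **zigzag index** of each
cell-cell contact — the path a junction takes between its two tricellular
endpoints, divided by the straight-line distance between them:

    zigzag = α / β,   α = geodesic junction path length, β = Euclidean chord.

The index is ≥ 1 by construction and dimensionless, hence invariant to the
pixel size (α and β scale together). Ruffled (functional, claudin-polymerized)
junctions give higher indexes than straight (claudin-deficient) junctions, so
ordering across conditions is the biologically meaningful output; per-image
means are the unit of analysis.

### Mask construction

1. **Maximum intensity projection** over z (idempotent on 2D input).
2. **Triangle ("Dark") auto-threshold**: on the intensity histogram, a line
   joins the peak (background mode) to the brightest occupied bin; the
   threshold is the bin between them farthest from that line; pixels strictly
   above are foreground. Ties resolve to the lowest bin. Integer-valued
   images — including float arrays holding photon counts — are binned at
   native integer levels (up to 65536); truly continuous images use 256
   min–max bins. Native binning matters: equal-width binning of integer data
   leaves interleaved empty bins whose zero counts capture the distance
   maximum right next to the background peak, which inflates masks
   catastrophically on Poisson backgrounds. Constant images (or < 2 occupied
   bins) raise `DegenerateHistogram`.
3. **Binary dilation** (3×3 square by default, configurable count — default 1)
   followed by a **binary median (disk-majority) filter**, default radius
   12 px; exact ties count as foreground, and the disk is clipped at the
   image border. The defaults suit 1024×1024 confocal frames; for data
   (or synthetic scenes) whose junction band is only a few pixels wide the
   median radius must stay below the band half-width or the filter erases
   the structure it is meant to clean (see "Synthetic validation protocol").

### Skeleton graph

The mask is thinned to a 1-px skeleton (Zhang two-subiteration thinning,
8-connected foreground) and converted to a graph with the classic
skeleton-analyzer semantics:

* pixels classify by 8-neighbor count: 1 → endpoint, 2 → slab, ≥ 3 →
  junction pixel; 8-adjacent junction pixels merge into one junction node;
* a branch is a maximal slab run between two node anchor pixels; its length
  α sums pixel steps (1 for orthogonal, √2 for diagonal moves, anchor steps
  included) and β is the Euclidean distance between the two anchor pixels —
  anchoring β at the branch's own terminal pixels (not node centroids)
  guarantees α ≥ β;
* loops (both ends on one node, or pure slab rings) are flagged and excluded
  from the zigzag statistics;
* branches are emitted in raster order of their first slab pixel, so exports
  are deterministic;
* masks that were never thinned (a free-standing 2×2 block anchoring no
  branch) raise `NotASkeleton`.

The implementation is cross-checked for exact agreement — node count, branch
count, and every α — against an independent networkx-based pixel-graph
oracle on hundreds of random skeletons.

### Contact filter and aggregation

Branches with α strictly below 2 μm are eliminated (a 2.0 μm branch
survives); loops are removed. Two optional, off-by-default restrictions are
exposed:

* `require_junction_ends` — keep only tricellular-to-tricellular spans
  (drop endpoint-terminated branches). The base filter is a pure length
  rule; this flag exists because the contact definition speaks of spans
  between tricellular junctions.
* `border_margin_px` — drop contacts whose path approaches the image border.
  Junction lines clipped by the field of view can merge at the border and
  masquerade as a single highly tortuous contact between two real
  tricellular nodes; a margin of a few band widths removes these.

The per-image statistic is the unweighted arithmetic mean of the surviving
contacts' indexes; an image with no surviving contact reports NaN with a
warning rather than a value.

### TJ-band intensity

From the same mask: 8-connected components with area strictly below 4 μm²
are deleted (a 4.0 μm² object survives); the cleaned mask is skeletonized
and re-dilated 6 times (3×3), giving a band 13 px wide on-axis (17 px
diagonally — the square element's Chebyshev geometry); the mean marker
intensity inside the band is the image's value. Within each experiment
(one round of immunostaining) values are divided by the experiment mean, so
normalized values average exactly 1 per experiment; the grouping key is an
explicit manifest column, never inferred from filenames.

### Colocalization

Pearson correlation over all in-scope voxels of complete z-stacks. Costes
thresholds come from the major-axis (total-least-squares) regression of B on
A: candidate thresholds step down the regression line from max(A) in 256
steps until the correlation of voxels strictly below both thresholds first
reaches ≤ 0; if it never does, thresholds fall to the minima and the result
is flagged unconverged. The headline value is the Pearson r of voxels above
both thresholds (the global r is also reported). Significance: channel A is
scrambled in PSF-sized blocks within each z-slice (block = 1 px reduces to a
full per-slice permutation; the ragged margin stays in place), n times
(default 10), and p is the fraction of scrambled correlations ≥ the observed
one — granularity 1/n, deterministic given the seed. The PSF is specified as
a block size in pixels because the physical phrase "1 pixel (208 nm/415 nm)"
is ambiguous between pixel pitch and per-channel PSF width.

## Synthetic scenes

`generate_junction_scene` emulates the imaging regime the analysis targets:

* **Geometry** — n quasi-Poisson-disk seed points in the field, bounded
  Voronoi tessellation (by 4-fold mirror reflection), every cell-cell edge
  replaced by a sinusoidal ruffle displaced perpendicular to its chord by
  A·sin(2πs/λ + φ)·sin²(πs/L). The squared-sine taper pins the tricellular
  endpoints so tessellation topology survives rasterization. True tortuosity
  per edge is computed on a dense polyline (≥ 16 samples/px, quadrature
  error ≪ 0.1%); edges clipped by the field border are drawn but excluded
  from the ground truth (they do not span two tricellular junctions).
* **Rendering** — polylines rasterized to `line_width_px` via a distance
  transform, scaled to `junction_intensity` over `background_intensity`,
  blurred by an isotropic Gaussian PSF, multiplied by a per-slice z envelope
  (half-sine by default), then Poisson shot noise and optional Gaussian read
  noise. Everything derives from one seed; identical parameters reproduce
  the image bit for bit.
* **Colocalization pairs** — channel B mixes a shifted copy of A with an
  independently generated scene plus noise, with the sharing fraction as the
  control variable.

What the generator does **not** emulate: claudin strand meshworks inside
cell-cell overlaps (a super-resolution feature), membrane-vs-junction marker
partitioning, true 3D junction geometry (the z envelope only modulates
intensity), uneven illumination, and spatially correlated noise. Passing the
validation suite therefore demonstrates correctness of the measurement
chain on well-posed junction networks, not robustness to every real-data
pathology.

## Synthetic validation protocol

Fixed in `tjmorph.validation` and exercised by the test suite and
`scripts/acceptance.py`:

* **Scenes**: 1024×1024 px at 0.04 μm/px (≈41 μm field, the frame size of
  typical confocal zigzag images), 14 cells (≈15–19 measurable contacts per
  image), junction line 3 px wide, 200 counts over a 10-count background
  with Poisson noise (SNR ≈ 13), PSF σ = 1 px, ruffle wavelength 2 μm.
* **Analysis**: no extra dilation, median radius 2 px, contacts restricted
  to tricellular-to-tricellular spans, border margin 20 px (≈3 band widths).
  The median radius is scaled to the synthetic band width for the reason
  given above; the remaining defaults are untouched.
* **Amplitude calibration**: the amplitude for a target true mean tortuosity
  is bisected against the realized ground-truth mean over calibration seeds
  (geometry only, no rendering), because short Voronoi edges ruffle
  disproportionately and shift the realized mean above the single-chord
  inversion.
* **Band-intensity scenes**: 768×768 px, 8 cells, 15 px (0.6 μm) junction
  band and gentle ruffling (A = 0.1 μm), so the skeleton-plus-6-dilations
  band covers the junction signal — the premise of the band procedure.

Typical results (seed 1): straight scenes measure 1.04–1.06 (bound 1.08);
recovery errors +4.5% / +3.7% / +2.0% at true means 1.1 / 1.3 / 1.6 with
ordering preserved; band intensity within 10% of the configured value;
normalized group means exactly 1; identical channels give r = 1 with
Costes p = 0, and independent noise channels give |r| < 3/√N with null p
centered near 0.5.

## Numerical conventions and edge cases

* Threshold ties → lowest bin; median ties → foreground; branch discovery →
  raster order; anchor choice is forced by slab-pixel degree (each chain end
  has exactly one non-chain neighbor).
* `zigzag_index` on a loop raises `LoopBranch`; an empty band raises
  `EmptyBand`; zero-variance channels raise `UndefinedCorrelation`;
  coincident edge endpoints raise `DegenerateEdge`.
* Pipeline stages wrap failures in `PipelineError` carrying the stage label.
* TIFF output embeds pixels-per-μm resolution tags and no timestamps, so
  CLI runs with fixed seeds are byte-reproducible.

## Known limitations

* **Digital arc-length bias.** The pixel-step metric (1/√2 steps) measures
  the digital, not the continuous, path length: a straight line at 22.5°
  reads ≈ +8%, an ideal digitized circular arc converges to 4(√2−1)/(π/2) ≈
  +5.5% regardless of radius, and thinning corner-cuts recover only part of
  it (a rasterized semicircle of chord 160 px measures ≈ 1.63 against the
  continuous π/2 ≈ 1.571). Straight-edge image means land at 1.04–1.06
  rather than 1.0 for the same reason. The bias is shared by the standard
  skeleton analyzers this implementation mirrors, affects all conditions of
  a comparison equally, and cancels in orderings; sub-pixel path refinement
  that would remove it is out of scope by design. Absolute index values
  should be compared only between analyses using the same metric.
* The Triangle threshold assumes a dominant background mode with a bright
  object tail; images that are mostly foreground violate it.
* β anchors at branch terminal pixels; analyses anchoring at junction-node
  centroids will differ slightly for thick nodes.
* The Costes stepping rule (256 steps, first r ≤ 0) is one of several
  conventions in circulation; unconverged regressions are flagged rather
  than silently accepted.
* Very short Voronoi edges (≪ 1 μm) can merge into single junction blobs at
  rasterization; ground-truth node degree is preserved, but node counts are
  compared within a border margin and a ±10% tolerance.
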