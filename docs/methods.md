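# Methods

## The measurement model

The pipeline treats a confocal z-stack of a 3D neuronal culture as a
series of independent 2D problems. Axial resolution in such stacks is
poor and noisy relative to the in-plane resolution, so no volumetric
filtering or 3D tracing is attempted; each analyzed optical section is
processed alone and the results are assembled into depth profiles.
Slices are sampled every `interval_um` (default 1.8 µm) from the
substrate plane upward; with the acquisition z-step of 0.3 µm that is
every 6th section. The stride is the nearest integer to
`interval_um / z_step_um`, clamped at 1, and depths are reported from the
substrate slice (`substrate_index`, default 0, exposed because the first
in-focus section need not coincide with the substrate).

Per slice the stages are:

1. **Soma detection** — Gaussian smooth (σ = 2 px), Otsu threshold,
   morphological opening with a disk of radius
   `ceil(sqrt(min_soma_area/π)/2)` to detach 1–2 px neurites, 8-connected
   components, an area band `[min_soma_area_px, max_soma_area_px]`
   (defaults 60–5000 px²), and an optional distance-transform watershed
   (on by default) seeded at the smoothed distance maxima, tie-broken in
   lexicographic (y, x) order. Components above the band (dense cell
   clusters) are excluded from the count but kept in the subtraction
   mask, since their texture would otherwise corrupt orientation
   statistics. Because Otsu always splits a histogram — even of pure
   background — the threshold must clear the sub-threshold *median* by
   `min_contrast_sigma` (default 4) robust standard deviations
   (1.4826·MAD); otherwise the slice is declared cell-free. The MAD is
   used rather than the SD because the low side of the histogram contains
   the smoothed halos of true objects.
2. **Vesselness and orientation** — multiscale Frangi filter at scales
   σ ∈ {1, 2, 3} px (spanning the 1–2 px rendered neurite widths), blob
   sensitivity β = 0.5, structureness scale c set per scale to half the
   maximum S ("auto" mode). Second Gaussian derivative kernels are
   truncated at 4σ and re-centred so they annihilate constants exactly;
   without this, a constant image acquires a spurious Hessian of order
   10⁻³ relative intensity, which auto-c then normalizes to order-one
   vesselness. The filter input is the slice with detected bodies
   *replaced by the background median* (not zeroed, and not left raw):
   zero-filling creates a step edge that scores as a circular ridge just
   outside every mask, while raw somas dominate the auto structureness
   scale and suppress dim neurites. The official subtraction product —
   the outgrowth-only image — still zeroes the dilated body mask.
3. **Skeleton extraction** — the neurite mask is
   `vesselness ≥ threshold` (default 0.15) restricted to nonzero pixels
   of the subtracted image (this applies the body mask, grown by
   `body_dilation_px = 2`, at thresholding time). The mask is
   skeletonized; terminal branches shorter than 4 px (edge-rule) are
   pruned, one-pixel junction nubs whose neighbours remain mutually
   connected are removed, components shorter than 10 px are dropped, and
   components whose mean underlying intensity does not clear the
   background median by 4 robust SDs are discarded (vesselness is
   contrast-normalized per slice, so a structureless slice would
   otherwise skeletonize its own noise).
4. **Length** — the sum over skeleton pixel adjacencies of 1 (axial) or
   √2 (diagonal) times the pixel size. A diagonal adjacency whose two
   pixels already share an axial skeleton neighbour is a corner shortcut,
   not an edge, and is not counted; an L of 35 axial steps therefore
   measures exactly 35 px. Digital straight lines at oblique angles
   measure up to ~8% longer than their Euclidean chord under any such
   rule; all length comparisons in this package are therefore made in
   edge-rule terms on both sides.
5. **Alignment** — support is the set of skeleton pixels with a defined
   ridge orientation; each votes once, so the statistic is length-weighted
   and thick filaments do not vote with their area. A pixel is aligned
   when its axial distance to the groove angle is strictly below 30°; the
   groove angle is a required input, never estimated from the image.
   Under isotropy the expected value is 60/180 = 33.3%. Per-pixel
   orientations are pooled along each skeleton segment (axial circular
   mean on doubled angles) before thresholding: rasterized 1–2 px
   filaments carry several degrees of pixel-level orientation jitter,
   which otherwise partially misclassifies whole neurites whose angle
   sits near the 30° boundary. Junction pixels and junction-to-junction
   stubs shorter than 6 px — crossing artifacts where a ridge direction
   is meaningless — are excluded from the support. Slices with no
   support report alignment as *missing*, never 0 or 33; profiling stops
   after two consecutive zero-outgrowth slices by default, mirroring the
   practice of not analyzing beyond the depth where outgrowths vanish.

## The synthetic stack generator

The generator emulates the structure of a 2D-seeded culture under a
hydrogel, with every parameter a study condition:

- **Geometry** — 41 slices of 384×384 px at 0.5 µm/px and a 0.3 µm
  z-step: a 192×192 µm field over the first 12 µm above the substrate,
  the depth range in which such cultures show dense analyzable outgrowth.
  The field size was chosen for statistical power: deep slices must hold
  enough neurites (~20–50) that per-depth statistics reflect the
  estimator rather than sampling noise.
- **Somas** — a substrate monolayer with expected count
  `n_cells_surface = 90` (≈2400 cells/mm²), plus a migrated population
  for z > 0 with expectation
  `migrated_fraction · n_cells_surface · exp(−z/decay_length_um)`
  (defaults 0.7 and 12 µm, calibrated so a 48-cell surface field decays
  to ~13 cells by 10–15 µm and a handful beyond 20 µm). Counts are
  Poisson; each soma is a filled disk of radius 6–10 px placed fully
  inside the field (border-clipped cells would fail the detector's area
  band for reasons unrelated to detection quality). Somas have no 3D
  extent: each lives in exactly one slice, because the screening method
  analyzes slices independently and cross-slice structure would create
  truth the pipeline cannot see.
- **Neurites** — 1–3 straight segments per soma, 15–50 µm long, 1–2 px
  wide, starting at the soma boundary and confined to the soma's slice.
  Axial orientation is θ = groove + φ/2 with φ ~ von Mises(0, κ(z)) and
  κ(z) = κ_surface · exp(−z/κ_decay); κ = 0 is exactly uniform on
  [0°, 180°). Defaults κ_surface = 1.2 and κ_decay = 3.5 µm give ≈58%
  aligned at the surface relaxing to ≈35% within several µm, the regime
  reported for cortical cultures on 587/219 nm grooves. The decay
  constants are calibration knobs, not measured quantities.
- **Image formation** — signal (somas 160, neurites 110 over a
  background of 40) → Poisson shot noise → additive Gaussian read noise
  (σ = 3) → clip and quantize to uint16. No PSF convolution or optical
  sectioning model is applied. An optional sub-resolution groove texture
  on the substrate slice exists only to stress-test that the alignment
  statistic ignores periodic background.
- **Ground truth** — per slice: soma count, *visible* centreline length
  (edge-rule length of the rasterized path, excluding out-of-field and
  soma-occluded pixels), and the length-weighted fraction of segments
  strictly within 30° of the groove. The full soma and neurite lists are
  stored so truth can be re-derived by brute force in tests.

What passing recovery tests does **not** show about real data: the
generator has no branching trees, no curved or z-spanning neurites, no
PSF blur, no multi-cell-type morphology, and its somas are clean disks.
Detector parameters that recover this truth will need retuning for real
stacks, and absolute agreement with any particular instrument is out of
scope.

## Known biases and limitations

- **Bundle merging.** Nearly parallel neurites closer than ~2 px share
  one ridge and one skeleton line, so aligned outgrowth is slightly
  under-weighted in concentrated regimes; the measured alignment runs
  ~2–3 percentage points below truth at high κ (the benchmark in
  `analysis/03_recovery_benchmark.py` quantifies this). Real cultures
  fasciculate too, so this is a property of any per-pixel screening
  method, not only of this implementation.
- **Length under-measurement near somas.** The subtraction mask is
  slightly larger than the true soma (threshold halo plus 2 px dilation),
  so each neurite loses a few px at its origin; dense-field skeleton
  length runs ~20–25% below the rendered truth while isolated filaments
  are recovered exactly (noise-free) or within ~3% (default noise).
- **Per-slice alignment scatter.** A single slice holds a finite number
  of neurites, so its alignment percentage carries irreducible sampling
  scatter of a few pp; recovery is therefore assessed on per-depth
  aggregates over replicate stacks (support-weighted measured vs
  length-weighted truth), which isolates estimator bias.
- **Degenerate inputs.** Constant slices yield zero vesselness and no
  somas (no error); empty masks yield zero-length skeletons; alignment on
  empty support propagates as a missing value. Eigenvalue ties leave
  orientation undefined and the pixel out of support. Determinism: a
  fixed generator seed yields bit-identical stacks and truth; the
  analysis pipeline is deterministic for fixed inputs.

## Numerical choices

β = 0.5 follows common Frangi practice; auto-c (half the per-scale
maximum S) makes the filter contrast-invariant per slice, which is why
the absolute-intensity anchor on skeleton components is needed as a
counterweight. Kernel truncation is 4σ. Angles are held in degrees on
[0°, 180°) everywhere; axial distance is `min(d, 180 − d)` with
`d = |θ − groove| mod 180`. Watershed seeds are sorted lexicographically
for determinism. CSV floats are written with 3 decimals; missing
alignment serializes as an empty field.
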