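# groovescreen

Automated image-based screening of neurite outgrowth in 3D neuronal
cultures on nanogrooved substrates.

Neurons and neuron-like cells (primary cortical cultures, SH-SY5Y) seeded
on sub-micron groove/ridge patterns align their outgrowths with the groove
axis by contact guidance. When such a 2D culture is overlaid with a
hydrogel, cells migrate tens of µm into the gel and the question becomes
*how far above the substrate the guidance effect persists*. `groovescreen`
answers it from a confocal z-stack: for optical sections sampled at a
fixed physical interval (default 1.8 µm) it reports, per depth,

- **number of cells** — somas detected by smooth → threshold → open →
  label (→ watershed for touching pairs);
- **total outgrowth length (µm)** — cell bodies are subtracted from the
  image, the remaining curvilinear structures are skeletonized to 1-px
  centrelines and measured by the 8-neighbour edge rule (axial step = 1 px,
  diagonal = √2 px);
- **outgrowth alignment (%)** — the percentage of skeleton pixels whose
  axial orientation lies strictly within 30° of the groove axis.

Orientation comes from multiscale Frangi vesselness: per scale σ the
scale-normalized Hessian (second Gaussian derivatives × σ²) is
eigen-decomposed with |λ₁| ≤ |λ₂|, and for bright ridges (λ₂ < 0)

    V = exp(−R_B² / 2β²) · (1 − exp(−S² / 2c²)),
    R_B = λ₁/λ₂,  S = √(λ₁² + λ₂²),

with the ridge direction given by the λ₁ eigenvector at the best scale,
stored as an axial angle in [0°, 180°). An isotropic culture scores 33%
aligned (a 60° window of the 180° axial range), so profiles are read
against that floor.

The study data this method was built for are not publicly deposited, so
the package ships a first-class **synthetic stack generator** with exact
per-slice ground truth: a substrate monolayer of somas with a migrated
population decaying over depth, neurites whose axial orientations follow a
groove-centred axial von Mises model with concentration κ(z) decaying with
height, hydrogel autofluorescence background, Poisson shot noise and
Gaussian readout noise. Every number the pipeline reports is validated by
recovery tests against that truth.

## Worked example

```sh
python analysis/01_simulate_stacks.py     # render three guidance regimes
python analysis/02_depth_profiles.py      # profile them with the pipeline
python analysis/03_recovery_benchmark.py  # compare against ground truth
```

The moderate-guidance regime (κ = 2 at the substrate, decaying with an
e-folding depth of 3.5 µm) prints:

```
moderate:
  z= 0.00 um  cells= 86  outgrowth=  3001.2 um  aligned= 79.0%
  z= 1.80 um  cells= 55  outgrowth=  2277.4 um  aligned= 71.7%
  z= 3.60 um  cells= 49  outgrowth=  2234.5 um  aligned= 43.4%
  z= 5.40 um  cells= 38  outgrowth=  2173.1 um  aligned= 44.7%
  z= 7.20 um  cells= 36  outgrowth=  1658.0 um  aligned= 41.0%
  z= 9.00 um  cells= 20  outgrowth=  1016.2 um  aligned= 31.2%
  z=10.80 um  cells= 25  outgrowth=  1487.9 um  aligned= 45.8%
```

Read: cell count peaks in the dense substrate monolayer and falls with
height as fewer cells migrate that far; alignment starts far above the 33%
isotropic floor at the grooved surface and relaxes toward it within a few
µm — the depth-resolved signature of nanotopographic contact guidance.
The isotropic control (κ = 0) hovers around 33% at every depth.

A `groovescreen` CLI wraps the same pipeline for real data:

```sh
groovescreen analyze --input stack.tif --pixel-size 0.5 --z-step 0.3 \
    --groove-angle 30 --interval 1.8 --out-dir results/
groovescreen simulate --seed 7 --out-dir results/   # synthetic stack + truth
groovescreen evaluate --profile results/…_profile.csv --truth results/…_truth.csv
```

`analyze` writes a CSV with columns
`slice_index,z_um,n_cells,total_outgrowth_um,alignment_pct,support_px`;
alignment is left empty on slices without detectable outgrowth.

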