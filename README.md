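# cellstream

Quantification of collective cell migration in time-lapse microscopy.

Primary mesenchymal cells — for example embryonic palatal mesenchyme in
wound-repair and open-field assays — migrate collectively: they form local
streams, align with neighbors, and advance into cell-free gaps. `cellstream`
turns phase-contrast time-lapse recordings (and DAPI-stained section images)
into the standard quantitative measures of that behavior:

- **Confluency kinetics and wound-front speed.** Cell-occupied area is
  segmented by thresholding the local standard deviation of image brightness
  (cells are textured, the substrate is flat). From the confluency trace
  *A(t)*, the wound-front speed is *V = (w/2)·(dA/dt)* with *w* the field
  width — two fronts advance into the gap.
- **PIV motility.** Velocity fields *v(x,t)* between consecutive frames by
  normalized cross-correlation block matching (50 µm windows, 50% overlap,
  two-pass coarse-to-fine, parabolic subpixel refinement), summarized as the
  spatial mean speed over the cell-occupied area.
- **Trajectory guidance statistics.** For tracked cells *P(i,t)*: total path
  length *T(i,t) = Σ|P(i,t′+1) − P(i,t′)|*, net displacement into the wound
  *D(i,t) = |X(i,t) − X(i,0)|* (projection on the wound axis), and guidance
  efficiency *D/T* ∈ [0, 1], with population mean ± SEM at a chosen time.
- **Co-movement correlation lengths.** The average flow field *U(x)* around
  moving cells (neighbor velocities rotated into each mover's aligned frame
  and binned by relative position) is sampled along the front–rear and
  left–right axes and fitted with *U(x) = a·exp(−x/x₀) + U₀*; *x₀* is the
  velocity correlation length, parallel or perpendicular to motion.
- **Nematic order of nuclei.** Segmented nuclei (global threshold +
  watershed) are reduced to moment ellipses; elongated nuclei define axis
  angles θ and the scalar 2D nematic order parameter
  *S² = ⟨cos 2θ⟩² + ⟨sin 2θ⟩²* on a 50-µm grid or pooled anatomical regions,
  with a Monte-Carlo null threshold for significance.
- **Group statistics.** Per-recording scalars compared by two-tailed Welch
  t-tests (Welch–Satterthwaite df); the unit of replication is always the
  recording or section, never the cell.

A first-class synthetic-data module generates ground-truthed inputs — a
self-propelled particle simulation with Vicsek-style neighbor alignment,
tunable wound-directed bias and soft-core repulsion; a phase-contrast-like
renderer whose speckle texture translates exactly with each cell; and nuclei
fields with prescribed nematic order (von Mises orientations on the doubled
angle) — so every analysis stage is testable by parameter recovery.

## Worked example

```python
from cellstream import (
    SimConfig, ImagingConfig, simulate_cells, render_timelapse,
    segment_confluency, wound_front_speed, population_summary,
)
from cellstream.comovement import correlation_lengths

# wound-repair assay: superconfluent culture, 500-µm gap, fronts
# programmed to advance at 6 µm/h; imaged field centered on the gap
W, field_w = 2200.0, 1000.0
cfg = SimConfig(
    arena_width_um=W, arena_height_um=250, density_per_mm2=1400,
    speed_um_per_h=6.0, rot_diffusion_per_h=0.0, wound_bias=1.0,
    gap_width_um=500, dt_min=30, n_frames=31, seed=0,
)
tracks = simulate_cells(cfg)
movie = render_timelapse(
    tracks, ImagingConfig(cell_radius_um=20),
    field_origin_um=((W - field_w) / 2, 0), field_size_um=(field_w, 250), seed=0,
)
trace = segment_confluency(movie)
res = wound_front_speed(trace, w_um=field_w, fit_interval_h=(1, 15))
print(f"wound-front speed V = {res.V_um_per_h:.2f} um/h (R^2 = {res.r_squared:.4f})")

stats = population_summary(tracks, t_eval_h=10.0)
p = stats.population
print(f"D/T = {p['ratio']['mean']:.3f}")

# correlation length of an aligned open-field culture at 300 cells/mm²
cfg2 = SimConfig(density_per_mm2=300, speed_um_per_h=4.0, align_strength=1.0,
                 align_radius_um=100, rot_diffusion_per_h=0.5, n_frames=61, seed=3)
fits = correlation_lengths(simulate_cells(cfg2))
for name, fit in fits.items():
    print(f"{name}: x0 = {fit.x0_um:.0f} um")
```

Output:

```
wound-front speed V = 6.22 um/h (R^2 = 0.9990)
D/T = 0.977
parallel: x0 = 487 um
perpendicular: x0 = 159 um
```

The recovered front speed matches the programmed 6 µm/h within a few
percent; fully biased cells have guidance efficiency near 1; and the aligned
culture shows co-movement correlations extending over hundreds of µm
(perfectly uncorrelated cultures fit no decay at all — the fit reports the
correlation length unidentifiable).

## Command line

Each analysis is also a subcommand of the `cellstream` entry point:
`simulate`, `confluency`, `wound-speed`, `piv`, `tracks`, `comove`,
`nematic`, `report`. For example:

```sh
cellstream simulate config.yaml --out run1/
cellstream confluency run1/movie.tif --out run1/trace.csv
cellstream wound-speed run1/trace.csv --width-um 1000 --interval 1:15
```

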