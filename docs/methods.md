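# Methods

This note documents the models, estimators and numerical choices behind
`cellstream`, in the spirit of a methods supplement: what each measure
assumes, which knobs matter, and what the synthetic benchmarks do and do not
demonstrate.

## Synthetic motion model

`cellstream.synthetic.simulate_cells` integrates an overdamped
self-propelled particle model, the minimal model with a tunable velocity
correlation length and tunable wound guidance:

- Each cell carries a persistent heading θᵢ. Per step (default Δt = 10 min,
  the usual imaging cadence), the heading relaxes toward the mean heading of
  neighbors within `align_radius_um` (Vicsek-style, weight `align_strength`,
  self included) and accumulates rotational noise of intensity
  `rot_diffusion_per_h` (θ-variance 2·D·Δt).
- The movement direction mixes the heading with a wound-bias unit vector:
  `(1 − wound_bias)·ê(θ) + wound_bias·b̂`, normalized. With no gap, b̂ = +x;
  with a gap, b̂ points toward the gap center from either side, which makes
  both fronts advance. At `wound_bias = 1` motion is exactly along b̂, so
  guidance efficiency is exactly 1 — a useful analytic limit.
- Cells advance at constant `speed_um_per_h` plus a linear soft-core
  repulsion within one cell diameter (2 × `cell_radius_um`, default 20 µm),
  which prevents overlap without stiff integration. The population mean step
  speed equals the speed parameter to within a few percent at moderate
  densities (repulsion adds a small contribution at high density).
- Boundaries: periodic in y, reflecting in x. Reflection flips both the
  position and the heading x-component (billiard reflection); reflecting the
  position alone makes cells accumulate against the walls. The reflecting
  axis keeps a well-defined wound axis; the periodic axis conserves density.
- Cell count = round(density × arena area); trajectories are never created
  or destroyed. Identical seeds give bit-identical output.

Default densities follow the assay conditions the generator emulates: 30,
100, 300 cells/mm² for open-field cultures ("low/medium/high") and
1400 cells/mm² with a 500-µm cell-free strip for wound-repair assays.

### What the renderer emulates — and what it does not

`render_timelapse` draws each cell as a fixed speckle patch (unit-variance
smoothed noise under a soft radial window, grain 2 px) that translates with
the cell via bilinear interpolation, over a uniform background with additive
Gaussian sensor noise, 8-bit output at 1 µm/px. Integer displacements
reproduce the texture exactly, which is what block-matching PIV and
texture-based confluency need; sub-pixel motion is band-limited and
recoverable to ~0.1 px.

Limitations worth knowing:

- Blobs are rigid disks; real confluent monolayers tile the plane by
  deformation. At 1400 cells/mm² randomly placed 20-µm blobs cover only
  ~80–90% of the substrate, so absolute confluency of a rendered "confluent"
  field plateaus near 0.7–0.9 rather than 1.0. Rate-based measures (dA/dt,
  front speed) are unaffected, which is why the wound benchmark programs a
  known *front speed* rather than a known absolute confluency.
- No cell division, death, shape change, or phase-contrast halo optics.
- Wound-repair benchmarks render a field centered on the gap inside a wider
  arena, as in a real microscope field: cells flow in from outside the field
  and the rear depletion stays out of view.

### Nuclei fields

`render_nuclei` places non-overlapping ellipses (bounding-circle test,
rejection sampling, ≤1000 retries per nucleus) and draws axis angles θ such
that 2θ follows a von Mises distribution. The concentration κ is obtained by
numerically inverting the Bessel ratio I₁(κ)/I₀(κ) = S (`kappa_for_order`,
Brent's method on an expanding bracket), so the *expected* sample order
equals the target; the realized order of n nuclei fluctuates by ~n^(−1/2).
`order_target = 1` is the exact parallel limit (κ would be infinite).

## Confluency and wound-front speed

The local standard deviation of brightness in a (2r+1)² window (default
r = 5 px, about the cellular texture scale at 1 µm/px) is computed by box
filters as √(E[x²] − E[x]²) with edge-duplicating reflected padding, and is
invariant to additive brightness shifts.

One global threshold is chosen on the first frame and held for the whole
sequence, so threshold drift cannot contaminate dA/dt. Two choices here are
deliberate:

- **Otsu on the log of the std map.** Texture amplitudes are long-tailed;
  linear Otsu places the threshold inside the textured mode and erodes the
  occupied area by tens of percent. The log transform restores bimodality.
- **Bimodality guard.** If the mean std above the threshold is less than 2×
  the mean below it, the frame contains no separable texture (blank or
  noise-only movie, or a field with no background) and segmentation raises
  an explicit error instead of thresholding noise.

Post-threshold cleanup (morphological closing with a 2-px disk + filling of
holes ≤ 64 px) suppresses speckle; it can be switched off.

dA/dt is the ordinary least-squares slope of A(t) over the fit interval
(default 1–15 h), not frame-to-frame differencing — an interval-average
front speed is what the wound-closure formula V = (w/2)(dA/dt) describes,
and OLS suppresses segmentation noise. A closing wound has rising A, so
V > 0. A constant trace yields V = 0 exactly, with a warning.

## PIV

Two-pass block matching: a first pass at the nominal window (default 50 µm,
50% overlap) with search radius `search_um`; a second pass at half the
window, each fine window's search pre-shifted by the nearest coarse
displacement. Matching uses normalized cross-correlation (gain- and
offset-invariant); the peak is refined per axis by a three-point parabola,
except when the peak is exact (correlation 1.0), where refinement is skipped
— the parabola vertex would otherwise be pulled off-center by texture
asymmetry even at zero displacement. Windows with sub-threshold texture or a
correlation peak below `peak_min` (0.3) are invalid; invalid nodes are
skipped downstream, never interpolated, so no motion is fabricated.
Velocities are µm/h (displacement × pixel size / (Δt/60)).

Known estimator behavior: near-frame-edge windows whose clipped search
region cannot contain the true displacement bias toward smaller shifts
(generic to windowed PIV), and averaging |v| over nodes folds subpixel noise
into a small positive speed bias when per-frame displacements are ≪ 1 px.
At the default cell speeds (~4 µm/h) a 20–30 min pair interval puts
displacements at 1–2 px, where the closure benchmark recovers ground-truth
mean speed within ~5% (the guarantee tested is 25%).

`mean_speed` averages |v| over valid nodes, optionally restricted to an
occupancy mask (nodes sampled at window centers), per frame pair; the scalar
is the time average, with empty frame pairs excluded and warned about.

## Co-movement and correlation length

For every velocity vector faster than `moving_min_um_per_h` (default: the
25th percentile of the recording's speed distribution — scale-free), all
same-frame neighbor velocities are rotated into the mover-aligned frame
(front = direction of motion, left = its 90° CCW normal) and accumulated
into Cartesian bins (default 25 µm, extent ±500 µm — profiles of cultured
mesenchyme decay within ~300 µm, so ±500 µm brackets the decay). Neighbor
*velocities* are rotated as well, so "co-moving speed" is the neighbor
velocity component along the reference direction. Self-pairs are excluded;
empty bins are flagged, never averaged as zero. An optional
`subtract_frame_mean` removes the per-frame mean velocity: with only a few
hundred cells per field the random net flow appears as a spurious
distance-independent correlation; the offset term of the fit also absorbs
it, so the default is off.

Profiles along the front–rear and left–right strips (half-width 1.5 bins)
are count-weighted; the front–rear profile reports the forward and backward
sides separately plus their weighted mean, the lateral profile folds
left/right by symmetry.

The exponential fit U(x) = a·exp(−x/x₀) + U₀ (a ≥ 0) is the numerically
delicate step; profiles from finite recordings carry autocorrelated bin
noise, and the RSS landscape has two degenerate basins (a single-point
"spike" with tiny x₀ and a "flat" mode with x₀ → ∞ trading against U₀).
Three safeguards keep the estimate honest:

- **Multi-start least squares** (four x₀ starts spanning the profile range;
  best weighted RSS wins), with per-point weights σ ∝ 1/√n when bin counts
  are supplied.
- **Range constraints**: x₀ is bounded below by the first sampled distance
  (faster decay is unresolvable at the bin scale) and above by the sampled
  extent (slower decay is indistinguishable from the offset).
- **Amplitude-significance gate**: if the fitted amplitude is below 3× the
  residual standard deviation, the profile is noise-flat and the fit is
  reported unconverged with x₀ undefined. Flat profiles (head
  indistinguishable from tail) short-circuit the same way.

For group comparisons a recording's correlation length is the mean of the
parallel and perpendicular fits, with unconverged fits entered as 0 (an
unidentifiable decay *is* the absence of measurable correlation); this is
the scalar the two-group benchmarks test.

## Nematic order

Nuclei segmentation: global Otsu threshold, watershed on the (smoothed)
distance transform seeded at local maxima ≥ 5 px apart, regions ≤ 10 px
dropped. Ellipses come from second central moments; regions with
minor/major ≥ 0.8 have no reliable axis and are excluded. Angles are
measured from the image +x axis, live on [0°, 180°), and all statistics use
the doubled angle, so θ and θ + 180° are identical and a global rotation
rotates only the prevailing direction, never S.

Grid order uses 50-µm cells with n_min = 3 (one or two nuclei are
degenerately ordered); pooled regional order concatenates nuclei from any
number of specimens into named polygons (shapely point-in-polygon by
centroid) before computing S — pooling is exactly concatenation.

The null threshold for S is the Monte-Carlo `level`-percentile (default
99%) over draws of n uniform orientations; it agrees with the 2D
random-walk closed form √(ln(1/(1−level))/n) within 5% for n ≥ 200 and is
exact at small n where the closed form is not.

## Statistics

Welch's two-tailed t-test with Welch–Satterthwaite degrees of freedom, on
per-recording (or per-section) scalars only. Degenerate inputs are handled
by convention: two identical constant groups give t = 0, p = 1; constant
but unequal groups are flagged degenerate (p = 0, infinite t). SEM uses the
n−1 sample standard deviation. No multiple-testing correction is applied;
reports carry the comparison count alongside raw p-values.

## Benchmark problem sizes

The validation suite chooses sizes that keep the full run in a few minutes
on one CPU while leaving comfortable statistical margins: wound benchmarks
use 2.2 × 0.25 mm arenas at 1400 cells/mm² imaged every 30 min for 15 h;
open-field benchmarks use 1 mm² at 300 cells/mm², 10-min cadence, 61–97
frames; nuclei benchmarks use 400 nuclei per field; the two-group power
benchmark compares 5 + 5 recordings across 10 meta-replicates. Passing these
shows the estimators recover known ground truth under the model's
assumptions (rigid textured blobs, constant speeds, Vicsek alignment); it
does not certify performance on features the generator lacks — deforming
cells, division, illumination drift, or stage jitter.
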