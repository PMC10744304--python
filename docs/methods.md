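# Methods

## Model

Neotissue growth inside a scaffold pore is modelled as interface motion:
the tissue/void boundary Γ advances into the void wherever the void is
locally concave as seen from the tissue, at speed A·κ, and is stationary
where κ ≤ 0. κ is the mean curvature of Γ (units 1/mm), A is a material
constant (mm²/day) absorbing everything biological — proliferation,
matrix deposition, and for active calcium-phosphate ceramics the effect of
released ions. The model deliberately contains no transport, mechanics or
differentiation; its claim is kinematic: curvature controls where and how
fast tissue appears. Two consequences anchor all verification:

* a circular (cylindrical) void of radius r closes along
  r(t) = √(r0² − 2At), a spherical one along r(t) = √(r0² − 4At);
* any convex cross-section loses void area at exactly 2πA per day
  (the turning number of the boundary is 1, and only κ > 0 arcs move), so
  at a common A the day-21 filling of convex channels ranks inversely with
  their initial area. Corners are where growth localizes, which is why the
  equilateral triangle (smallest area at a given side length) fills
  fastest and large flat-walled channels barely fill at all.

The second point is also the model's structural limitation: filling
percentages of convex channels at one observation day are tied to each
other through their areas, whatever the value of A. Observed datasets that
deviate from the 1/area ranking (shape-specific biology, seeding
inhomogeneity) can therefore not be fitted exactly; the calibration
distributes that residual across geometries, and our fit to the packaged
hydroxyapatite table leaves an RMSE of about 14 percentage points. For the
same reason the 2 mm channels cannot fall below ≈0.45× the 1 mm circle's
filling when the triangle's side-length convention is used — a bound worth
keeping in mind when comparing against reported per-size numbers, which in
our runs puts the fastest 2 mm shape in the low twenties of percent rather
than below 20%.

## Discretization

Fields live on uniform isotropic grids (2D cross-sections for prismatic
channels — the beams are translation-invariant along their axis, so
lateral growth has no axial component away from the ends; full 3D for
gyroids and spheres). Lengths are mm, time days.

* **Geometry.** Channel cross-sections are exact signed distances
  (analytic for the circle, point-to-polygon via shapely otherwise),
  positive in the void, with a 4-cell pad beyond the wall. Size
  conventions: circle d = diameter, square/triangle d = side, hexagon
  d = across-flats. The gyroid wall is the band |F| ≤ τ around the minimal
  surface F = sin x̃ cos ỹ + sin ỹ cos z̃ + sin z̃ cos x̃ (x̃ = 2πx/L); τ is
  set from the maximal surface gradient so the thinnest pore-to-pore
  crossing equals the requested wall thickness (first order in τ, verified
  by ray-casting in the tests), and the field is redistanced to a true
  signed distance. When a pore size rather than a period is given, L is
  solved numerically so the largest inscribed pore sphere has that
  diameter; the result is recorded in the field metadata.
* **Initial condition.** φ0 = layer − ψ: a tissue film of the given
  thickness on the wall. ψ being a signed distance, φ0 needs no extra
  redistancing. Default film 10 µm; the gyroid presets L1/L2 (10 µm/1 µm)
  emulate confluent vs sparse seeding, the latter standing in for an
  initial 2D-growth phase the model does not resolve.
* **Normal and curvature.** n = ∇φ/|∇φ| (central differences), then each
  component is passed through the screened-diffusion solve
  (I − εΔ)u = f with homogeneous Neumann walls and renormalized; κ = ∇·n
  gets the same treatment. The solve is done spectrally (DCT-II
  diagonalizes the Neumann Laplacian), i.e. exactly for the discrete
  operator. ε = 1e-4 mm² by default: √ε ≈ one cell at the default
  resolutions, enough to bound the corner singularities of polygonal
  initial data without distorting resolved curvature (the circle's κ is
  reproduced to ~0.1%). κ is additionally clamped to ±1/h; the clamp only
  acts on unresolved corners during the first few steps.
* **Transport.** Semi-Lagrangian (method of characteristics): each node
  samples φ at the foot of its backward characteristic, traced with a
  midpoint (RK2) step and evaluated by linear interpolation with
  nearest-edge extension. Arrival-point (first-order) tracing was measured
  to accelerate shrinking fronts systematically near collapse (−3.8 cells
  at 95% of the circle collapse vs ≤1.5 with RK2). The scheme is
  unconditionally stable; no CFL limit applies.
* **Time stepping.** dt adapts so the interface moves at most
  `max_step_frac` (default 0.5) cells per step, using the maximum speed on
  the narrow band |φ| ≤ 3h. Off-band speeds are ignored on purpose: κ
  computed globally from φ diverges at the medial axis (e.g. a channel
  centre), which is irrelevant to the zero set and harmless to a
  semi-Lagrangian update. Runs land exactly on requested recording days.
* **Redistancing.** Every 5 advection steps (default) the φ = 0 contour is
  extracted by marching squares/cubes (sub-cell accurate), densified, and
  each node receives its k-d-tree distance to the contour point set,
  signed by side. Zero-set displacement is a small fraction of a cell;
  redistancing is skipped while the interface has not moved (exact
  initial data stay exact, and an A = 0 run leaves filling bit-identical).
  The scaffold wall is *not* enforced by freezing φ in the solid: the wall
  is static because it lives in the masks and the speed vanishes where
  κ ≤ 0; freezing was measured to bias near-wall interpolation by about a
  cell at startup.
* **Quantification.** Filling is the mean sub-cell coverage
  clip(½ + φ/2h, 0, 1) over the initial void mask — the seeded film counts
  as filled tissue (at ≤10 µm on ≥0.5 mm channels the offset is a few
  percent). Circularity is 4π·Area/Perimeter² of the marching-squares
  contour (sphericity in 3D); it rises toward 1 as polygonal channels
  round off. Simulations assert per-step monotonicity of filling (no
  retraction, tolerance 2e-3 for redistancing jitter) and stop early at
  99.9% filling, reporting the full-fill time.

Verification levels: circle collapse at h = 0.01 mm tracks the analytic
radius within ~1.5 cells everywhere and ~0.5 cells over 80% of the
collapse, full-fill time −1.4% of r0²/2A; the 64³ sphere stays within
2 cells down to a 3-cell radius; halving the spacing moves day-21 filling
of the 1 mm circle by < 2 percentage points.

## Calibration

One A per material, shared across shapes and sizes. The objective is the
RMSE (percentage points) between simulated and observed fillings at the
observation days (day 10 and 21); observed values pooled over shapes are
compared against the mean of the four simulated cross-sections at that
size. The optimizer is SMBO over log10 A ∈ [1e-4, 1] mm²/day (spanning
sub-day to multi-year fill times for millimetre channels): a Gaussian
process (Matérn 5/2, fitted noise floor) is refit after every evaluation
and the next point maximizes expected improvement over a fixed candidate
grid; the first six points are a seeded stratified design. Everything is
deterministic given the seed — re-running reproduces the trace exactly.
25 evaluations locate the optimum of the packaged tables robustly (the
same A* to three significant figures across seeds 0–4).

The pseudo-data generator runs the simulator itself at a known A_true,
samples the filling at the observation days, and adds seeded Gaussian
noise in percentage points (clipped to [0, 100]). It emulates the
*structure* of the observation tables, not their biology: real
measurements carry shape-specific and replicate variability, segmentation
bias and day-to-day culture effects that are not Gaussian or independent.
Recovery experiments therefore demonstrate that the inverse problem is
well-posed and the optimizer sound — not that A is identifiable to the
same accuracy from wet-lab data. Recovery uses a 2 mm circle plus a 1 mm
triangle: fast-growing coefficients saturate small channels before day 10,
which would make A unidentifiable from small-channel observations alone.

## Default problem sizes

Channel production runs use spacing d/50 (the calibration default);
coarse test and recovery runs use d/25, where day-21 filling differs from
d/50 by at most a couple of percentage points. Gyroid runs default to one
unit cell at half-wall-thickness spacing with a configurable voxel budget
guard. These sizes were chosen so that a full calibration (25 evaluations
× 8 channel simulations) completes in about a minute on one CPU while
staying inside the grid-convergence envelope above.

## Known limitations

* No nutrient, oxygen, flow or differentiation coupling; A lumps all
  biology and material activity, so it is valid only for the culture
  conditions it was calibrated on.
* The convex-channel area law ties per-shape fillings together (see
  above); shape-specific deviations in data become irreducible residual.
* The initial 2D spreading phase after sparse seeding is only emulated by
  a thinner initial film, not modelled.
* Curvature at freshly initialized polygon corners is unresolved by
  construction (clamped at 1/h); corner rounding during the first few
  steps is therefore grid-regularized, though the integrated area loss it
  controls converges under refinement.
* The gyroid wall-thickness calibration is first order in τ and verified
  to 10%; very thick walls relative to the period are rejected rather
  than approximated.
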