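# neogrowth

Curvature-driven neotissue growth simulation in additively manufactured
scaffold pores, with Bayesian calibration of the growth coefficient.

## The problem

When skeletal progenitor cells are cultured inside the pores of a bone
scaffold (calcium-phosphate ceramics such as hydroxyapatite (HAp),
tricalcium phosphate (TCP) or their 60/40 blend BCP), the neotissue — cells
plus the extracellular matrix they deposit — does not advance uniformly.
Deposition starts in corners and concave regions and stalls on flat or
convex walls: the local interface speed is proportional to the positive
local mean curvature. This package implements that growth law for scaffold
designers who want to rank candidate pore shapes and sizes in silico before
printing them.

## The model

The neotissue/void interface Γ is the zero set of a level-set function φ
(φ > 0 in neotissue, φ < 0 in the void) transported by

    ∂φ/∂t + V·∇φ = 0,      V = A · g(κ) · n,
    g(κ) = −κ if κ > 0, else 0,

with n = ∇φ/|∇φ| the unit normal pointing into the tissue and κ = ∇·n the
mean curvature (1/r for a cylindrical void of radius r, 2/r for a sphere).
Normal and curvature are regularized by a screened-diffusion solve
(I − εΔ)u = f with homogeneous Neumann boundaries; φ is periodically
redistanced back to a signed distance function. The single biological
parameter A (mm²/day) is calibrated per material by sequential model-based
(Bayesian) optimization against observed channel-filling percentages,
minimizing the RMSE at the measurement days.

Geometry generators cover the four prismatic channel cross-sections
(triangle, square, hexagon, circle; size parameter d) and 3D gyroid
networks (period or target pore size, wall thickness), both delivered as
signed distance fields. A useful closed-form consequence of the growth law:
a convex void loses cross-section area at exactly 2πA per day, so the
circular channel collapses along r(t) = √(r0² − 2At).

## Worked example

Simulate a 1 mm square channel in a material with A = 0.003 mm²/day,
starting from a 10 µm seeded cell film:

```bash
neogrowth simulate-channel --shape square --d 1.0 --a 0.003 \
    --spacing 0.02 --t-end 30 --record-at 10,21 --out sq_run
```

prints

```
day 10: filling 23.28%
day 21: filling 45.06%
day 30: filling 62.73%
```

i.e. growth from the four corners fills 23% of the cross-section by day 10
and 45% by day 21; the interface has rounded into a shrinking near-circle
(its length drops from 3.12 mm at day 10 to 2.63 mm at day 21, visible in
`sq_run/filling.csv`). The run directory also holds the final φ field as
VTK image data and a `metadata.json` sidecar that records every parameter
needed to reproduce the run.

Calibrating A against the packaged hydroxyapatite observations:

```bash
neogrowth calibrate --material HAp --n-iter 25 --seed 1 --out hap.json
# A* = 0.0027384 mm²/day  (RMSE 13.75 pp, 25 evaluations)
```

The same machinery is available as a library (`neogrowth.simulate`,
`neogrowth.bayes_optimize`, …); see `docs/methods.md` for the numerical
details and modelling assumptions.

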