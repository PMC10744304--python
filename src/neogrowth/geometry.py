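"""Implicit scaffold geometry: channel cross-sections and gyroid walls.

Every geometry is delivered as a signed distance field ψ on a uniform grid,
with ψ > 0 inside the pore/channel void, ψ = 0 on the scaffold wall and
ψ < 0 inside the solid.  ``initial_levelset`` turns ψ into the level-set
state φ₀ = layer − ψ that seeds growth with a neotissue film of the given
thickness on the wall.

Size conventions (lengths in mm):

* circle — ``d`` is the diameter;
* square and triangle — ``d`` is the side length;
* hexagon — ``d`` is the across-flats diameter (inradius ``d/2``, matching
  the circle's behaviour; the across-corners width is ``2d/√3``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely

from .fields import LevelSetState, ScalarField

CHANNEL_SHAPES = ("triangle", "square", "hexagon", "circle")

#: shape/size pairs of the printed disk design (any positive d is accepted)
TABLE1_GEOMETRIES: tuple[tuple[str, float], ...] = tuple(
    [(s, d) for s in ("circle", "hexagon") for d in (0.5, 0.7, 1.0)]
    + [(s, d) for s in ("square", "triangle") for d in (0.7, 1.0, 2.0)]
)


@dataclass(frozen=True)
class ChannelSpec:
    """A prismatic channel: cross-section shape plus size parameter d."""

    shape: str
    d: float
    height: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in CHANNEL_SHAPES:
            raise ValueError(
                f"unknown shape {self.shape!r}; expected one of {CHANNEL_SHAPES}"
            )
        if self.d <= 0:
            raise ValueError("channel size d must be positive")

    @property
    def geometry_id(self) -> str:
        return f"{self.shape}-{self.d:g}mm"


@dataclass(frozen=True)
class GyroidSpec:
    """Gyroid scaffold: unit-cell period L, wall thickness, cell count."""

    period: float
    wall_thickness: float
    n_cells: int = 1
    initial_layer: float = 0.010

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness < self.period / 2:
            raise ValueError("require 0 < wall_thickness < period/2")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def geometry_id(self) -> str:
        return f"gyroid-L{self.period:g}-w{self.wall_thickness:g}mm"

    @classmethod
    def from_pore_size(
        cls,
        pore_size: float,
        wall_thickness: float,
        n_cells: int = 1,
        initial_layer: float = 0.010,
        resolution: int = 48,
    ) -> "GyroidSpec":
        """Choose the period so the largest sphere inscribed in the pore
        space has diameter ``pore_size`` (computed numerically from ψ)."""
        L = period_for_pore_size(pore_size, wall_thickness, resolution=resolution)
        return cls(L, wall_thickness, n_cells, initial_layer)


def channel_polygon(spec: ChannelSpec) -> shapely.Polygon:
    """Cross-section polygon centred on its centroid (circle → 128-gon not
    used; circles are handled analytically)."""
    d = spec.d
    if spec.shape == "square":
        h = d / 2
        verts = [(-h, -h), (h, -h), (h, h), (-h, h)]
    elif spec.shape == "triangle":
        R = d / math.sqrt(3.0)  # circumradius of equilateral triangle, side d
        ang = np.deg2rad([90.0, 210.0, 330.0])
        verts = [(R * math.cos(a), R * math.sin(a)) for a in ang]
    elif spec.shape == "hexagon":
        R = d / math.sqrt(3.0)  # circumradius for across-flats d
        ang = np.deg2rad([0.0, 60.0, 120.0, 180.0, 240.0, 300.0])
        verts = [(R * math.cos(a), R * math.sin(a)) for a in ang]
    else:
        raise ValueError(f"no polygon for shape {spec.shape!r}")
    return shapely.Polygon(verts)


def channel_sdf(spec: ChannelSpec, spacing: float, pad_cells: int = 4) -> ScalarField:
    """Signed distance into the channel void on a 2D grid.

    ψ > 0 inside the channel, ψ = 0 on the wall, ψ < 0 in the solid; the
    grid extends ``pad_cells`` cells beyond the wall on every side.
    """
    if spacing > spec.d / 20:
        raise ValueError(
            f"spacing {spacing} too coarse for d={spec.d}; need <= d/20"
        )
    pad = pad_cells * spacing
    if spec.shape == "circle":
        r = spec.d / 2
        lo, hi = -r - pad, r + pad
        n = int(math.ceil((hi - lo) / spacing)) + 1
        x = lo + spacing * np.arange(n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        psi = r - np.hypot(xx, yy)
        return ScalarField(psi, spacing, (lo, lo), meta=_channel_meta(spec))
    poly = channel_polygon(spec)
    xmin, ymin, xmax, ymax = poly.bounds
    x0, y0 = xmin - pad, ymin - pad
    nx = int(math.ceil((xmax + pad - x0) / spacing)) + 1
    ny = int(math.ceil((ymax + pad - y0) / spacing)) + 1
    xx, yy = np.meshgrid(
        x0 + spacing * np.arange(nx), y0 + spacing * np.arange(ny), indexing="ij"
    )
    pts = shapely.points(xx.ravel(), yy.ravel())
    dist = shapely.distance(pts, poly.boundary)
    sign = np.where(shapely.contains(poly, pts), 1.0, -1.0)
    psi = (sign * dist).reshape(xx.shape)
    return ScalarField(psi, spacing, (x0, y0), meta=_channel_meta(spec))


def _channel_meta(spec: ChannelSpec) -> dict:
    return {
        "geometry_id": spec.geometry_id,
        "shape": spec.shape,
        "d_mm": spec.d,
        "kind": "channel",
    }


# ---------------------------------------------------------------------------
# gyroid


def gyroid_field(x, y, z, period: float):
    """The gyroid level function F; F = 0 is the minimal midsurface."""
    w = 2 * math.pi / period
    return (
        np.sin(w * x) * np.cos(w * y)
        + np.sin(w * y) * np.cos(w * z)
        + np.sin(w * z) * np.cos(w * x)
    )


def gyroid_gradient(x, y, z, period: float):
    w = 2 * math.pi / period
    gx = w * (np.cos(w * x) * np.cos(w * y) - np.sin(w * z) * np.sin(w * x))
    gy = w * (np.cos(w * y) * np.cos(w * z) - np.sin(w * x) * np.sin(w * y))
    gz = w * (np.cos(w * z) * np.cos(w * x) - np.sin(w * y) * np.sin(w * z))
    return gx, gy, gz


# |F| at which the two pore labyrinths of the thickened gyroid pinch shut;
# walls requiring tau beyond this are not manufacturable as a single sheet.
_TAU_PINCH = 1.413


def gyroid_sdf(spec: GyroidSpec, spacing: float) -> ScalarField:
    """Signed distance field of the thickened gyroid: ψ > 0 in the pore,
    ψ ≤ 0 in the wall (the set |F| ≤ τ around the midsurface).

    τ is chosen from the surface-maximal |∇F| so that the *thinnest*
    pore-to-pore crossing of the wall equals ``wall_thickness`` (to first
    order in τ); the result is redistanced to a true signed distance.
    """
    if spacing > spec.wall_thickness / 2:
        raise ValueError(
            f"spacing {spacing} too coarse; need <= wall_thickness/2 "
            f"= {spec.wall_thickness / 2}"
        )
    L = spec.period
    extent = spec.n_cells * L
    n = max(int(round(extent / spacing)), 8) + 1
    h = extent / (n - 1)  # snap spacing so the box is an exact cell multiple
    ax = h * np.arange(n)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    F = gyroid_field(xx, yy, zz, L)
    gx, gy, gz = gyroid_gradient(xx, yy, zz, L)
    gmag = np.sqrt(gx**2 + gy**2 + gz**2)
    near = np.abs(F) < 0.2
    gmax = float(gmag[near].max()) if near.any() else float(gmag.max())
    tau = 0.5 * spec.wall_thickness * gmax
    if tau > _TAU_PINCH:
        raise ValueError(
            f"wall thickness {spec.wall_thickness} not achievable at period {L}"
        )
    from .lsm import redistance  # local import: lsm does not import geometry

    raw = ScalarField(np.abs(F) - tau, h, (0.0, 0.0, 0.0))
    psi = redistance(raw)
    psi.meta = {
        "geometry_id": spec.geometry_id,
        "kind": "gyroid",
        "period_mm": L,
        "wall_thickness_mm": spec.wall_thickness,
        "tau": tau,
        "n_cells": spec.n_cells,
    }
    return psi


def measure_pore_diameter(psi: ScalarField) -> float:
    """Diameter of the largest sphere inscribed in the pore space (ψ > 0)."""
    return 2.0 * float(psi.values.max())


def period_for_pore_size(
    pore_size: float,
    wall_thickness: float,
    resolution: int = 48,
    tol: float = 1e-3,
) -> float:
    """Solve for the gyroid period L such that the largest inscribed pore
    sphere has diameter ``pore_size``.  Monotone in L; solved by bisection."""
    from scipy.optimize import brentq

    def f(L: float) -> float:
        spec = GyroidSpec(L, wall_thickness)
        psi = gyroid_sdf(spec, spacing=L / resolution)
        return measure_pore_diameter(psi) - pore_size

    lo = max(pore_size, 2.5 * wall_thickness)
    hi = 4.0 * pore_size + 2 * wall_thickness
    while f(lo) > 0:
        lo *= 0.8
        if lo < 0.2 * pore_size:
            raise ValueError("no period found (pore too small for this wall)")
    return float(brentq(f, lo, hi, xtol=tol * pore_size))


# ---------------------------------------------------------------------------
# initial condition


def initial_levelset(domain: ScalarField, layer: float) -> LevelSetState:
    """Seed the growth simulation with a neotissue film on the wall.

    φ₀ = layer − ψ in the void: the band of thickness ``layer`` along the
    wall starts as neotissue (φ₀ > 0), the rest of the pore as void.  Since
    ψ is a signed distance, φ₀ already satisfies |∇φ| = 1 and needs no
    further redistancing.  The solid (ψ ≤ 0) is masked out of the dynamics.
    """
    if layer < 0:
        raise ValueError("initial layer thickness must be >= 0")
    psi = domain.values
    void0 = psi > 0
    if not void0.any():
        raise ValueError("domain has no void region (psi <= 0 everywhere)")
    phi0 = layer - psi
    meta = dict(domain.meta)
    meta["initial_layer_mm"] = layer
    if layer >= float(psi.max()):
        meta["already_full"] = True  # void pre-filled; filling_fraction = 1
    return LevelSetState(
        phi=domain.with_values(phi0),
        time=0.0,
        void0_mask=void0,
        solid_mask=~void0,
        meta=meta,
    )
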