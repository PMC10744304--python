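"""Uniform-grid scalar and vector fields.

All lengths are in millimetres and the grid is isotropic: a field of shape
``(nx, ny[, nz])`` samples node ``(i, j[, k])`` at physical position
``origin + spacing * (i, j[, k])``.  Axis 0 is x, axis 1 is y, axis 2 is z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass
class ScalarField:
    """Scalar values on a regular, isotropic grid.

    Parameters
    ----------
    values : ndarray
        Node values, shape ``(nx, ny)`` or ``(nx, ny, nz)``.
    spacing : float
        Grid spacing in mm (same along every axis).
    origin : tuple of float
        Physical coordinates of node ``(0, 0[, 0])`` in mm.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.values.ndim not in (2, 3):
            raise ValueError("ScalarField supports 2D or 3D grids")
        if not self.origin:
            self.origin = (0.0,) * self.values.ndim
        if len(self.origin) != self.values.ndim:
            raise ValueError("origin length must match field dimensionality")

    @property
    def dim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def axes(self) -> list[np.ndarray]:
        """Physical coordinates along each axis."""
        return [
            self.origin[a] + self.spacing * np.arange(n)
            for a, n in enumerate(self.shape)
        ]

    def meshgrid(self) -> list[np.ndarray]:
        return list(np.meshgrid(*self.axes(), indexing="ij"))

    def with_values(self, values: np.ndarray) -> "ScalarField":
        return replace(self, values=np.asarray(values, dtype=float))

    def copy(self) -> "ScalarField":
        return replace(self, values=self.values.copy())


@dataclass
class VectorField:
    """Colocated vector field: one value array per spatial component."""

    components: list[np.ndarray]
    spacing: float
    origin: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.components = [np.asarray(c, dtype=float) for c in self.components]
        shapes = {c.shape for c in self.components}
        if len(shapes) != 1:
            raise ValueError("vector components must share one grid")
        if len(self.components) != self.components[0].ndim:
            raise ValueError("need one component per spatial axis")
        if not self.origin:
            self.origin = (0.0,) * len(self.components)

    @property
    def dim(self) -> int:
        return len(self.components)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(sum(c * c for c in self.components))


@dataclass
class LevelSetState:
    """The evolving simulation object.

    ``phi`` is positive in neotissue, negative in the void, zero on the
    interface.  ``void0_mask`` marks the initial void (inside the channel or
    pore, outside the solid wall); filling is always measured against it.
    ``solid_mask`` marks scaffold material, where ``phi`` is held fixed.
    """

    phi: ScalarField
    time: float = 0.0
    void0_mask: np.ndarray | None = None
    solid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.void0_mask is not None:
            self.void0_mask = np.asarray(self.void0_mask, dtype=bool)
            if self.void0_mask.shape != self.phi.shape:
                raise ValueError("void0_mask shape must match phi")
        if self.solid_mask is not None:
            self.solid_mask = np.asarray(self.solid_mask, dtype=bool)
            if self.solid_mask.shape != self.phi.shape:
                raise ValueError("solid_mask shape must match phi")

    def copy(self) -> "LevelSetState":
        return LevelSetState(
            phi=self.phi.copy(),
            time=self.time,
            void0_mask=None if self.void0_mask is None else self.void0_mask.copy(),
            solid_mask=None if self.solid_mask is None else self.solid_mask.copy(),
            meta=dict(self.meta),
        )


def gradient(values: np.ndarray, spacing: float) -> list[np.ndarray]:
    """Central-difference gradient (one-sided at the box boundary)."""
    out = np.gradient(values, spacing, edge_order=1)
    return list(out) if isinstance(out, (list, tuple)) else [out]


def divergence(components: Sequence[np.ndarray], spacing: float) -> np.ndarray:
    return sum(
        np.gradient(c, spacing, axis=a, edge_order=1)
        for a, c in enumerate(components)
    )
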