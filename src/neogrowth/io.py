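"""Writers: VTK image data, STL surfaces, CSV series, metadata JSON."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .fields import ScalarField


def write_vti(field: ScalarField, path, name: str = "phi") -> None:
    """Write a scalar field as ASCII VTK XML image data (.vti)."""
    v = field.values
    if v.ndim == 2:
        v = v[:, :, None]
        origin = (*field.origin, 0.0)
    else:
        origin = field.origin
    nx, ny, nz = v.shape
    extent = f"0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"
    h = field.spacing
    # VTK expects x varying fastest
    flat = v.ravel(order="F")
    body = "\n".join(
        " ".join(f"{x:.9g}" for x in flat[i : i + 8])
        for i in range(0, flat.size, 8)
    )
    xml = f"""<?xml version="1.0"?>
<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">
  <ImageData WholeExtent="{extent}" Origin="{origin[0]} {origin[1]} {origin[2]}" Spacing="{h} {h} {h}">
    <Piece Extent="{extent}">
      <PointData Scalars="{name}">
        <DataArray type="Float64" Name="{name}" format="ascii">
{body}
        </DataArray>
      </PointData>
      <CellData/>
    </Piece>
  </ImageData>
</VTKFile>
"""
    Path(path).write_text(xml)


def write_surface_stl(field: ScalarField, path, level: float = 0.0) -> None:
    """Export the zero surface of a 3D field as STL (inspection only)."""
    import trimesh
    from skimage import measure

    if field.dim != 3:
        raise ValueError("STL export needs a 3D field")
    verts, faces, _, _ = measure.marching_cubes(
        field.values, level, spacing=(field.spacing,) * 3
    )
    verts = verts + np.asarray(field.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(path)


def render_contour_png(state, path, title: str | None = None) -> None:
    """Contour-overlay render of a 2D state: wall (void mask edge) plus the
    current φ = 0 growth front."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phi = state.phi
    if phi.dim != 2:
        raise ValueError("contour render is 2D only")
    x, y = phi.axes()
    fig, ax = plt.subplots(figsize=(4, 4))
    if state.void0_mask is not None:
        ax.contour(
            x, y, state.void0_mask.T.astype(float), levels=[0.5],
            colors="k", linewidths=1.0,
        )
    ax.contour(x, y, phi.values.T, levels=[0.0], colors="tab:green")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def write_metadata(path, payload: dict) -> None:
    """Dump run metadata (config, params, seed, version) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
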