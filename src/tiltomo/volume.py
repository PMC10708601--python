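"""Volume assembly, orthogonal reslicing and TIFF export.

Axis convention (the default, "fig6"): ``x`` runs along the image columns
(the rotation axis), ``z`` along the image rows (the detector direction) and
``y`` is the optical/depth axis perpendicular to the slide.  Reconstructed
slices live in the (y, z) plane, one per rotation-axis position, so the
voxel grid is stored as ``voxels[x, y, z]``.

Reslicing families:

================  ==========  ====================================
plane             fixed axis  image layout (columns x rows)
================  ==========  ====================================
axial             z           x across columns, y down rows
coronal           y           x across columns, z down rows
sagittal          x           y across columns, z down rows
================  ==========  ====================================

The alternative convention "prose" swaps the roles of x and z (the written
axis description and the figure-based one in the source protocol disagree;
both readings are reproducible via ``plane_convention``).  Voxel spacing is
assumed isotropic and is recorded as metadata only — the depth scale of the
reconstructed y axis is uncalibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, ContractError
from .reconstruct import Slice2D

__all__ = ["Volume", "assemble_volume", "reslice", "export_stack"]

_PLANES = ("axial", "coronal", "sagittal")
_CONVENTIONS = ("fig6", "prose")


@dataclass
class Volume:
    """3D intensity grid ``voxels[x, y, z]`` with its axis record."""

    voxels: np.ndarray
    axes: tuple[str, str, str] = ("x", "y", "z")
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ContractError("voxels must be 3D")
        if sorted(self.axes) != ["x", "y", "z"]:
            raise ContractError("axis record must name x, y, z exactly once")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def assemble_volume(slices: list[Slice2D], method: str = "") -> Volume:
    """Stack reconstructed (y, z) slices along the rotation axis (x).

    Slices are stacked in index order; voxel values are preserved
    bit-exactly.
    """
    if len(slices) == 0:
        raise ContractError("need at least one slice")
    shapes = {s.pixels.shape for s in slices}
    if len(shapes) != 1:
        raise ContractError(f"slices disagree in shape: {sorted(shapes)}")
    voxels = np.stack([s.pixels for s in slices], axis=0)
    method = method or (slices[0].method if slices[0].method else "")
    return Volume(voxels, axes=("x", "y", "z"), method=method)


def _resolve_plane(plane: str, convention: str) -> str:
    if convention not in _CONVENTIONS:
        raise ConfigError(f"unknown plane convention {convention!r}")
    if plane not in _PLANES:
        raise ContractError(f"unknown plane {plane!r}; choose from {_PLANES}")
    if convention == "prose":
        # the prose reading swaps the x and z axis labels, which exchanges
        # the axial and sagittal families and transposes the coronal one
        plane = {"axial": "sagittal", "sagittal": "axial", "coronal": "coronal"}[plane]
    return plane


def reslice(
    volume: Volume, plane: str, index: int, convention: str = "fig6"
) -> np.ndarray:
    """Extract one 2D section of the given plane family.

    The first named axis of the plane runs across the image columns, the
    second down the rows (see the module docstring's table).
    """
    plane = _resolve_plane(plane, convention)
    n_x, n_y, n_z = volume.shape
    v = volume.voxels
    if plane == "axial":  # x-y at fixed z: image[y, x]
        if not 0 <= index < n_z:
            raise ContractError(f"axial index {index} out of range [0, {n_z})")
        return v[:, :, index].T.copy()
    if plane == "coronal":  # x-z at fixed y: image[z, x]
        if not 0 <= index < n_y:
            raise ContractError(f"coronal index {index} out of range [0, {n_y})")
        return v[:, index, :].T.copy()
    # sagittal: y-z at fixed x: image[z, y]
    if not 0 <= index < n_x:
        raise ContractError(f"sagittal index {index} out of range [0, {n_x})")
    return v[index, :, :].T.copy()


def plane_extent(volume: Volume, plane: str, convention: str = "fig6") -> int:
    """Number of sections in the given plane family."""
    plane = _resolve_plane(plane, convention)
    n_x, n_y, n_z = volume.shape
    return {"axial": n_z, "coronal": n_y, "sagittal": n_x}[plane]


def export_stack(
    volume: Volume,
    plane: str,
    directory: str | Path,
    bit_depth: int = 16,
    convention: str = "fig6",
) -> list[Path]:
    """Write one grayscale TIFF per section of the plane family.

    Intensities are min-max normalized over the whole *volume* (not per
    slice) so relative contrast across sections is preserved; a constant
    volume maps to all zeros.  A JSON sidecar records the axis convention
    and method.  Returns the written paths in index order.
    """
    if bit_depth not in (8, 16):
        raise ConfigError(f"bit_depth must be 8 or 16, got {bit_depth}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo = float(volume.voxels.min())
    span = float(volume.voxels.max()) - lo
    vmax = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    n = plane_extent(volume, plane, convention)
    width = max(3, len(str(n - 1)))
    paths: list[Path] = []
    for i in range(n):
        img = reslice(volume, plane, i, convention)
        if span > 0:
            scaled = np.round((img - lo) / span * vmax)
        else:
            scaled = np.zeros_like(img)
        path = directory / f"{plane}_{i:0{width}d}.tif"
        try:
            tifffile.imwrite(path, scaled.astype(dtype))
        except OSError as exc:  # pragma: no cover - depends on filesystem
            raise OSError(f"failed to write {path}: {exc}") from exc
        paths.append(path)
    sidecar = {
        "plane": plane,
        "convention": convention,
        "axes": list(volume.axes),
        "method": volume.method,
        "bit_depth": bit_depth,
        "normalization": {"min": lo, "span": span},
        "voxel_spacing": "isotropic (depth axis uncalibrated)",
        **volume.meta,
    }
    (directory / f"{plane}_meta.json").write_text(json.dumps(sidecar, indent=2))
    return paths
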