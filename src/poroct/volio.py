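"""Image-stack I/O with explicit voxel-size metadata.

MicroCT exports are isotropic 3D grayscale grids delivered either as a
multipage TIFF or as a directory of equally sized per-slice images.  The
voxel size is never trusted from TIFF resolution tags: it must be supplied
by the caller or by a YAML sidecar written next to the stack.

Axis convention: axis 0 is the scan axis (the bone long axis after
alignment), axes 1 and 2 are in-plane rows and columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "SliceWindow",
    "read_stack",
    "write_stack",
    "slices_for_height",
    "select_window",
]

_SLICE_EXTS = {".tif", ".tiff", ".png"}


@dataclass
class VoxelVolume:
    """An isotropic 3D grayscale volume.

    Parameters
    ----------
    data : ndarray, shape (slice, row, column)
        Intensity grid.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres; shared by all axes.
    provenance : str
        Free-text metadata (scan settings, phantom spec id, ...).
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a non-empty 3D array")
        if not (self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.voxel_size_um, self.provenance)


@dataclass(frozen=True)
class SliceWindow:
    """A contiguous run of slices along the scan axis (0-based)."""

    start_slice: int
    n_slices: int

    def __post_init__(self) -> None:
        if self.start_slice < 0:
            raise ValueError("start_slice must be >= 0")
        if self.n_slices <= 0:
            raise ValueError("n_slices must be positive")


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "voxel_metadata.yaml"
    return path.with_suffix(path.suffix + ".yaml")


def read_stack(path: str | os.PathLike, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a multipage TIFF or a directory of slice images.

    ``voxel_size_um`` overrides any sidecar value; if omitted, the YAML
    sidecar written by :func:`write_stack` is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")

    provenance = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        provenance = str(meta.get("provenance", ""))
        if voxel_size_um is None:
            voxel_size_um = meta.get("voxel_size_um")
    if voxel_size_um is None:
        raise ValueError(f"voxel size not given and no sidecar found for {path}")
    if not (float(voxel_size_um) > 0):
        raise ValueError("voxel_size_um must be positive")

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS)
        if not files:
            raise ValueError(f"directory contains no slice images: {path}")
        slices = [tifffile.imread(f) if f.suffix.lower() in (".tif", ".tiff")
                  else _read_png(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"heterogeneous slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    return VoxelVolume(data, float(voxel_size_um), provenance)


def _read_png(f: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(f)
    if arr.ndim == 3:  # collapse RGB(A) exports to grayscale
        arr = arr[..., 0]
    return arr


def write_stack(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a multipage TIFF plus a YAML sidecar carrying the voxel size."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, np.ascontiguousarray(vol.data), photometric="minisblack")
    meta = {"voxel_size_um": float(vol.voxel_size_um), "provenance": vol.provenance}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def slices_for_height(height_mm: float, voxel_size_um: float) -> int:
    """Number of slices spanning a physical height.

    A 1.2 mm analysis window is 600 slices at 2 μm voxels and 1200 slices
    at 1 μm voxels.
    """
    if not (height_mm > 0 and voxel_size_um > 0):
        raise ValueError("height and voxel size must be positive")
    return int(round(height_mm * 1000.0 / voxel_size_um))


def select_window(vol: VoxelVolume, window: SliceWindow) -> VoxelVolume:
    """Extract a contiguous sub-volume along the scan axis."""
    stop = window.start_slice + window.n_slices
    if stop > vol.data.shape[0]:
        raise ValueError(
            f"window [{window.start_slice}, {stop}) overruns stack of "
            f"{vol.data.shape[0]} slices"
        )
    return VoxelVolume(vol.data[window.start_slice:stop], vol.voxel_size_um, vol.provenance)
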