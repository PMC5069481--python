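"""Binarisation, morphology and volume-based despeckling.

This is the pre-analysis chain of a CTAn-style bone workflow: Otsu (or
manual global) thresholding, a 3D closing, removal of connected components
below/above a physical volume, and automatic construction of the cortical
region of interest (the solid annulus that hugs the cortex and contains no
pore voids).

Connectivity convention: 26-connectivity for the foreground phase and
6-connectivity for background holes — the standard complementary pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volio import VoxelVolume

__all__ = [
    "BinaryMask",
    "LabeledComponents",
    "RegionMask",
    "otsu_threshold",
    "binarize",
    "morphological_closing",
    "despeckle",
    "despeckle_upper",
    "volume_to_voxels",
    "voxels_to_volume",
    "label_components",
    "fit_cortical_roi",
    "fill_marrow",
    "align_to_axis",
]

_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass
class BinaryMask:
    """A segmented phase: 3D boolean grid plus voxel size and a phase label."""

    data: np.ndarray
    voxel_size_um: float
    phase_name: str = "bone"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not (self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3


@dataclass
class RegionMask(BinaryMask):
    """A :class:`BinaryMask` designating an analysis region (VOI/ROI)."""

    role: str = "roi"


@dataclass
class LabeledComponents:
    """Connected components of a mask with per-component voxel counts."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: label, voxels, volume_um3
    voxel_size_um: float


def otsu_threshold(vol: VoxelVolume, roi: RegionMask | None = None) -> float:
    """Otsu's threshold over a 256-bin histogram of the (ROI-restricted) volume.

    Maximises the between-class variance of the global 3D histogram; a
    per-slice variant would break volume-level metrics.  Raises on a
    constant image.
    """
    vals = vol.data[roi.data] if roi is not None else vol.data.ravel()
    vals = np.sort(np.asarray(vals, dtype=np.float64))
    if vals.size == 0:
        raise ValueError("empty ROI")
    vmin, vmax = float(vals[0]), float(vals[-1])
    if vmin == vmax:
        raise ValueError("constant image: Otsu threshold undefined")
    edges = np.histogram_bin_edges(vals, bins=256, range=(vmin, vmax))
    cuts = edges[1:-1]                     # the 255 candidate thresholds
    prefix = np.concatenate([[0.0], np.cumsum(vals)])
    w0 = np.searchsorted(vals, cuts, side="left").astype(np.float64)
    w1 = vals.size - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = prefix[w0.astype(int)] / w0
        mu1 = (prefix[-1] - prefix[w0.astype(int)]) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv[~np.isfinite(bcv)] = -np.inf
    return float(cuts[int(np.argmax(bcv))])


def binarize(vol: VoxelVolume, threshold: float, polarity: str = "above") -> BinaryMask:
    """Global threshold: ``above`` keeps intensity >= t, ``below`` keeps < t."""
    if polarity == "above":
        data = vol.data >= threshold
        phase = "bone"
    elif polarity == "below":
        data = vol.data < threshold
        phase = "pore"
    else:
        raise ValueError(f"unknown polarity: {polarity!r}")
    return BinaryMask(data, vol.voxel_size_um, phase)


def _ball_offsets(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= radius**2


def _closing_edt(mask: np.ndarray, radius: float) -> np.ndarray:
    """Closing with a Euclidean ball via two distance transforms.

    The grid border is treated as a continuation of the structure (edge
    padding) so objects touching the window faces are not eroded.
    """
    pad = int(np.ceil(radius)) + 1
    m = np.pad(mask, pad, mode="edge")
    dil = ndi.distance_transform_edt(~m) <= radius
    closed = ndi.distance_transform_edt(dil) > radius
    sl = tuple(slice(pad, -pad) for _ in range(3))
    return closed[sl] | mask


def morphological_closing(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Dilation then erosion with a 3D ball of the given radius (voxels)."""
    if radius_voxels < 1:
        raise ValueError("radius must be >= 1")
    if radius_voxels <= 2:
        pad = radius_voxels + 1
        m = np.pad(mask.data, pad, mode="edge")
        closed = ndi.binary_closing(m, structure=_ball_offsets(radius_voxels))
        sl = tuple(slice(pad, -pad) for _ in range(3))
        out = closed[sl] | mask.data
    else:
        out = _closing_edt(mask.data, float(radius_voxels))
    return BinaryMask(out, mask.voxel_size_um, mask.phase_name)


def volume_to_voxels(volume_um3: float, voxel_size_um: float) -> int:
    """Physical volume expressed in voxels: 280 μm³ is 35 voxels at 2 μm."""
    if not (volume_um3 > 0 and voxel_size_um > 0):
        raise ValueError("arguments must be positive")
    return int(round(volume_um3 / voxel_size_um**3))


def voxels_to_volume(n_voxels: int, voxel_size_um: float) -> float:
    """Inverse of :func:`volume_to_voxels` (exact, no rounding)."""
    if not (n_voxels > 0 and voxel_size_um > 0):
        raise ValueError("arguments must be positive")
    return float(n_voxels) * voxel_size_um**3


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabeledComponents:
    """Label maximal connected foreground sets and tabulate their volumes."""
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, n = ndi.label(mask.data, structure=_STRUCTS[connectivity])
    counts = np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int)
    table = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "voxels": counts.astype(int),
            "volume_um3": counts * mask.voxel_volume_um3,
        }
    )
    return LabeledComponents(labels, table, mask.voxel_size_um)


def _remove_small(mask: np.ndarray, min_voxels_strict: float, structure: np.ndarray) -> np.ndarray:
    """Drop connected components whose voxel count is < min_voxels_strict."""
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels_strict
    keep[0] = False
    return keep[labels]


def despeckle(mask: BinaryMask, min_volume_um3: float, phase: str = "white") -> BinaryMask:
    """Remove ("despeckle") small components of one phase.

    ``white`` removes foreground components with volume < ``min_volume_um3``
    (26-connectivity); ``black`` flips small background holes to foreground
    (6-connectivity).  The comparison is strict: a component survives iff
    its volume >= the threshold, mirroring removal of speckles "less than"
    the stated volume.
    """
    if min_volume_um3 < 0:
        raise ValueError("min_volume_um3 must be >= 0")
    min_vox = min_volume_um3 / mask.voxel_volume_um3
    if phase == "white":
        out = _remove_small(mask.data, min_vox, _STRUCTS[26])
    elif phase == "black":
        holes = _remove_small(~mask.data, min_vox, _STRUCTS[6])
        out = ~holes
    else:
        raise ValueError(f"unknown phase: {phase!r}")
    return BinaryMask(out, mask.voxel_size_um, mask.phase_name)


def despeckle_upper(mask: BinaryMask, max_volume_um3: float) -> BinaryMask:
    """Remove foreground components with volume >= ``max_volume_um3``.

    The upper bound is the lower edge of the vascular-canal volume class,
    so removal at 4000 μm³ leaves exactly the lacunar class [280, 4000).
    """
    if not (max_volume_um3 > 0):
        raise ValueError("max_volume_um3 must be positive")
    max_vox = max_volume_um3 / mask.voxel_volume_um3
    labels, n = ndi.label(mask.data, structure=_STRUCTS[26])
    if n == 0:
        return BinaryMask(mask.data.copy(), mask.voxel_size_um, mask.phase_name)
    counts = np.bincount(labels.ravel())
    keep = counts < max_vox
    keep[0] = False
    return BinaryMask(keep[labels], mask.voxel_size_um, mask.phase_name)


_STRUCT2D_4 = ndi.generate_binary_structure(2, 1)


def _slice_fill(closed_slice: np.ndarray, fill_marrow_too: bool) -> np.ndarray:
    """Fill enclosed background regions of one cross-section.

    The largest enclosed region is taken to be the marrow cavity and is
    left open unless ``fill_marrow_too``; every smaller enclosed region
    (an intracortical pore cross-section) is filled.
    """
    bg = ~closed_slice
    labels, n = ndi.label(bg, structure=_STRUCT2D_4)
    if n == 0:
        return closed_slice
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    exterior = np.unique(labels[border & bg])
    counts = np.bincount(labels.ravel())
    enclosed = np.ones(n + 1, dtype=bool)
    enclosed[0] = False
    enclosed[exterior] = False
    idx = np.nonzero(enclosed)[0]
    if idx.size and not fill_marrow_too:
        marrow = idx[np.argmax(counts[idx])]
        enclosed[marrow] = False
    return closed_slice | enclosed[labels]


def fit_cortical_roi(bone: BinaryMask, closing_radius_um: float = 10.0) -> RegionMask:
    """Automatic cortical ROI: the solid annulus around the cortex.

    Takes the largest bone component, closes it with a Euclidean ball
    (default 10 μm — wide enough to bridge lacunae, far smaller than the
    marrow cavity), then fills, slice by slice, every enclosed void except
    the marrow.  The result hugs the cortex and contains no intracortical
    porosity, so ROI minus bone is exactly the pore set.
    """
    if not bone.data.any():
        raise ValueError("empty bone mask")
    labels, n = ndi.label(bone.data, structure=_STRUCTS[26])
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    main = labels == np.argmax(counts)

    r_vox = closing_radius_um / bone.voxel_size_um
    closed = _closing_edt(main, r_vox) if r_vox > 0 else main

    roi = np.empty_like(closed)
    for k in range(closed.shape[0]):
        roi[k] = _slice_fill(closed[k], fill_marrow_too=False)

    mid = roi.shape[0] // 2
    marrow_open = (~roi[mid]) & ndi.binary_fill_holes(roi[mid])
    if not marrow_open.any():
        raise ValueError("no annular topology: mid-slice has no enclosed marrow cavity")
    return RegionMask(roi, bone.voxel_size_um, phase_name="roi", role="cortical_roi")


def fill_marrow(roi: RegionMask) -> RegionMask:
    """Fill the marrow cavity slice by slice, yielding solid shaft sections."""
    out = np.empty_like(roi.data)
    for k in range(roi.data.shape[0]):
        if not roi.data[k].any():
            raise ValueError(f"slice {k} has no closed contour")
        out[k] = ndi.binary_fill_holes(roi.data[k])
    return RegionMask(out, roi.voxel_size_um, phase_name="roi", role="filled_shaft")


def align_to_axis(vol: VoxelVolume, threshold: float | None = None) -> VoxelVolume:
    """Rotate the volume so the object's principal axis lies along axis 0.

    Optional helper for stacks not already oriented along the bone long
    axis.  Nearest-neighbour resampling about the volume centre; raises for
    a near-spherical (degenerate) object.
    """
    if threshold is None:
        threshold = otsu_threshold(vol)
    fg = vol.data >= threshold
    if not fg.any():
        raise ValueError("nothing above threshold")
    pts = np.argwhere(fg).astype(np.float64)
    pts -= pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] < 1.1 * evals[1]:
        raise ValueError("degenerate (near-isotropic) object: principal axis undefined")
    axis = evecs[:, 2]
    if axis[0] < 0:
        axis = -axis
    # rotation taking `axis` to e0 (Rodrigues)
    e0 = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, e0)
    c = float(axis @ e0)
    if np.linalg.norm(v) < 1e-12:
        return vol.copy()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    center = (np.array(vol.data.shape) - 1) / 2.0
    offset = center - rot.T @ center
    data = ndi.affine_transform(vol.data, rot.T, offset=offset, order=0,
                                mode="constant", cval=vol.data.min())
    return VoxelVolume(data, vol.voxel_size_um, vol.provenance)
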