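"""Model-independent 3D thickness and macrostructural bone indices.

Local thickness follows the maximal-sphere definition: the thickness at a
voxel is the diameter of the largest sphere that fits entirely inside the
structure and contains that voxel.  It is computed from the Euclidean
distance transform by an opening ladder — for each candidate radius r, the
morphological opening with a ball of radius r (erosion by EDT threshold,
dilation by a second EDT) marks every voxel reachable by a fitting sphere
of that radius.  Candidate radii form a uniform ladder up to the EDT
maximum (half-voxel steps when the budget allows), which bounds the
number of passes without ever biasing the estimate upward: sparser
candidates can only under-report, never invent a larger sphere.

The grid border is treated as a continuation of the structure (no padding),
matching the physical situation of a scan window cut from a longer bone.

Indices:

* BV/TV   — bone volume fraction (%) inside a region of interest,
* Tb.Th   — volume-weighted mean local thickness of the bone phase (μm),
* Tb.Sp   — same on the background phase inside the ROI (μm),
* Tb.N    — (BV/TV)/Tb.Th, reported per mm (plate-model-free convention),
* Ct.Th   — volume-weighted mean thickness of the solid cortical ROI (μm),
* Ct.OD   — cortical outer diameter from per-slice area A and perimeter P:
  the printed plate-model form 2/(P/A) = 2A/P, or the diameter-consistent
  4A/P for a circular section (``cylinder_corrected``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .segment import BinaryMask, RegionMask

__all__ = [
    "ThicknessMap",
    "TrabecularMetrics",
    "CorticalMetrics",
    "local_thickness",
    "mean_thickness",
    "thickness_histogram",
    "bvtv",
    "trabecular_metrics",
    "ct_thickness",
    "ct_outer_diameter",
]


@dataclass
class ThicknessMap:
    """Local thickness (μm) on foreground voxels; NaN elsewhere."""

    data: np.ndarray
    voxel_size_um: float

    @property
    def foreground(self) -> np.ndarray:
        return np.isfinite(self.data)


def _thickness_voxels(fg: np.ndarray, max_candidates: int, exact: bool) -> np.ndarray:
    edt = ndi.distance_transform_edt(fg)
    if edt.size > 2**24:  # keep working set small on large grids
        edt = edt.astype(np.float32)
    if exact:
        cand = np.unique(edt[fg])
    else:
        # half-voxel steps just below the maximum (where shell- and
        # plate-like structures concentrate their voxels), coarser below
        emax = float(edt.max())
        n_fine = max_candidates // 2
        fine = emax - 0.5 * np.arange(n_fine)
        fine = fine[fine > 1.0]
        lo = fine.min() if fine.size else emax
        n_coarse = max(2, max_candidates - fine.size)
        coarse = np.linspace(1.0, lo, n_coarse, endpoint=False)
        cand = np.unique(np.concatenate([coarse, fine]))
    th = np.where(fg, 2.0 * edt.astype(edt.dtype) - 1.0, np.nan).astype(edt.dtype)
    uncovered = fg.copy()
    for rho in cand[::-1]:  # descending: the first covering sphere is the largest
        if rho <= 1.0 or not uncovered.any():
            break
        centers = edt >= rho - 1e-9
        if not centers.any():
            continue
        dist = ndi.distance_transform_edt(~centers)
        cover = fg & (dist <= rho + 1e-9)
        del dist
        new = cover & uncovered
        th[new] = np.maximum(th[new], edt.dtype.type(2.0 * rho - 1.0))
        uncovered &= ~cover
    return th


def local_thickness(mask: BinaryMask, max_candidates: int = 32,
                    exact: bool | None = None,
                    boundary: str = "continue") -> ThicknessMap:
    """Maximal-sphere local thickness of the mask foreground.

    Discrete definition: the sphere centred on a foreground voxel c has
    radius EDT(c) (it reaches, but does not include, the nearest
    background voxel) and contains every voxel p with |p - c| <= EDT(c).
    Its diameter in voxels across is 2·EDT(c) − 1, and the thickness at p
    is the largest such diameter over spheres containing p.  This
    calibration returns t for a t-voxel slab and d for a d-voxel sphere.

    ``exact=True`` uses every distinct EDT radius as a candidate (exact for
    the discrete definition; intended for small grids).  By default small
    grids (<= 32³ voxels) are computed exactly and larger ones with at
    most ``max_candidates`` opening passes.

    ``boundary`` states what lies beyond the grid faces: ``continue``
    (default — the structure carries on, as for a scan window cut from a
    longer bone) or ``background`` (the structure ends at the faces;
    exact for lattice phantoms whose structure faces coincide with the
    domain faces).  A 3-tuple gives one mode per axis, e.g.
    ``("background", "continue", "continue")`` for plates normal to the
    scan axis.
    """
    fg = mask.data
    if not fg.any():
        raise ValueError("empty mask")
    modes = (boundary,) * 3 if isinstance(boundary, str) else tuple(boundary)
    if len(modes) != 3 or any(m not in ("continue", "background") for m in modes):
        raise ValueError(f"unknown boundary mode: {boundary!r}")
    pads = [1 if m == "background" else 0 for m in modes]
    if any(pads):
        work = np.pad(fg, [(p, p) for p in pads])
        crop = tuple(slice(p, p + s) for p, s in zip(pads, fg.shape))
    else:
        work, crop = fg, None
    if exact is None:
        exact = work.size <= 32**3
    th = _thickness_voxels(work, max_candidates, exact)
    if crop is not None:
        th = th[crop]
    return ThicknessMap(th * mask.voxel_size_um, mask.voxel_size_um)


def mean_thickness(tmap: ThicknessMap) -> float:
    """Volume-weighted mean: every foreground voxel contributes its value."""
    return float(np.nanmean(tmap.data))


def thickness_histogram(tmap: ThicknessMap, bin_width_um: float | None = None):
    """Histogram of the thickness distribution, binned at one voxel by default.

    Returns ``(bin_centers_um, fraction)`` with fractions summing to 1.
    """
    vals = tmap.data[tmap.foreground]
    if bin_width_um is None:
        bin_width_um = tmap.voxel_size_um
    top = float(vals.max()) + bin_width_um
    edges = np.arange(0.0, top + bin_width_um, bin_width_um)
    hist, edges = np.histogram(vals, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, hist / hist.sum()


@dataclass
class TrabecularMetrics:
    bvtv_pct: float
    tb_th_um: float
    tb_sp_um: float
    tb_n_per_mm: float
    thickness_histogram: tuple = field(repr=False, default=())


@dataclass
class CorticalMetrics:
    ct_th_um: float
    ct_od_um: float
    ct_tv_mm3: float


def bvtv(bone: BinaryMask, roi: RegionMask) -> float:
    """Bone volume fraction in the ROI, in percent."""
    n_roi = int(np.count_nonzero(roi.data))
    if n_roi == 0:
        raise ValueError("empty ROI")
    n_bone = int(np.count_nonzero(bone.data & roi.data))
    return 100.0 * n_bone / n_roi


def trabecular_metrics(bone: BinaryMask, roi: RegionMask,
                       max_candidates: int = 32,
                       boundary: str = "continue") -> TrabecularMetrics:
    """BV/TV, Tb.Th, Tb.Sp, Tb.N and the thickness distribution in one pass.

    ``boundary`` is forwarded to :func:`local_thickness`; use
    ``background`` for lattice phantoms spanning whole periods.
    """
    bone_in = bone.data & roi.data
    sep_in = roi.data & ~bone.data
    if not bone_in.any():
        raise ValueError("no bone phase inside the ROI")
    if not sep_in.any():
        raise ValueError("ROI is all bone: separation undefined")
    bvtv_pct = bvtv(bone, roi)
    th_map = local_thickness(BinaryMask(bone_in, bone.voxel_size_um, "bone"),
                             max_candidates=max_candidates, boundary=boundary)
    sp_map = local_thickness(BinaryMask(sep_in, bone.voxel_size_um, "sep"),
                             max_candidates=max_candidates, boundary=boundary)
    tb_th = mean_thickness(th_map)
    tb_sp = mean_thickness(sp_map)
    tb_n = (bvtv_pct / 100.0) / tb_th * 1000.0  # per mm
    return TrabecularMetrics(bvtv_pct, tb_th, tb_sp, tb_n,
                             thickness_histogram(th_map))


def ct_thickness(roi: RegionMask, max_candidates: int = 32) -> float:
    """Volume-weighted mean thickness of the solid cortical ROI (μm).

    Because the ROI hugs the cortex and carries no pore voids, this is the
    cortical wall thickness unaffected by intracortical porosity.
    """
    if not roi.data.any():
        raise ValueError("empty ROI")
    tmap = local_thickness(BinaryMask(roi.data, roi.voxel_size_um, "roi"),
                           max_candidates=max_candidates)
    return mean_thickness(tmap)


def ct_outer_diameter(filled: RegionMask, variant: str = "as_printed") -> float:
    """Cortical outer diameter from 2D sections of the filled shaft (μm).

    ``as_printed`` evaluates the plate-model expression 2/(P/A) = 2A/P; for
    a circular section this equals the radius, so ``cylinder_corrected``
    (4A/P, the section's hydraulic diameter) is also exposed.  The
    perimeter is estimated with the 4-direction Crofton formula, which is
    multigrid-convergent (voxel-edge counting would overestimate by up to
    4/π).  The mean over slices is returned.
    """
    if variant not in ("as_printed", "cylinder_corrected"):
        raise ValueError(f"unknown variant: {variant!r}")
    factor = 2.0 if variant == "as_printed" else 4.0
    vals = []
    for k in range(filled.data.shape[0]):
        sl = filled.data[k]
        area = np.count_nonzero(sl)
        if area == 0:
            raise ValueError(f"empty slice {k} in filled shaft mask")
        perim = measure.perimeter_crofton(sl, directions=4)
        vals.append(factor * area / perim)
    return float(np.mean(vals)) * filled.voxel_size_um
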