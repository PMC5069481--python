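"""Intracortical porosity: extraction, volume-class segmentation, metrics.

Pores are the voids inside the solid cortical ROI.  After removal of
speckles below a lower despeckling volume (default 280 μm³), connected
pore components are split by volume into two classes:

* osteocyte lacunae — components with 280 μm³ <= V < 4000 μm³,
* vascular canals  — components with V >= 4000 μm³.

The class boundaries are half-open so the classes partition the components
exactly.  Per class the pipeline reports porosity (class volume / Ct.TV,
%), density (count / Ct.TV, #/mm³) and diameter (volume-weighted mean
local thickness of the member components, μm).  Ct.TV is the volume of the
solid cortical ROI, pores included, so densities are per mm³ of cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volio import VoxelVolume
from .segment import (BinaryMask, RegionMask, binarize, despeckle,
                      fit_cortical_roi, fill_marrow, otsu_threshold)
from .morpho import CorticalMetrics, ct_outer_diameter, ct_thickness, _thickness_voxels

__all__ = [
    "PoreTable",
    "PoreClassMetrics",
    "SensitivityTable",
    "CorticalConfig",
    "CorticalResult",
    "extract_pores",
    "classify_pores",
    "pore_class_metrics",
    "despeckle_sensitivity",
    "run_cortical_pipeline",
    "viable_osteocyte_density",
]

_STRUCT26 = ndi.generate_binary_structure(3, 3)

DEFAULT_LOWER_UM3 = 280.0
DEFAULT_UPPER_UM3 = 4000.0
SENSITIVITY_VOLUMES_UM3 = (150.0, 220.0, 250.0, 280.0, 310.0, 340.0, 450.0, 550.0)


@dataclass
class PoreTable:
    """Per-pore records after classification.

    ``table`` columns: id, voxels, volume_um3, pore_class (removed | lacuna
    | canal), mean_diameter_um (local-thickness based; NaN for removed),
    esd_um (equivalent-sphere diameter, stored for comparison),
    touches_border.
    """

    table: pd.DataFrame
    voxel_size_um: float
    lower_um3: float
    upper_um3: float
    labels: np.ndarray | None = field(default=None, repr=False)

    def members(self, pore_class: str) -> pd.DataFrame:
        return self.table[self.table.pore_class == pore_class]

    def class_volume_um3(self, pore_class: str) -> float:
        return float(self.members(pore_class).volume_um3.sum())

    def class_count(self, pore_class: str) -> int:
        return int(len(self.members(pore_class)))

    @property
    def total_pore_volume_um3(self) -> float:
        return float(self.table.volume_um3.sum())


@dataclass
class PoreClassMetrics:
    porosity_pct: float
    density_per_mm3: float
    diameter_um: float  # NaN when the class is empty
    count: int
    class_volume_um3: float


@dataclass
class SensitivityTable:
    """Lacunar metrics as a function of the lower despeckling volume."""

    table: pd.DataFrame  # despeckle_volume_um3, lacuna_count, lacunar_volume_um3,
    #                      lacunar_porosity_pct, lacunar_diameter_um


def extract_pores(roi: RegionMask, bone: BinaryMask) -> BinaryMask:
    """Pore mask = ROI minus bone (always a subset of the ROI)."""
    if not roi.data.any():
        raise ValueError("empty ROI")
    return BinaryMask(roi.data & ~bone.data, roi.voxel_size_um, "pore")


def _component_diameter(crop_fg: np.ndarray, voxel: float) -> float:
    """Volume-weighted mean local thickness of one component (μm)."""
    pad = np.pad(crop_fg, 1)  # pores are bounded structures: pad background
    th = _thickness_voxels(pad, max_candidates=16, exact=pad.size <= 32**3)
    return float(np.nanmean(th[pad])) * voxel


def classify_pores(pores: BinaryMask,
                   lower_um3: float = DEFAULT_LOWER_UM3,
                   upper_um3: float = DEFAULT_UPPER_UM3,
                   compute_diameters: bool = True,
                   exclude_border: bool = False) -> PoreTable:
    """Label pore components (26-connectivity) and classify by volume.

    V < lower → removed; lower <= V < upper → lacuna; V >= upper → canal.
    At a 2 μm voxel the default lower bound operates at 35 voxels, at 1 μm
    at 280 voxels.  With ``exclude_border`` components touching the volume
    faces are set to class ``removed`` (kept by default).
    """
    if not (0 <= lower_um3 < upper_um3):
        raise ValueError("need 0 <= lower < upper")
    vox3 = pores.voxel_size_um ** 3
    labels, n = ndi.label(pores.data, structure=_STRUCT26)
    counts = (np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int))
    volumes = counts * vox3

    border = np.zeros(n + 1, dtype=bool)
    if n:
        for face in (labels[0], labels[-1], labels[:, 0], labels[:, -1],
                     labels[:, :, 0], labels[:, :, -1]):
            border[np.unique(face)] = True

    cls = np.where(volumes < lower_um3, "removed",
                   np.where(volumes < upper_um3, "lacuna", "canal")).astype(object)
    if exclude_border:
        cls[border[1:]] = "removed"

    diam = np.full(n, np.nan)
    esd = (6.0 * volumes / np.pi) ** (1.0 / 3.0)
    if compute_diameters and n:
        objects = ndi.find_objects(labels)
        for i, sl in enumerate(objects):
            if cls[i] == "removed":
                continue
            crop = labels[sl] == (i + 1)
            diam[i] = _component_diameter(crop, pores.voxel_size_um)

    table = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "voxels": counts.astype(int),
        "volume_um3": volumes,
        "pore_class": cls,
        "mean_diameter_um": diam,
        "esd_um": esd,
        "touches_border": border[1:],
    })
    return PoreTable(table, pores.voxel_size_um, lower_um3, upper_um3, labels)


def pore_class_metrics(table: PoreTable, which: str, ct_tv_mm3: float) -> PoreClassMetrics:
    """Porosity, density and diameter of one pore class.

    Porosity = 100 × class volume / Ct.TV; density = class count / Ct.TV.
    The diameter is the volume-weighted mean of member diameters and is NaN
    for an empty class.
    """
    if which not in ("canal", "lacuna"):
        raise ValueError("which must be 'canal' or 'lacuna'")
    if not (ct_tv_mm3 > 0):
        raise ValueError("Ct.TV must be positive")
    members = table.members(which)
    vol_um3 = float(members.volume_um3.sum())
    count = len(members)
    porosity = 100.0 * vol_um3 / (ct_tv_mm3 * 1e9)
    density = count / ct_tv_mm3
    if count and members.mean_diameter_um.notna().any():
        w = members.volume_um3.to_numpy()
        d = members.mean_diameter_um.to_numpy()
        diameter = float(np.nansum(w * d) / w[~np.isnan(d)].sum())
    else:
        diameter = float("nan")
    return PoreClassMetrics(porosity, density, diameter, count, vol_um3)


def despeckle_sensitivity(pores: BinaryMask,
                          volumes_um3=SENSITIVITY_VOLUMES_UM3,
                          upper_um3: float = DEFAULT_UPPER_UM3,
                          ct_tv_mm3: float | None = None) -> SensitivityTable:
    """Lacunar metrics across a sweep of lower despeckling volumes.

    Components are labelled once; each row reclassifies them with a
    different lower bound and a fixed upper bound, so the lacuna count and
    porosity are non-increasing down the sweep while canal metrics are
    untouched.  Porosity is NaN when no Ct.TV denominator is given.
    """
    volumes = list(volumes_um3)
    if volumes != sorted(volumes):
        raise ValueError("despeckle volumes must be sorted ascending")
    base = classify_pores(pores, lower_um3=min(volumes), upper_um3=upper_um3)
    t = base.table
    rows = []
    for v in volumes:
        lac = t[(t.volume_um3 >= v) & (t.volume_um3 < upper_um3)]
        vol = float(lac.volume_um3.sum())
        if len(lac) and lac.mean_diameter_um.notna().any():
            w = lac.volume_um3.to_numpy()
            d = lac.mean_diameter_um.to_numpy()
            diam = float(np.nansum(w * d) / w[~np.isnan(d)].sum())
        else:
            diam = float("nan")
        rows.append({
            "despeckle_volume_um3": v,
            "lacuna_count": int(len(lac)),
            "lacunar_volume_um3": vol,
            "lacunar_porosity_pct": (100.0 * vol / (ct_tv_mm3 * 1e9)
                                     if ct_tv_mm3 else float("nan")),
            "lacunar_diameter_um": diam,
        })
    return SensitivityTable(pd.DataFrame(rows))


@dataclass
class CorticalConfig:
    """Parameters of the cortical pipeline.

    ``pore_threshold`` None selects Otsu (adequate for phantoms; real
    scans were thresholded by a manually chosen global value, so supply
    one for real data).
    """

    pore_threshold: float | None = None
    lower_um3: float = DEFAULT_LOWER_UM3
    upper_um3: float = DEFAULT_UPPER_UM3
    roi_closing_radius_um: float = 10.0
    ct_od_variant: str = "as_printed"
    compute_thickness: bool = True
    compute_diameters: bool = True
    exclude_border: bool = False
    max_candidates: int = 32


@dataclass
class CorticalResult:
    cortical: CorticalMetrics
    canal: PoreClassMetrics
    lacunar: PoreClassMetrics
    pore_table: PoreTable
    threshold: float
    roi: RegionMask = field(repr=False, default=None)
    bone: BinaryMask = field(repr=False, default=None)

    def row(self) -> dict:
        """Flat record with the conventional symbol names."""
        return {
            "Ct_Th_um": self.cortical.ct_th_um,
            "Ct_OD_um": self.cortical.ct_od_um,
            "Ct_TV_mm3": self.cortical.ct_tv_mm3,
            "Ca_V_Ct_TV_pct": self.canal.porosity_pct,
            "N_Ca_Ct_TV_per_mm3": self.canal.density_per_mm3,
            "Ca_D_um": self.canal.diameter_um,
            "Lc_V_Ct_TV_pct": self.lacunar.porosity_pct,
            "N_Lc_Ct_TV_per_mm3": self.lacunar.density_per_mm3,
            "Lc_D_um": self.lacunar.diameter_um,
            "threshold": self.threshold,
        }


def run_cortical_pipeline(vol: VoxelVolume,
                          config: CorticalConfig | None = None) -> CorticalResult:
    """The full cortical chain, deterministic given the volume and config.

    Threshold → bone mask → automatic cortical ROI → pore extraction →
    volume-class segmentation → per-class metrics, plus Ct.Th (thickness
    of the solid ROI), Ct.OD (on the marrow-filled sections) and Ct.TV.
    """
    config = config or CorticalConfig()
    threshold = (config.pore_threshold if config.pore_threshold is not None
                 else otsu_threshold(vol))
    bone = binarize(vol, threshold, "above")
    roi = fit_cortical_roi(bone, config.roi_closing_radius_um)
    pores = extract_pores(roi, bone)
    table = classify_pores(pores, config.lower_um3, config.upper_um3,
                           compute_diameters=config.compute_diameters,
                           exclude_border=config.exclude_border)
    ct_tv_mm3 = np.count_nonzero(roi.data) * (roi.voxel_size_um ** 3) / 1e9
    canal = pore_class_metrics(table, "canal", ct_tv_mm3)
    lacunar = pore_class_metrics(table, "lacuna", ct_tv_mm3)
    if config.compute_thickness:
        ct_th = ct_thickness(roi, max_candidates=config.max_candidates)
    else:
        ct_th = float("nan")
    ct_od = ct_outer_diameter(fill_marrow(roi), config.ct_od_variant)
    cortical = CorticalMetrics(ct_th, ct_od, ct_tv_mm3)
    return CorticalResult(cortical, canal, lacunar, table, threshold, roi, bone)


def viable_osteocyte_density(lacunar_density_per_mm3: float,
                             tunel_pos_fraction: float) -> float:
    """Viable-osteocyte density: lacunar density × TUNEL-negative fraction.

    Combines the microCT lacunar density (#/mm³) with the histological
    apoptosis stain: lacunae hosting TUNEL-positive (apoptotic) osteocytes
    are discounted.
    """
    if not (0.0 <= tunel_pos_fraction <= 1.0):
        raise ValueError("tunel_pos_fraction must be in [0, 1]")
    if lacunar_density_per_mm3 < 0:
        raise ValueError("density must be >= 0")
    return lacunar_density_per_mm3 * (1.0 - tunel_pos_fraction)
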