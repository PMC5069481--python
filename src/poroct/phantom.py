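"""Synthetic bone phantoms with analytic ground truth, and a scan simulator.

Two families are generated:

* a cortical shaft — a hollow tube whose wall carries quasi-longitudinal
  cylindrical voids (vascular canals, diameters of order 5–30 μm) and
  dispersed ellipsoidal voids (osteocyte lacunae, volumes of order
  100–4000 μm³);
* trabecular lattices of plates or rods with known thickness and spacing.

Rendering is anti-aliased: each voxel's gray level is set from the signed
distance of its centre to the nearest structure surface, clipped to a
one-voxel ramp, so boundary voxels carry partial-volume gray levels just
as a real reconstruction does.  Thresholding at the mid gray level then
reduces to centre-inclusion digitisation, which is unbiased for smooth
convex structures.  Every structure's analytic volume and diameter is
recorded in a :class:`PhantomTruth` for recovery testing.  Lacunae are
rejection-sampled so they touch neither the canals nor each other nor the
wall surfaces, keeping component counts exact.

:func:`simulate_scan` emulates acquisition at a coarser voxel size:
Gaussian detector blur of stated FWHM, block-average downsampling by an
integer factor, then additive Gaussian noise.  This reproduces the partial
volume effect by which thin canals lose contrast and fall out of the
segmented pore phase at coarser resolution.

Defaults are desk-scale (a ~0.3 mm field rather than a whole mouse tibia)
but preserve realistic structure sizes; they are order-of-magnitude
choices, since canal and lacuna size distributions are only known from
figures in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .volio import VoxelVolume

__all__ = [
    "CorticalPhantomSpec",
    "TrabecularPhantomSpec",
    "PhantomTruth",
    "ScanModel",
    "make_cortical_phantom",
    "make_trabecular_phantom",
    "simulate_scan",
]

BONE_INTENSITY = 200.0
BACKGROUND_INTENSITY = 20.0
_MAX_TRIES = 2000


@dataclass
class CorticalPhantomSpec:
    """Hollow-shaft phantom: wall with canals and lacunae.

    Sizes in μm; ``canal_diameter_um`` and ``lacuna_volume_um3`` are
    (mean, sd) of truncated normal draws.  ``lacuna_volume_range`` clips
    lacuna volumes (default keeps them safely inside the 280–4000 μm³
    lacunar volume class).
    """

    outer_diameter_um: float = 280.0
    wall_thickness_um: float = 80.0
    length_um: float = 200.0
    canal_count: int = 10
    canal_diameter_um: tuple[float, float] = (16.0, 3.0)
    canal_tilt_deg_max: float = 5.0
    lacuna_count: int = 150
    lacuna_volume_um3: tuple[float, float] = (700.0, 250.0)
    lacuna_volume_range: tuple[float, float] = (350.0, 3500.0)
    lacuna_aspect_ratios: tuple[float, float, float] = (1.0, 0.55, 0.4)
    render_voxel_um: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.wall_thickness_um < self.outer_diameter_um / 2):
            raise ValueError("need 0 < wall thickness < outer diameter / 2")
        if self.canal_count and not (self.canal_diameter_um[0] < self.wall_thickness_um):
            raise ValueError("mean canal diameter must be below the wall thickness")
        if self.canal_count < 0 or self.lacuna_count < 0:
            raise ValueError("counts must be >= 0")
        if not (self.render_voxel_um > 0 and self.length_um > 0):
            raise ValueError("positive dimensions required")


@dataclass
class TrabecularPhantomSpec:
    """Rod/plate lattice phantom with known thickness and spacing (μm)."""

    lattice_type: str = "plates"  # plates | rods | mixed
    element_thickness_um: float = 40.0
    element_spacing_um: float = 200.0
    domain_size_um: float = 600.0
    render_voxel_um: float = 2.0
    rng_seed: int = 0
    jitter_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.lattice_type not in ("plates", "rods", "mixed"):
            raise ValueError(f"unknown lattice type: {self.lattice_type!r}")
        if not (0 < self.element_thickness_um < self.element_spacing_um):
            raise ValueError("need 0 < thickness < spacing")
        if not (self.domain_size_um > 0 and self.render_voxel_um > 0):
            raise ValueError("positive dimensions required")
        if not (0 <= self.jitter_fraction < 0.5):
            raise ValueError("jitter_fraction must be in [0, 0.5)")


@dataclass
class PhantomTruth:
    """Analytic ground truth paired with a rendered phantom."""

    ct_th_um: float | None = None
    ct_od_um: float | None = None
    wall_volume_um3: float | None = None
    canal_count: int | None = None
    canal_volumes_um3: list[float] = field(default_factory=list)
    canal_diameters_um: list[float] = field(default_factory=list)
    canal_volume_fraction: float | None = None
    lacuna_count: int | None = None
    lacuna_volumes_um3: list[float] = field(default_factory=list)
    lacunar_volume_fraction: float | None = None
    bvtv_pct: float | None = None
    tb_th_um: float | None = None
    tb_sp_um: float | None = None
    tb_n_per_mm: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScanModel:
    """Acquisition model: blur FWHM, integer downsampling, additive noise.

    The PSF default is 2× the target voxel, a typical detector blur scale.
    """

    target_voxel_um: float
    psf_fwhm_um: float | None = None
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.target_voxel_um > 0):
            raise ValueError("target voxel must be positive")
        if self.psf_fwhm_um is None:
            self.psf_fwhm_um = 2.0 * self.target_voxel_um
        if self.psf_fwhm_um < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm and noise_sd must be >= 0")


def _block_mean(a: np.ndarray, f: int) -> np.ndarray:
    nz, ny, nx = (s // f for s in a.shape)
    a = a[: nz * f, : ny * f, : nx * f]
    return a.reshape(nz, f, ny, f, nx, f).mean(axis=(1, 3, 5), dtype=np.float64)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, n: int) -> np.ndarray:
    out = np.empty(n)
    for i in range(n):
        for _ in range(_MAX_TRIES):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                out[i] = v
                break
        else:
            out[i] = min(max(mean, lo), hi)
    return out


def _occ(signed_dist_um: np.ndarray, voxel_um: float) -> np.ndarray:
    """Occupancy from signed distance (positive inside): one-voxel ramp."""
    return np.clip(0.5 + signed_dist_um / voxel_um, 0.0, 1.0)


def make_cortical_phantom(spec: CorticalPhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Render the cortical phantom and its analytic truth.

    Bone is high intensity (200), pores and background low (20).  Raises
    ``RuntimeError`` if the requested structures cannot be placed without
    overlap within a bounded number of retries.
    """
    rng = np.random.default_rng(spec.rng_seed)
    vox = spec.render_voxel_um
    r_out = spec.outer_diameter_um / 2.0
    r_in = r_out - spec.wall_thickness_um
    margin_um = 4.0
    nxy = int(round((spec.outer_diameter_um + 2 * margin_um) / vox))
    nz = int(round(spec.length_um / vox))
    half = nxy * vox / 2.0

    coords = (np.arange(nxy) + 0.5) * vox - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rr = np.sqrt(yy**2 + xx**2)
    wall_occ2d = _occ(np.minimum(r_out - rr, rr - r_in), vox).astype(np.float32)
    zc = (np.arange(nz) + 0.5) * vox  # physical z of slice centres
    void_occ = np.zeros((nz, nxy, nxy), dtype=np.float32)

    truth = PhantomTruth(
        ct_th_um=spec.wall_thickness_um,
        ct_od_um=spec.outer_diameter_um,
        wall_volume_um3=math.pi * (r_out**2 - r_in**2) * spec.length_um,
        canal_count=spec.canal_count,
        lacuna_count=spec.lacuna_count,
    )

    # ---- canals: cylinders nearly parallel to the shaft axis ----
    clearance = 2.0
    canals = []  # (p0 (3,), u (3,), radius)
    radii = _truncnorm(rng, spec.canal_diameter_um[0] / 2, spec.canal_diameter_um[1] / 2,
                       1.5, spec.wall_thickness_um / 2 - clearance, spec.canal_count)
    zmid = spec.length_um / 2.0
    for rc in radii:
        if r_in + rc + clearance >= r_out - rc - clearance:
            raise RuntimeError("infeasible packing: canal does not fit in the wall")
        for _ in range(_MAX_TRIES):
            theta = rng.uniform(0, 2 * math.pi)
            rho = rng.uniform(r_in + rc + clearance, r_out - rc - clearance)
            tilt = math.radians(rng.uniform(0, spec.canal_tilt_deg_max))
            phi = rng.uniform(0, 2 * math.pi)
            u = np.array([math.cos(tilt),
                          math.sin(tilt) * math.cos(phi),
                          math.sin(tilt) * math.sin(phi)])
            p0 = np.array([zmid, rho * math.cos(theta), rho * math.sin(theta)])
            ok = True
            for z_end in (0.0, spec.length_um):  # stay in the wall at both ends
                xy = p0[1:] + (z_end - zmid) / u[0] * u[1:]
                rad = math.hypot(*xy)
                if not (r_in + rc + clearance <= rad <= r_out - rc - clearance):
                    ok = False
                    break
            if ok:
                for q0, qu, qr in canals:
                    for z_chk in (0.0, zmid, spec.length_um):
                        a = p0[1:] + (z_chk - zmid) / u[0] * u[1:]
                        b = q0[1:] + (z_chk - zmid) / qu[0] * qu[1:]
                        if np.hypot(*(a - b)) <= rc + qr + clearance:
                            ok = False
                            break
                    if not ok:
                        break
            if ok:
                canals.append((p0, u, rc))
                break
        else:
            raise RuntimeError("infeasible packing: could not place all canals")

    for p0, u, rc in canals:
        rwin = rc / u[0] + 2 * vox
        for k in range(nz):
            xy = p0[1:] + (zc[k] - zmid) / u[0] * u[1:]
            j0 = max(0, int((xy[0] + half - rwin) / vox))
            j1 = min(nxy, int((xy[0] + half + rwin) / vox) + 1)
            i0 = max(0, int((xy[1] + half - rwin) / vox))
            i1 = min(nxy, int((xy[1] + half + rwin) / vox) + 1)
            py = yy[j0:j1, i0:i1]
            px = xx[j0:j1, i0:i1]
            dz = zc[k] - p0[0]
            dy = py - p0[1]
            dx = px - p0[2]
            proj = dz * u[0] + dy * u[1] + dx * u[2]
            dist = np.sqrt(np.maximum(dz**2 + dy**2 + dx**2 - proj**2, 0.0))
            occ = _occ(rc - dist, vox)
            np.maximum(void_occ[k, j0:j1, i0:i1], occ.astype(np.float32),
                       out=void_occ[k, j0:j1, i0:i1])
        truth.canal_volumes_um3.append(math.pi * rc**2 * spec.length_um / u[0])
        truth.canal_diameters_um.append(2.0 * rc)

    # ---- lacunae: ellipsoids, non-touching ----
    q1, q2, q3 = spec.lacuna_aspect_ratios
    vols = _truncnorm(rng, spec.lacuna_volume_um3[0], spec.lacuna_volume_um3[1],
                      spec.lacuna_volume_range[0], spec.lacuna_volume_range[1],
                      spec.lacuna_count)
    placed = []  # (center (3,), max semi-axis)
    for v in vols:
        t = (3.0 * v / (4.0 * math.pi * q1 * q2 * q3)) ** (1.0 / 3.0)
        semi = np.array([q1, q2, q3]) * t
        amax = float(semi.max())
        if (r_in + amax + clearance >= r_out - amax - clearance
                or amax + clearance >= spec.length_um - amax - clearance):
            raise RuntimeError(
                "infeasible packing: lacuna does not fit in the wall/length")
        for _ in range(_MAX_TRIES):
            theta = rng.uniform(0, 2 * math.pi)
            rho = rng.uniform(r_in + amax + clearance, r_out - amax - clearance)
            z = rng.uniform(amax + clearance, spec.length_um - amax - clearance)
            c = np.array([z, rho * math.cos(theta), rho * math.sin(theta)])
            ok = all(np.linalg.norm(c - pc) > amax + pa + clearance for pc, pa in placed)
            if ok:
                for p0, u, rc in canals:
                    d = c - p0
                    dist = np.linalg.norm(d - (d @ u) * u)
                    if dist <= rc + amax + clearance:
                        ok = False
                        break
            if ok:
                placed.append((c, amax))
                # orientation: long axis within 30 degrees of the shaft axis
                tilt = math.radians(rng.uniform(0, 30))
                phi = rng.uniform(0, 2 * math.pi)
                a1 = np.array([math.cos(tilt),
                               math.sin(tilt) * math.cos(phi),
                               math.sin(tilt) * math.sin(phi)])
                tmp = np.array([0.0, 1.0, 0.0])
                if abs(a1 @ tmp) > 0.9:
                    tmp = np.array([0.0, 0.0, 1.0])
                a2 = np.cross(a1, tmp)
                a2 /= np.linalg.norm(a2)
                a3 = np.cross(a1, a2)
                rot = np.stack([a1, a2, a3])  # rows: ellipsoid axes
                _carve_ellipsoid(void_occ, c, semi, rot, half, vox, zc)
                truth.lacuna_volumes_um3.append(float(v))
                break
        else:
            raise RuntimeError("infeasible packing: could not place all lacunae")

    truth.canal_volume_fraction = (
        sum(truth.canal_volumes_um3) / truth.wall_volume_um3)
    truth.lacunar_volume_fraction = (
        sum(truth.lacuna_volumes_um3) / truth.wall_volume_um3)

    span = BONE_INTENSITY - BACKGROUND_INTENSITY
    data = (BACKGROUND_INTENSITY
            + span * wall_occ2d[None, :, :] * (1.0 - void_occ)).astype(np.float32)
    vol = VoxelVolume(data, vox, provenance=f"cortical phantom seed={spec.rng_seed}")
    return vol, truth


def _carve_ellipsoid(void_occ, center, semi, rot, half, vox, zc):
    """Max-combine an ellipsoid's occupancy into the void field.

    The signed distance is approximated near the surface by the level-set
    value of the normalised quadratic form divided by its gradient norm.
    """
    amax = float(semi.max())
    k0 = max(0, int((center[0] - amax - vox) / vox) - 1)
    k1 = min(void_occ.shape[0], int((center[0] + amax + vox) / vox) + 2)
    j0 = max(0, int((center[1] + half - amax - vox) / vox) - 1)
    j1 = min(void_occ.shape[1], int((center[1] + half + amax + vox) / vox) + 2)
    i0 = max(0, int((center[2] + half - amax - vox) / vox) - 1)
    i1 = min(void_occ.shape[2], int((center[2] + half + amax + vox) / vox) + 2)
    zz = zc[k0:k1, None, None] - center[0]
    yy = ((np.arange(j0, j1) + 0.5) * vox - half - center[1])[None, :, None]
    xx = ((np.arange(i0, i1) + 0.5) * vox - half - center[2])[None, None, :]
    u = rot[0, 0] * zz + rot[0, 1] * yy + rot[0, 2] * xx
    v = rot[1, 0] * zz + rot[1, 1] * yy + rot[1, 2] * xx
    w = rot[2, 0] * zz + rot[2, 1] * yy + rot[2, 2] * xx
    q = np.sqrt((u / semi[0]) ** 2 + (v / semi[1]) ** 2 + (w / semi[2]) ** 2)
    grad = np.sqrt((u / semi[0] ** 2) ** 2 + (v / semi[1] ** 2) ** 2
                   + (w / semi[2] ** 2) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.where(grad > 0, (1.0 - q) * q / grad, amax)
    occ = _occ(sd, vox).astype(np.float32)
    block = void_occ[k0:k1, j0:j1, i0:i1]
    np.maximum(block, occ, out=block)


def make_trabecular_phantom(spec: TrabecularPhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Render a rod/plate lattice and its analytic truth.

    Plates are slabs normal to the scan axis; rods are three orthogonal
    families of cylinders on a cubic lattice.  The domain is periodic when
    it spans a whole number of periods.  With zero jitter the BV/TV truth
    is exact (inclusion–exclusion of the Steinmetz intersections for
    rods); jitter displaces elements and leaves the truth approximate.
    """
    rng = np.random.default_rng(spec.rng_seed)
    vox = spec.render_voxel_um
    n = int(round(spec.domain_size_um / vox))
    t = spec.element_thickness_um
    p = spec.element_spacing_um
    coords = (np.arange(n) + 0.5) * vox
    jit = spec.jitter_fraction * p
    n_l = int(np.ceil(spec.domain_size_um / p)) + 1

    def slab_occ(c):
        """Occupancy along one axis for slabs [i·p, i·p + t)."""
        occ = np.zeros(n, dtype=np.float32)
        for i in range(-1, n_l):
            lo = i * p + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
            sd = np.minimum(c - lo, lo + t - c)
            np.maximum(occ, _occ(sd, vox).astype(np.float32), out=occ)
        return occ

    def rod_occ_2d(c):
        """In-plane occupancy of rods (circles radius t/2) at cell centres."""
        r = t / 2.0
        m = np.zeros((n, n), dtype=np.float32)
        cy, cx = np.meshgrid(c, c, indexing="ij")
        for i in range(-1, n_l):
            for j in range(-1, n_l):
                y0 = i * p + p / 2 + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
                x0 = j * p + p / 2 + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
                sd = r - np.sqrt((cy - y0) ** 2 + (cx - x0) ** 2)
                np.maximum(m, _occ(sd, vox).astype(np.float32), out=m)
        return m

    occ = np.zeros((n, n, n), dtype=np.float32)
    if spec.lattice_type == "plates":
        occ = np.maximum(occ, slab_occ(coords)[:, None, None])
        f = t / p
        truth = PhantomTruth(bvtv_pct=100 * f, tb_th_um=t, tb_sp_um=p - t,
                             tb_n_per_mm=(f / t) * 1000.0)
    elif spec.lattice_type == "rods":
        occ = np.maximum(occ, rod_occ_2d(coords)[None, :, :])
        occ = np.maximum(occ, rod_occ_2d(coords)[:, None, :])
        occ = np.maximum(occ, rod_occ_2d(coords)[:, :, None])
        r = t / 2.0
        cell = (3 * math.pi * r**2 * p
                - 3 * (16.0 / 3.0) * r**3
                + 8 * (2 - math.sqrt(2)) * r**3)
        f = cell / p**3
        truth = PhantomTruth(bvtv_pct=100 * f, tb_th_um=t,
                             tb_sp_um=p - t, tb_n_per_mm=(f / t) * 1000.0)
    else:  # mixed: plates normal to the scan axis plus connecting rods along it
        occ = np.maximum(occ, slab_occ(coords)[:, None, None])
        occ = np.maximum(occ, rod_occ_2d(coords)[None, :, :])
        r = t / 2.0
        f = t / p + (math.pi * r**2 / p**2) * (1 - t / p)
        truth = PhantomTruth(bvtv_pct=100 * f, tb_th_um=t, tb_sp_um=p - t,
                             tb_n_per_mm=(f / t) * 1000.0)

    span = BONE_INTENSITY - BACKGROUND_INTENSITY
    data = (BACKGROUND_INTENSITY + span * occ).astype(np.float32)
    vol = VoxelVolume(data, vox,
                      provenance=f"trabecular phantom {spec.lattice_type} seed={spec.rng_seed}")
    return vol, truth


def simulate_scan(vol: VoxelVolume, model: ScanModel) -> VoxelVolume:
    """Acquire the volume at a coarser voxel: blur, block-average, noise.

    The downsampling factor must be an integer; with factor 1, zero FWHM
    and zero noise this is the identity.  Blur and block-averaging conserve
    the mean intensity (edge-replicated boundaries).
    """
    factor_f = model.target_voxel_um / vol.voxel_size_um
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target voxel ({model.target_voxel_um}) must be an integer multiple "
            f"of the source voxel ({vol.voxel_size_um})")
    data = np.asarray(vol.data, dtype=np.float32)
    sigma_vox = (model.psf_fwhm_um / 2.35482) / vol.voxel_size_um
    if sigma_vox > 0:
        data = ndi.gaussian_filter(data, sigma_vox, mode="nearest")
    if factor > 1:
        data = _block_mean(data, factor).astype(np.float32)
    else:
        data = data.copy()
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.rng_seed)
        data = data + rng.normal(0.0, model.noise_sd, data.shape).astype(np.float32)
    prov = f"{vol.provenance} | scanned at {model.target_voxel_um} um"
    return VoxelVolume(data.astype(np.float32), model.target_voxel_um, prov)
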