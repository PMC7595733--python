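"""Seeded synthetic phantoms with ground truth.

Two generators are provided:

* :func:`generate_em_volume` — a desk-scale stand-in for a serial block-face
  SEM sub-ROI: cylindrical myofibrils with controlled folded-normal
  transmural (θ) and elliptical (Φ) angle distributions, ellipsoidal nuclei,
  blob-like mitochondria, an extracellular phase of controlled volume
  fraction, per-class intensities with Gaussian noise, optional per-slice
  brightness offsets and translation jitter.  Ground-truth labels, per-fibril
  ids and the true (θ, Φ) table are returned alongside the grayscale stack.
* :func:`generate_heart_phantom` — a two-chamber whole-heart label volume at
  micro-CT scale with ellipsoidal LV/RV lumens of controlled volume ratio.

All randomness flows from a single integer seed; identical parameters and
seed give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import VolumeGeometry
from .volumes import (
    CLASS_EXTRACELLULAR,
    CLASS_MITOCHONDRION,
    CLASS_MYOFIBRIL,
    CLASS_NUCLEUS,
    CLASS_OTHER_CYTOPLASM,
    EM_CLASS_MAP,
    HEART_CLASS_MAP,
    HEART_LV_LUMEN,
    HEART_RV_LUMEN,
    HEART_TISSUE,
    LabelVolume,
    VoxelVolume,
)


class PackingError(RuntimeError):
    """Raised when an object class cannot be placed without overlap."""


DEFAULT_INTENSITY_MEANS = {
    CLASS_EXTRACELLULAR: 210.0,   # resin-filled space images bright
    CLASS_NUCLEUS: 60.0,          # heavily stained chromatin
    CLASS_MITOCHONDRION: 95.0,
    CLASS_MYOFIBRIL: 135.0,
    CLASS_OTHER_CYTOPLASM: 170.0,
}


@dataclass(frozen=True)
class EmPhantomParams:
    """Parameters of the EM-scale phantom.

    ``grid_shape`` is (nx, ny, nz) voxels; spacing is nm per axis.  Angle
    means/SDs parameterize folded normals on [0°, 180°) — fibrils are
    unoriented axes, so 175° and −5° denote the same direction.
    """

    seed: int
    grid_shape: tuple[int, int, int] = (400, 600, 100)
    spacing: tuple[float, float, float] = (10.0, 10.0, 40.0)
    n_myofibrils: int = 30
    fibril_radius: float = 60.0       # nm
    fibril_length: float = 1500.0     # nm
    theta_mean: float = 45.0
    theta_sd: float = 32.0
    phi_mean: float = 70.0
    phi_sd: float = 36.0
    n_nuclei: int = 2
    nucleus_semiaxes: tuple[float, float, float] = (800.0, 500.0, 500.0)  # nm
    n_mitochondria: int = 40
    mito_semiaxes: tuple[float, float, float] = (220.0, 160.0, 160.0)     # nm
    ec_fraction_target: float = 0.20
    intensity_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS))
    noise_sd: float = 8.0
    slice_brightness_sd: float = 0.0
    slice_jitter_sd: float = 0.0      # voxels
    max_retries: int = 100

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not (0.0 <= self.ec_fraction_target < 1.0):
            raise ValueError("ec_fraction_target must lie in [0, 1)")
        if self.fibril_radius < min(self.spacing[0], self.spacing[1]):
            raise ValueError("fibril_radius must be at least one lateral voxel")
        means = list(self.intensity_means.values())
        if len(set(means)) != len(means):
            raise ValueError("class intensity means must be pairwise distinct")
        if any(n < 0 for n in (self.n_myofibrils, self.n_nuclei, self.n_mitochondria)):
            raise ValueError("object counts must be non-negative")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(spacing=self.spacing, unit="nm")


@dataclass(frozen=True)
class HeartPhantomParams:
    """Two-chamber heart label phantom at micro-CT scale (lengths in µm)."""

    seed: int
    grid_shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (20.0, 20.0, 20.0)
    lv_semiaxes: tuple[float, float, float] = (600.0, 500.0, 800.0)
    rv_semiaxes: tuple[float, float, float] = (506.0, 421.7, 674.7)
    wall_thickness: float = 200.0
    lv_center_frac: tuple[float, float, float] = (0.32, 0.5, 0.5)
    rv_center_frac: tuple[float, float, float] = (0.75, 0.5, 0.5)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")
        if any(a <= 0 for a in self.lv_semiaxes + self.rv_semiaxes):
            raise ValueError("lumen semiaxes must be > 0")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(spacing=self.spacing, unit="um")


def rv_semiaxes_for_ratio(lv_semiaxes: tuple[float, float, float],
                          ratio: float) -> tuple[float, float, float]:
    """RV semiaxes giving an analytic RV/LV lumen volume ratio.

    Ellipsoid volume is 4/3·π·abc, so scaling all semiaxes by ratio^(1/3)
    scales the volume by exactly ``ratio``.
    """
    s = ratio ** (1.0 / 3.0)
    return tuple(a * s for a in lv_semiaxes)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# geometric rasterizers (anisotropic voxel grids, physical coordinates)


def fold_axial(angles_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold angles into the axial range [0°, 180°)."""
    return np.mod(angles_deg, 180.0)


def direction_from_angles(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit axis vector (x, y, z) whose x–y projection makes angle θ with +x
    and whose x–z projection makes angle Φ with +x.

    Sign-normalized to x ≥ 0 so that folded angles are recovered exactly.
    """
    t = math.radians(fold_axial(theta_deg))
    p = math.radians(fold_axial(phi_deg))
    d = np.array([1.0, math.tan(t), math.tan(p)])
    d /= np.linalg.norm(d)
    if d[0] < 0 or (d[0] == 0 and (d[1] < 0 or (d[1] == 0 and d[2] < 0))):
        d = -d
    return d


def rasterize_cylinder(axis: np.ndarray, center: np.ndarray, radius: float,
                       length: float, geometry: VolumeGeometry,
                       grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel indices (N, 3) as (i, j, k) inside a finite cylinder.

    ``axis`` is a direction in physical coordinates (normalized internally);
    ``center`` and the radius/length are physical.  A voxel is included when
    its center lies strictly within ``radius`` of the axis segment and its
    axial coordinate t satisfies 0 ≤ t < length (half-open, so a cylinder of
    length L aligned with an axis of spacing s spans exactly L/s voxel
    centers).  Parts outside the grid are clipped; a cylinder entirely
    outside yields an empty set.
    """
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("axis vector must be nonzero")
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be > 0")
    a = a / norm
    center = np.asarray(center, dtype=float)
    p0 = center - 0.5 * length * a
    nx, ny, nz = grid_shape
    sx, sy, sz = geometry.spacing

    lo = np.minimum(p0, p0 + length * a) - radius
    hi = np.maximum(p0, p0 + length * a) + radius
    j0, j1 = int(np.floor(lo[0] / sx)), int(np.ceil(hi[0] / sx))
    i0, i1 = int(np.floor(lo[1] / sy)), int(np.ceil(hi[1] / sy))
    k0, k1 = int(np.floor(lo[2] / sz)), int(np.ceil(hi[2] / sz))
    i0, i1 = max(i0, 0), min(i1, ny - 1)
    j0, j1 = max(j0, 0), min(j1, nx - 1)
    k0, k1 = max(k0, 0), min(k1, nz - 1)
    if i0 > i1 or j0 > j1 or k0 > k1:
        return np.empty((0, 3), dtype=np.int64)

    # broadcastable physical offsets from p0
    wy = (np.arange(i0, i1 + 1) * sy - p0[1])[:, None, None]
    wx = (np.arange(j0, j1 + 1) * sx - p0[0])[None, :, None]
    wz = (np.arange(k0, k1 + 1) * sz - p0[2])[None, None, :]
    t = wx * a[0] + wy * a[1] + wz * a[2]
    d2 = wx * wx + wy * wy + wz * wz - t * t
    inside = (t >= 0.0) & (t < length) & (d2 < radius * radius)
    ii, jj, kk = np.nonzero(inside)
    out = np.empty((ii.size, 3), dtype=np.int64)
    out[:, 0] = ii + i0
    out[:, 1] = jj + j0
    out[:, 2] = kk + k0
    return out


def rasterize_ellipsoid(center: np.ndarray, semiaxes: np.ndarray,
                        geometry: VolumeGeometry,
                        grid_shape: tuple[int, int, int],
                        rotation_z_deg: float = 0.0) -> np.ndarray:
    """Voxel indices (i, j, k) whose centers lie inside an ellipsoid.

    The ellipsoid may be rotated about the z axis (in-plane) by
    ``rotation_z_deg``.  Inclusion is Σ(q/a)² ≤ 1 on voxel centers.
    """
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semiaxes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semiaxes must be > 0")
    nx, ny, nz = grid_shape
    sx, sy, sz = geometry.spacing
    r = max(semi[0], semi[1])
    lo = center - np.array([r, r, semi[2]])
    hi = center + np.array([r, r, semi[2]])
    j0, j1 = max(int(np.floor(lo[0] / sx)), 0), min(int(np.ceil(hi[0] / sx)), nx - 1)
    i0, i1 = max(int(np.floor(lo[1] / sy)), 0), min(int(np.ceil(hi[1] / sy)), ny - 1)
    k0, k1 = max(int(np.floor(lo[2] / sz)), 0), min(int(np.ceil(hi[2] / sz)), nz - 1)
    if i0 > i1 or j0 > j1 or k0 > k1:
        return np.empty((0, 3), dtype=np.int64)
    dy = (np.arange(i0, i1 + 1) * sy - center[1])[:, None, None]
    dx = (np.arange(j0, j1 + 1) * sx - center[0])[None, :, None]
    dz = (np.arange(k0, k1 + 1) * sz - center[2])[None, None, :]
    c, s = math.cos(math.radians(rotation_z_deg)), math.sin(math.radians(rotation_z_deg))
    u = c * dx + s * dy     # along first semiaxis
    v = -s * dx + c * dy    # along second semiaxis
    q = (u / semi[0]) ** 2 + (v / semi[1]) ** 2 + (dz / semi[2]) ** 2
    ii, jj, kk = np.nonzero(q <= 1.0)
    out = np.empty((ii.size, 3), dtype=np.int64)
    out[:, 0] = ii + i0
    out[:, 1] = jj + j0
    out[:, 2] = kk + k0
    return out


# ---------------------------------------------------------------------------
# EM phantom


@dataclass
class EmPhantom:
    """Output bundle of :func:`generate_em_volume`."""

    intensity: VoxelVolume
    labels: LabelVolume
    fibril_ids: np.ndarray            # int32 volume, 0 = no fibril, ids from 1
    angles: pd.DataFrame              # fibril_id, theta_true_deg, phi_true_deg
    true_slice_shifts: np.ndarray     # (nz, 2) applied (di, dj) jitter per slice
    params: EmPhantomParams


def _mark_blocked(blocked: np.ndarray, voxels: np.ndarray) -> None:
    """Set a 1-voxel dilated neighbourhood of ``voxels`` in ``blocked`` so
    subsequently placed objects stay disconnected (26-connectivity) from
    earlier ones."""
    if voxels.size == 0:
        return
    shape = blocked.shape
    lo = np.maximum(voxels.min(axis=0) - 1, 0)
    hi = np.minimum(voxels.max(axis=0) + 2, shape)
    sub = np.zeros(tuple(hi - lo), dtype=bool)
    sub[tuple((voxels - lo).T)] = True
    sub = ndimage.binary_dilation(sub, structure=np.ones((3, 3, 3), dtype=bool))
    region = tuple(slice(a, b) for a, b in zip(lo, hi))
    blocked[region] |= sub


def _sample_center(rng: np.random.Generator, extent: np.ndarray,
                   half_span: np.ndarray) -> np.ndarray:
    """Uniform center such that the object's bounding box fits in the grid."""
    lo = np.minimum(half_span, 0.5 * extent)
    hi = np.maximum(extent - half_span, 0.5 * extent)
    return lo + rng.random(3) * (hi - lo)


def generate_em_volume(params: EmPhantomParams) -> EmPhantom:
    """Generate a seeded EM phantom with ground-truth labels and angles.

    Placement uses bounded rejection sampling: objects never overwrite
    already-placed objects or the extracellular phase, and placed objects are
    separated by at least one voxel so each fibril is its own 26-connected
    component.  Raises :class:`PackingError` naming the class when a
    placement cannot be found within ``max_retries`` attempts.
    """
    rng = np.random.default_rng(params.seed)
    nx, ny, nz = params.grid_shape
    geom = params.geometry
    sx, sy, sz = geom.spacing
    shape = (ny, nx, nz)
    extent = np.array([nx * sx, ny * sy, nz * sz])

    labels = np.full(shape, CLASS_OTHER_CYTOPLASM, dtype=np.uint8)
    fibril_ids = np.zeros(shape, dtype=np.int32)
    blocked = np.zeros(shape, dtype=bool)

    def place(candidate_fn, class_name: str) -> np.ndarray:
        for _ in range(params.max_retries):
            vox = candidate_fn()
            if vox.size == 0:
                continue
            if not blocked[tuple(vox.T)].any():
                _mark_blocked(blocked, vox)
                return vox
        raise PackingError(
            f"could not place a {class_name} without overlap after "
            f"{params.max_retries} retries")

    # nuclei first (largest objects)
    for _ in range(params.n_nuclei):
        semi = np.asarray(params.nucleus_semiaxes, dtype=float)

        def cand_nuc(semi=semi):
            c = _sample_center(rng, extent, np.array([max(semi[0], semi[1])] * 2 + [semi[2]]))
            rot = rng.uniform(0.0, 180.0)
            return rasterize_ellipsoid(c, semi, geom, params.grid_shape, rot)

        vox = place(cand_nuc, "nucleus")
        labels[tuple(vox.T)] = CLASS_NUCLEUS

    # myofibrils with ground-truth angles
    records = []
    theta = fold_axial(rng.normal(params.theta_mean, params.theta_sd,
                                  params.n_myofibrils))
    phi = fold_axial(rng.normal(params.phi_mean, params.phi_sd,
                                params.n_myofibrils))
    for n in range(params.n_myofibrils):
        d = direction_from_angles(float(theta[n]), float(phi[n]))
        half = 0.5 * params.fibril_length * np.abs(d) + params.fibril_radius

        def cand_fib(d=d, half=half):
            c = _sample_center(rng, extent, half)
            return rasterize_cylinder(d, c, params.fibril_radius,
                                      params.fibril_length, geom,
                                      params.grid_shape)

        vox = place(cand_fib, "myofibril")
        labels[tuple(vox.T)] = CLASS_MYOFIBRIL
        fibril_ids[tuple(vox.T)] = n + 1
        records.append((n + 1, float(theta[n]), float(phi[n])))
    angles = pd.DataFrame(records,
                          columns=["fibril_id", "theta_true_deg", "phi_true_deg"])

    # mitochondria: ellipsoidal blobs with jittered semiaxes
    for _ in range(params.n_mitochondria):
        def cand_mito():
            semi = np.asarray(params.mito_semiaxes) * rng.uniform(0.7, 1.3, 3)
            c = _sample_center(rng, extent,
                               np.array([max(semi[0], semi[1])] * 2 + [semi[2]]))
            rot = rng.uniform(0.0, 180.0)
            return rasterize_ellipsoid(c, semi, geom, params.grid_shape, rot)

        vox = place(cand_mito, "mitochondrion")
        labels[tuple(vox.T)] = CLASS_MITOCHONDRION

    # Extracellular phase, carved last from the remaining cytoplasm: a
    # smoothed Gaussian random field gives contiguous blobs, and taking the
    # top-valued free voxels realizes the requested fraction of the TOTAL
    # grid exactly (organelles are never overwritten).
    if params.ec_fraction_target > 0:
        n_ec = int(round(params.ec_fraction_target * labels.size))
        free = labels == CLASS_OTHER_CYTOPLASM
        n_free = int(free.sum())
        if n_ec > n_free:
            raise PackingError(
                "could not realize the extracellular fraction: only "
                f"{n_free} unoccupied voxels for a target of {n_ec}")
        f = rng.standard_normal(shape)
        sig_lat = 12.0
        f = ndimage.gaussian_filter(f, sigma=(sig_lat, sig_lat, sig_lat * sx / sz))
        fv = np.where(free, f, -np.inf).ravel()
        take = np.argpartition(fv, -n_ec)[-n_ec:]
        labels.ravel()[take] = CLASS_EXTRACELLULAR

    # intensity model: class mean + optional per-slice offset + white noise
    means = np.zeros(256)
    for cls, m in params.intensity_means.items():
        means[cls] = m
    img = means[labels]
    if params.slice_brightness_sd > 0:
        img = img + rng.normal(0.0, params.slice_brightness_sd, nz)[None, None, :]
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # per-slice translation jitter (circular shifts, slice 0 is the reference)
    shifts = np.zeros((nz, 2), dtype=np.int64)
    if params.slice_jitter_sd > 0:
        shifts[1:] = np.rint(
            rng.normal(0.0, params.slice_jitter_sd, (nz - 1, 2))).astype(np.int64)
        for k in range(1, nz):
            img[:, :, k] = np.roll(img[:, :, k], tuple(shifts[k]), axis=(0, 1))

    return EmPhantom(
        intensity=VoxelVolume(img, geom),
        labels=LabelVolume(labels, dict(EM_CLASS_MAP), geom),
        fibril_ids=fibril_ids,
        angles=angles,
        true_slice_shifts=shifts,
        params=params,
    )


# ---------------------------------------------------------------------------
# whole-heart phantom


def generate_heart_phantom(params: HeartPhantomParams) -> LabelVolume:
    """Two-chamber heart label phantom: background / tissue / LV lumen / RV lumen.

    Lumens are ellipsoids; tissue is an ellipsoidal shell of ``wall_thickness``
    around each lumen (shells may merge into a septum).  Raises ``ValueError``
    if the rasterized lumens overlap.
    """
    nx, ny, nz = params.grid_shape
    geom = params.geometry
    extent = np.array([nx * geom.spacing[0], ny * geom.spacing[1],
                       nz * geom.spacing[2]])
    labels = np.zeros((ny, nx, nz), dtype=np.uint8)

    lv_c = np.asarray(params.lv_center_frac) * extent
    rv_c = np.asarray(params.rv_center_frac) * extent
    w = params.wall_thickness
    for center, semi in ((lv_c, params.lv_semiaxes), (rv_c, params.rv_semiaxes)):
        outer = rasterize_ellipsoid(center, np.asarray(semi) + w, geom,
                                    params.grid_shape)
        labels[tuple(outer.T)] = HEART_TISSUE
    lv = rasterize_ellipsoid(lv_c, np.asarray(params.lv_semiaxes), geom,
                             params.grid_shape)
    rv = rasterize_ellipsoid(rv_c, np.asarray(params.rv_semiaxes), geom,
                             params.grid_shape)
    lv_set = set(map(tuple, lv))
    if lv_set.intersection(map(tuple, rv)):
        raise ValueError("LV and RV lumens overlap after rasterization")
    labels[tuple(lv.T)] = HEART_LV_LUMEN
    labels[tuple(rv.T)] = HEART_RV_LUMEN
    return LabelVolume(labels, dict(HEART_CLASS_MAP), geom)
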