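"""Synthetic 3D-echocardiography-like phantoms.

Real 3DE volumes show a dark left-ventricular (LV) blood pool inside a bright
myocardial shell, heavy multiplicative speckle, and — crucially for
segmentation — a left atrium (LA) of the same blood-pool intensity adjacent to
the LV across the mitral plane.  Because LV and LA are connected through the
mitral opening with no intensity edge between them, boundary-attracted
segmentation methods tend to "leak" from the ventricle into the atrium.

This module builds a geometric stand-in for that scene: the LV cavity is a
truncated (half) ellipsoid — the standard geometric LV approximation with
circular short-axis cross-sections — wrapped in a constant-thickness bright
wall obtained from a Euclidean distance transform of the blood pool.  An
optional atrial cavity sits past the basal plane, connected through a
cylindrical channel of the mitral opening radius, reproducing the leak hazard
axially.  Speckle is multiplicative with a right-skewed unit-mean gamma
distribution followed by Gaussian smoothing — a first-order B-mode texture
surrogate, not a physical ultrasound simulation.

Alongside the intensity volume the generator returns the analytic ground
truth: the exact voxelized cavity mask and a ring-parametrized surface mesh
sampled from the analytic half-ellipsoid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .core import LabelMask, Volume
from .mesh import TubeMesh

__all__ = ["PhantomSpec", "generate_phantom", "degrade_mask", "analytic_cavity_mesh"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one phantom volume.

    All lengths are in mm; intensities are gray levels in [0, 1].  The basal
    plane is the last Z slice of the cavity; the atrium sits beyond it so that
    the LV/LA leak hazard is axial.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cavity_semi_axes: tuple[float, float, float] = (14.0, 14.0, 28.0)
    wall_thickness: float = 4.0
    cavity_intensity: float = 0.10
    wall_intensity: float = 0.80
    background_intensity: float = 0.30
    atrium_enabled: bool = False
    atrium_offset: float = 4.0
    mitral_opening_radius: float = 12.0
    speckle_scale: float = 0.15
    smoothing_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cavity_semi_axes):
            raise ValueError("cavity semi-axes must be strictly positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be strictly positive")
        if self.mitral_opening_radius <= 0:
            raise ValueError("mitral opening radius must be strictly positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        for name in ("cavity_intensity", "wall_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.speckle_scale < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise parameters must be non-negative")

    # --- derived geometry ------------------------------------------------
    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing)

    @property
    def center_xy(self) -> tuple[float, float]:
        """In-plane cavity center (mm, voxel-center convention)."""
        ext = self.extent_mm
        return (ext[0] / 2.0, ext[1] / 2.0)

    @property
    def apical_margin(self) -> float:
        return self.wall_thickness + max(self.spacing)

    @property
    def base_z(self) -> float:
        """z (mm) of the basal plane — the last slice of the LV cavity."""
        return self.apical_margin + self.cavity_semi_axes[2]

    def validate_fit(self) -> None:
        a, b, c = self.cavity_semi_axes
        t = self.wall_thickness
        ext = self.extent_mm
        cx, cy = self.center_xy
        if cx - (a + t) < 0 or cy - (b + t) < 0:
            raise ValueError(
                "grid too small: cavity plus wall exceeds the in-plane extent; "
                "enlarge grid_shape or shrink cavity_semi_axes/wall_thickness"
            )
        z_needed = self.base_z + t
        if self.atrium_enabled:
            z_needed = self.base_z + self.atrium_offset + 2 * self._atrium_half_height() + t
        if z_needed > ext[2]:
            raise ValueError(
                "grid too small along z: cavity (and atrium) plus wall does not fit; "
                "enlarge grid_shape[2] or shrink the geometry"
            )

    def _atrium_half_height(self) -> float:
        ext = self.extent_mm
        avail = ext[2] - (self.base_z + self.atrium_offset) - self.wall_thickness - max(self.spacing)
        return max(min(0.5 * self.cavity_semi_axes[2], avail / 2.0), 2 * max(self.spacing))

    # --- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        for k in ("grid_shape", "spacing", "cavity_semi_axes"):
            d[k] = list(d[k])
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("grid_shape", "spacing", "cavity_semi_axes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center world coordinates (mm) on the phantom grid, (X,Y,Z) sparse."""
    xs, ys, zs = (
        (np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, spec.spacing)
    )
    return np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)


def _cavity_mask(spec: PhantomSpec) -> np.ndarray:
    """Exact voxelization of the half-ellipsoid LV cavity (voxel-center rule)."""
    a, b, c = spec.cavity_semi_axes
    cx, cy = spec.center_xy
    zb = spec.base_z
    x, y, z = _coordinate_grids(spec)
    inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - zb) / c) ** 2 <= 1.0
    return inside & (z <= zb)


def _blood_pool(spec: PhantomSpec, lv: np.ndarray) -> np.ndarray:
    """LV cavity plus (optionally) the atrial cavity and the mitral channel."""
    if not spec.atrium_enabled:
        return lv
    a, b, _ = spec.cavity_semi_axes
    cx, cy = spec.center_xy
    zb = spec.base_z
    ha = spec._atrium_half_height()
    az = zb + spec.atrium_offset + ha  # atrium center z
    aa, ab = 0.85 * a, 0.85 * b  # LA nearly as wide as the LV base
    x, y, z = _coordinate_grids(spec)
    atrium = ((x - cx) / aa) ** 2 + ((y - cy) / ab) ** 2 + ((z - az) / ha) ** 2 <= 1.0
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    channel = (r2 <= spec.mitral_opening_radius**2) & (z > zb - max(spec.spacing)) & (z <= az)
    return lv | atrium | channel


def generate_phantom(
    spec: PhantomSpec, points_per_ring: int = 36
) -> tuple[Volume, LabelMask, TubeMesh]:
    """Generate (intensity volume, exact LV cavity mask, analytic surface mesh).

    The mask voxels are exactly the analytic half-ellipsoid interior sampled
    at voxel centers; the volume is the piecewise-constant intensity map with
    multiplicative speckle and Gaussian smoothing; the mesh samples the
    analytic cavity surface slice by slice.  Identical spec (including seed)
    yields bit-identical outputs.
    """
    spec.validate_fit()
    lv = _cavity_mask(spec)
    pool = _blood_pool(spec, lv)

    # constant-thickness bright wall around the whole blood pool
    dist = ndimage.distance_transform_edt(~pool, sampling=spec.spacing)
    wall = (dist <= spec.wall_thickness) & ~pool

    img = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    img[wall] = spec.wall_intensity
    img[pool] = spec.cavity_intensity

    if spec.speckle_scale > 0:
        rng = np.random.default_rng(spec.seed)
        s2 = spec.speckle_scale**2
        img *= rng.gamma(shape=1.0 / s2, scale=s2, size=img.shape)
    if spec.smoothing_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=[spec.smoothing_sigma / s for s in spec.spacing]
        )

    half_vox = tuple(s / 2.0 for s in spec.spacing)
    vol = Volume(img.astype(np.float32), spec.spacing, half_vox)
    mask = LabelMask(lv.astype(np.uint8), spec.spacing, half_vox)
    mesh = analytic_cavity_mesh(spec, points_per_ring)
    return vol, mask, mesh


def analytic_cavity_mesh(spec: PhantomSpec, points_per_ring: int = 36) -> TubeMesh:
    """Exact cavity surface sampled as one contour ring per z slice.

    Rings run apex-to-base; the apex vertex is the analytic apex of the
    half-ellipsoid.  Apical slices whose cross-section radius falls below half
    a voxel are folded into the apex cap rather than emitted as degenerate
    rings.
    """
    a, b, c = spec.cavity_semi_axes
    cx, cy = spec.center_xy
    zb = spec.base_z
    sz = spec.spacing[2]
    z_centers = (np.arange(spec.grid_shape[2]) + 0.5) * sz
    in_cavity = (z_centers >= zb - c) & (z_centers <= zb)
    frac = np.sqrt(np.clip(1.0 - ((z_centers - zb) / c) ** 2, 0.0, None))
    min_r = 0.5 * max(spec.spacing[:2])
    keep = in_cavity & (a * frac >= min_r)
    theta = 2 * np.pi * np.arange(points_per_ring) / points_per_ring
    rings = np.empty((keep.sum(), points_per_ring, 3))
    for k, z in enumerate(z_centers[keep]):
        f = np.sqrt(1.0 - ((z - zb) / c) ** 2)
        rings[k, :, 0] = cx + a * f * np.cos(theta)
        rings[k, :, 1] = cy + b * f * np.sin(theta)
        rings[k, :, 2] = z
    apex = np.array([cx, cy, zb - c])
    return TubeMesh(rings, apex)


def sphere_phantom(
    radius: float = 16.0,
    wall_thickness: float = 4.0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    cavity_intensity: float = 0.10,
    wall_intensity: float = 0.80,
    background_intensity: float = 0.30,
    smoothing_sigma: float = 0.5,
) -> tuple[Volume, TubeMesh]:
    """Noiseless ball phantom: dark spherical cavity in a bright shell.

    A validation target with a clean radial edge at every latitude — the
    analytic answer for any edge-seeking surface is the sphere of the given
    radius.  Returns the volume and the exact lower-hemisphere tube mesh
    (rings apex-to-equator, apex at the sphere's south pole).
    """
    ext = np.asarray(grid_shape) * np.asarray(spacing)
    ctr = ext / 2.0
    xs, ys, zs = (
        (np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing)
    )
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    d = np.sqrt((x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2)
    img = np.full(grid_shape, background_intensity, dtype=np.float64)
    img[d <= radius + wall_thickness] = wall_intensity
    img[d <= radius] = cavity_intensity
    if smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=[smoothing_sigma / s for s in spacing])
    vol = Volume(img.astype(np.float32), tuple(spacing), tuple(s / 2 for s in spacing))

    # lower hemisphere rings, one per z slice below the center plane
    z_centers = (np.arange(grid_shape[2]) + 0.5) * spacing[2]
    keep = (z_centers >= ctr[2] - radius) & (z_centers <= ctr[2])
    theta = 2 * np.pi * np.arange(36) / 36
    rings = []
    for zc in z_centers[keep]:
        r = np.sqrt(max(radius**2 - (zc - ctr[2]) ** 2, 0.0))
        if r < max(spacing[:2]):
            continue
        rings.append(
            np.stack(
                [ctr[0] + r * np.cos(theta), ctr[1] + r * np.sin(theta), np.full(36, zc)],
                axis=1,
            )
        )
    apex = np.array([ctr[0], ctr[1], ctr[2] - radius])
    return vol, TubeMesh(np.asarray(rings), apex)


def degrade_mask(
    mask: LabelMask,
    dropout_rate: float = 0.1,
    blob_rate: float = 0.2,
    boundary_jitter: int = 1,
    seed: int = 0,
) -> LabelMask:
    """Simulate coarse pixel-classifier imperfections on a clean mask.

    Per z slice: a random erosion/dilation of up to ``boundary_jitter`` voxels,
    random hole dropout inside the foreground at rate ``dropout_rate``, and
    spurious off-target blobs at rate ``blob_rate``.  With all three knobs at
    zero the input is returned unchanged.  Degradation is reproducible for a
    fixed seed.
    """
    if not (0.0 <= dropout_rate < 1.0 and 0.0 <= blob_rate < 1.0):
        raise ValueError("rates must be in [0, 1)")
    if boundary_jitter < 0:
        raise ValueError("boundary_jitter must be non-negative")
    if dropout_rate == 0 and blob_rate == 0 and boundary_jitter == 0:
        return LabelMask(mask.data.copy(), mask.spacing, mask.origin)

    rng = np.random.default_rng(seed)
    out = mask.data.copy()
    nx, ny, nz = out.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    for z in range(nz):
        sl = out[:, :, z].astype(bool)
        if not sl.any():
            continue
        if boundary_jitter > 0:
            k = int(rng.integers(-boundary_jitter, boundary_jitter + 1))
            if k > 0:
                sl = ndimage.binary_dilation(sl, iterations=k)
            elif k < 0:
                eroded = ndimage.binary_erosion(sl, iterations=-k)
                if eroded.any():
                    sl = eroded
        if dropout_rate > 0 and sl.any() and rng.random() < dropout_rate:
            fg = np.argwhere(sl)
            cx_, cy_ = fg[rng.integers(len(fg))]
            r = rng.integers(1, 4)
            sl &= (xx - cx_) ** 2 + (yy - cy_) ** 2 > r**2
        if blob_rate > 0 and rng.random() < blob_rate:
            # spurious blob well clear of the true component
            far = ndimage.distance_transform_edt(~sl) > 6
            far[:2, :] = far[-2:, :] = False
            far[:, :2] = far[:, -2:] = False
            cand = np.argwhere(far)
            if len(cand):
                bx, by = cand[rng.integers(len(cand))]
                r = rng.integers(1, 5)
                sl |= (xx - bx) ** 2 + (yy - by) ** 2 <= r**2
        out[:, :, z] = sl
    return LabelMask(out.astype(np.uint8), mask.spacing, mask.origin)
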