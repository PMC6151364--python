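"""Automatic geometric initialization of the 3D deformable model.

From a stack of coarse per-slice LV masks (typically pixel-classifier output,
hence imperfect) this module builds the initialization surface ``X_init``:

1.  Per-slice LV centers as the mean coordinate of all foreground pixels.
2.  Quadratic (least-squares) curve correction of the center trajectory along
    z — raw centers of noisy coarse masks are non-collinear in 3D, and
    stacking rings on them misaligns adjacent slices.
3.  Per-slice scale as the mean of 8 ray-cast radii at 45-degree increments,
    under the standard assumption that short-axis LV cross-sections are
    approximately circular: R = (R1 + ... + R8)/8.
4.  Equal resampling of the contour stack at interval k (keep every k-th
    ring; the basal ring is always force-included so the tube spans the full
    chamber).
5.  Tube-mesh reconstruction: rings stitched with triangle bands and an apex
    fan placed one slice beyond the apical ring on the fitted center curve.

Radii are measured from corrected centers and against the largest connected
component of each slice, which makes the initializer robust to the spurious
islands coarse masks contain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .core import LabelMask
from .mesh import TubeMesh

__all__ = [
    "SliceCenter",
    "ContourRing",
    "estimate_centers",
    "fit_center_curve",
    "estimate_ring",
    "resample_contours",
    "build_mesh",
    "initialize_mesh",
]

_RAY_ANGLES = np.deg2rad(np.arange(8) * 45.0)


@dataclass
class SliceCenter:
    """Per-slice LV center estimate (pixel coordinates)."""

    z: int
    raw_center: tuple[float, float] | None
    foreground_count: int
    corrected_center: tuple[float, float] | None = None

    @property
    def has_foreground(self) -> bool:
        return self.foreground_count > 0


@dataclass
class ContourRing:
    """One per-slice circular LV contour."""

    z: int
    center: tuple[float, float]
    ray_radii: np.ndarray  # 8 entries, NaN where the ray found no foreground
    R: float
    points: np.ndarray  # (N, 2) closed counter-clockwise ring, pixel coords

    def __post_init__(self) -> None:
        valid = self.ray_radii[np.isfinite(self.ray_radii)]
        assert np.isclose(self.R, valid.mean()), "R must be the mean of valid rays"


def estimate_centers(mask: LabelMask | np.ndarray) -> list[SliceCenter]:
    """Mean foreground coordinate of every z slice of a coarse mask stack.

    Slices with no foreground are flagged (``raw_center is None``), never
    fabricated.  Requires at least 3 foreground slices (the downstream
    quadratic fit needs them).
    """
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    centers: list[SliceCenter] = []
    n_fg = 0
    for z in range(data.shape[2]):
        sl = data[:, :, z]
        cnt = int(sl.sum())
        if cnt == 0:
            centers.append(SliceCenter(z, None, 0))
            continue
        n_fg += 1
        xs, ys = np.nonzero(sl)
        centers.append(SliceCenter(z, (float(xs.mean()), float(ys.mean())), cnt))
    if n_fg < 3:
        raise ValueError(
            f"need at least 3 slices with foreground for center-curve fitting, got {n_fg}"
        )
    return centers


def fit_center_curve(centers: list[SliceCenter]) -> list[SliceCenter]:
    """Least-squares quadratic fit x(z), y(z) over foreground slices.

    ``corrected_center`` evaluates the fitted polynomials at every slice with
    foreground and also interpolates across flagged empty interior slices
    (between the first and last foreground slice).  A line or 3 exact points
    is reproduced exactly — the quadratic nests those cases.
    """
    fg = [c for c in centers if c.has_foreground]
    if len(fg) < 3:
        raise ValueError("need at least 3 centers to fit a quadratic")
    zs = np.array([c.z for c in fg], dtype=float)
    if np.ptp(zs) == 0:
        raise ValueError("all centers at the same z: quadratic fit is rank-deficient")
    xs = np.array([c.raw_center[0] for c in fg])
    ys = np.array([c.raw_center[1] for c in fg])
    px = np.polynomial.polynomial.polyfit(zs, xs, 2)
    py = np.polynomial.polynomial.polyfit(zs, ys, 2)
    z_lo, z_hi = int(zs.min()), int(zs.max())
    out: list[SliceCenter] = []
    for c in centers:
        cc = None
        if z_lo <= c.z <= z_hi:
            cc = (
                float(np.polynomial.polynomial.polyval(c.z, px)),
                float(np.polynomial.polynomial.polyval(c.z, py)),
            )
        out.append(SliceCenter(c.z, c.raw_center, c.foreground_count, cc))
    return out


def center_curve_eval(centers: list[SliceCenter], z: float) -> tuple[float, float]:
    """Evaluate the fitted center polynomials at an arbitrary (fractional) z."""
    fg = [c for c in centers if c.has_foreground]
    zs = np.array([c.z for c in fg], dtype=float)
    px = np.polynomial.polynomial.polyfit(zs, [c.raw_center[0] for c in fg], 2)
    py = np.polynomial.polynomial.polyfit(zs, [c.raw_center[1] for c in fg], 2)
    return (
        float(np.polynomial.polynomial.polyval(z, px)),
        float(np.polynomial.polynomial.polyval(z, py)),
    )


def _largest_component(sl: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(sl)
    if n <= 1:
        return sl.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def estimate_ring(
    mask_slice: np.ndarray,
    center: tuple[float, float],
    z: int = 0,
    points_per_ring: int = 36,
    step: float = 0.25,
) -> ContourRing:
    """8-ray radius estimate of one slice's circular LV contour.

    Rays are marched from ``center`` at 0, 45, ..., 315 degrees; each radius is
    the distance to the last foreground-to-background transition of the
    slice's largest connected component along the ray.  Rays that never hit
    foreground are excluded (flagged NaN); fewer than 4 valid rays rejects the
    slice.  The returned ring samples ``points_per_ring`` points
    counter-clockwise on the circle of the mean radius R.
    """
    sl = np.asarray(mask_slice)
    cx, cy = center
    if not (0 <= cx < sl.shape[0] and 0 <= cy < sl.shape[1]):
        raise ValueError(f"center {center} outside the image {sl.shape}")
    if not sl.any():
        raise ValueError("empty slice: no foreground to estimate a radius from")
    main = _largest_component(sl)
    max_r = float(np.hypot(*sl.shape))
    radii = np.full(8, np.nan)
    ts = np.arange(step, max_r, step)
    for i, ang in enumerate(_RAY_ANGLES):
        px = cx + ts * np.cos(ang)
        py = cy + ts * np.sin(ang)
        ok = (px >= 0) & (px <= sl.shape[0] - 1) & (py >= 0) & (py <= sl.shape[1] - 1)
        if not ok.any():
            continue
        hit = main[np.round(px[ok]).astype(int), np.round(py[ok]).astype(int)]
        if hit.any():
            radii[i] = ts[ok][np.nonzero(hit)[0][-1]]  # outermost fg sample
    valid = np.isfinite(radii)
    if valid.sum() < 4:
        raise ValueError(f"only {int(valid.sum())} of 8 rays hit foreground; slice rejected")
    r_mean = float(radii[valid].mean())
    theta = 2 * np.pi * np.arange(points_per_ring) / points_per_ring
    pts = np.stack([cx + r_mean * np.cos(theta), cy + r_mean * np.sin(theta)], axis=1)
    return ContourRing(z=z, center=(cx, cy), ray_radii=radii, R=r_mean, points=pts)


def resample_contours(rings: list[ContourRing], k: int) -> list[ContourRing]:
    """Keep every k-th ring (0-based positions 0, k, 2k, ...).

    The basal-most ring (the last one) is force-included if the stride does
    not land on it, so the mesh always spans the full chamber.
    """
    if k < 1:
        raise ValueError(f"sampling interval k must be >= 1, got {k}")
    idx = list(range(0, len(rings), k))
    if idx[-1] != len(rings) - 1:
        idx.append(len(rings) - 1)
    return [rings[i] for i in idx]


def build_mesh(
    rings: list[ContourRing],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    apex_z: float | None = None,
    apex_center: tuple[float, float] | None = None,
) -> TubeMesh:
    """Stitch ordered contour rings (apex-to-base) into a tube mesh in mm.

    Adjacent rings are joined by 2N triangles matching points by angular
    index; the apical end is capped by a fan to an apex vertex placed one
    slice beyond the apical ring (at ``apex_z`` if given, else one z step
    below ring 0) on the center curve; the base stays open.  Pixel indices
    are mapped to mm as ``origin + index * spacing`` (voxel centers).
    """
    if len(rings) < 2:
        raise ValueError("need at least 2 rings to build a tube mesh")
    n = rings[0].points.shape[0]
    if any(r.points.shape[0] != n for r in rings):
        raise ValueError("all rings must have the same number of points")
    sp = np.asarray(spacing, dtype=float)
    og = np.asarray(origin, dtype=float)
    grid = np.empty((len(rings), n, 3))
    for i, r in enumerate(rings):
        grid[i, :, 0] = og[0] + r.points[:, 0] * sp[0]
        grid[i, :, 1] = og[1] + r.points[:, 1] * sp[1]
        grid[i, :, 2] = og[2] + r.z * sp[2]
    if apex_z is None:
        apex_z = rings[0].z - 1.0
    if apex_center is None:
        apex_center = rings[0].center
    apex = og + np.array([apex_center[0] * sp[0], apex_center[1] * sp[1], apex_z * sp[2]])
    return TubeMesh(grid, apex)


def initialize_mesh(
    coarse: LabelMask,
    k: int = 10,
    points_per_ring: int = 36,
    apex_low_z: bool | None = None,
) -> tuple[TubeMesh, list[ContourRing]]:
    """Full initialization pipeline: coarse mask stack -> X_init tube mesh.

    ``apex_low_z`` overrides apex/base orientation; by default it is detected
    from the foreground-area gradient along z (the cross-section area shrinks
    toward the apex).  Rings are estimated on corrected centers, resampled at
    interval ``k``, ordered apex-to-base, and stitched with the apex placed on
    the fitted center curve one slice beyond the apical ring.
    """
    centers = fit_center_curve(estimate_centers(coarse))
    usable = [c for c in centers if c.has_foreground and c.corrected_center is not None]
    rings: list[ContourRing] = []
    for c in usable:
        try:
            rings.append(
                estimate_ring(
                    coarse.data[:, :, c.z], c.corrected_center, z=c.z,
                    points_per_ring=points_per_ring,
                )
            )
        except ValueError:
            continue  # degenerate slice (empty after component filtering)
    if len(rings) < 2:
        raise ValueError("fewer than 2 usable contour rings; cannot build a mesh")

    if apex_low_z is None:
        areas = np.array([r.R for r in rings])
        half = max(len(areas) // 3, 1)
        apex_low_z = areas[:half].mean() < areas[-half:].mean()
    if not apex_low_z:
        rings = rings[::-1]

    rings = resample_contours(rings, k)
    apex_dir = -1 if apex_low_z else 1
    apex_z = rings[0].z + apex_dir * 1.0
    apex_center = center_curve_eval(centers, apex_z)
    mesh = build_mesh(
        rings, coarse.spacing, coarse.origin, apex_z=apex_z, apex_center=apex_center
    )
    return mesh, rings


def rings_to_yaml(rings: list[ContourRing], path: str | Path) -> Path:
    """Write the ring table (z, center, R) to YAML."""
    tab = [
        {
            "z": int(r.z),
            "center": [float(r.center[0]), float(r.center[1])],
            "R": float(r.R),
        }
        for r in rings
    ]
    path = Path(path)
    path.write_text(yaml.safe_dump({"rings": tab}, sort_keys=False))
    return path
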