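"""Spatially regularized 3D snake (active surface) for LV refinement.

The surface ``X`` is the ring-parametrized tube mesh produced by the
initializer.  It evolves by explicit gradient descent on the energy

    E(X) = sum over vertices of
             1/2 alpha |X'|^2  +  1/2 beta |X''|^2          (internal)
           + delta * E_ext(X)                               (external)
           + eta   * |X - X_init|^2                         (spatial regularization)

where the parametric derivatives are realized discretely as circular finite
differences along each ring plus open-chain differences along the z
(ring-to-ring) direction, the apex vertex being the head of every angular
chain (so its first-order neighborhood is the apical ring fan).  The external
energy is the classical snake edge attraction, E_ext = -|grad(G_sigma * I)|^2,
sampled with trilinear interpolation whose analytic in-cell gradient is used
for the force — value and force are therefore consistent to machine precision
away from cell faces, which makes the whole gradient verifiable by finite
differences.

The spatial regularization term ties every vertex to its initialization
counterpart (correspondence is by ring/index, which exists by construction
since the snake evolves X_init's own mesh).  It limits the freedom of
deformation and is what prevents the surface from leaking through the mitral
opening into the atrium, where no intensity edge exists to stop it.

The tension term alone contracts a closed ring (curve-shortening); the
external and regularization terms balance it.  The basal ring is constrained
to its plane (it moves only in-plane) so the open base cannot drift axially.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .core import Volume
from .mesh import TubeMesh

__all__ = [
    "SnakeParams",
    "EnergyBreakdown",
    "ExternalField",
    "external_field",
    "internal_forces",
    "chain_parameter_spacing",
    "energy_and_grad",
    "evolve",
    "leak_test",
]


@dataclass(frozen=True)
class SnakeParams:
    """Snake weights and descent controls.

    alpha/beta/delta/eta follow the published defaults (0.1, 0.2, 0.1, 0.1);
    step_size is the explicit-Euler step tau in mm per unit force, tol the
    mean-vertex-displacement convergence threshold in mm, sigma_ext the
    Gaussian scale of the external field in mm.
    """

    alpha: float = 0.1
    beta: float = 0.2
    delta: float = 0.1
    eta: float = 0.1
    step_size: float = 0.1
    max_iters: int = 500
    tol: float = 1e-3
    sigma_ext: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.delta, self.eta) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.step_size <= 0 or self.tol <= 0:
            raise ValueError("step_size and tol must be positive")
        if self.sigma_ext <= 0:
            raise ValueError("sigma_ext must be positive")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SnakeParams":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class EnergyBreakdown:
    """Per-iteration decomposition of the snake energy."""

    e_internal_1: float
    e_internal_2: float
    e_external: float
    e_init: float

    @property
    def total(self) -> float:
        return self.e_internal_1 + self.e_internal_2 + self.e_external + self.e_init


class ExternalField:
    """Edge-attraction field E_ext = -|grad(G_sigma * I)|^2 with trilinear sampling.

    The continuous field is the trilinear interpolant of the discrete one;
    :meth:`value_and_grad` returns that interpolant's value and its exact
    in-cell spatial gradient (mm^-1), so force and energy agree.  Positions
    are clamped to the valid grid before sampling.
    """

    def __init__(self, vol: Volume, sigma_ext: float, normalize: bool = True):
        if sigma_ext <= 0:
            raise ValueError("sigma_ext must be positive")
        self.spacing = np.asarray(vol.spacing, dtype=float)
        self.origin = np.asarray(vol.origin, dtype=float)
        sigma_vox = [sigma_ext / s for s in vol.spacing]
        smoothed = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma_vox)
        gx, gy, gz = np.gradient(smoothed, *vol.spacing)
        self.field = -(gx**2 + gy**2 + gz**2)
        if normalize and self.field.min() < 0:
            # scale to [-1, 0] so delta weighs images of any contrast equally
            self.field = self.field / -self.field.min()
        self.shape = np.asarray(self.field.shape)

    def _voxel_coords(self, points_mm: np.ndarray) -> np.ndarray:
        p = (np.atleast_2d(points_mm) - self.origin) / self.spacing
        return np.clip(p, 0.0, self.shape - 1.0 - 1e-9)

    def value_and_grad(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Field values and spatial gradients at world points, shapes (K,), (K, 3)."""
        p = self._voxel_coords(points_mm)
        i0 = np.minimum(p.astype(int), self.shape - 2)
        f = p - i0  # fractional position in the cell, each in [0, 1]
        x0, y0, z0 = i0.T
        c = np.empty(p.shape[:1] + (2, 2, 2))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    c[:, dx, dy, dz] = self.field[x0 + dx, y0 + dy, z0 + dz]
        fx, fy, fz = f.T
        wx = np.stack([1 - fx, fx], axis=1)
        wy = np.stack([1 - fy, fy], axis=1)
        wz = np.stack([1 - fz, fz], axis=1)
        dwx = np.stack([-np.ones_like(fx), np.ones_like(fx)], axis=1)
        dwy = np.stack([-np.ones_like(fy), np.ones_like(fy)], axis=1)
        dwz = np.stack([-np.ones_like(fz), np.ones_like(fz)], axis=1)

        def contract(ax, ay, az):
            return np.einsum("kxyz,kx,ky,kz->k", c, ax, ay, az)

        val = contract(wx, wy, wz)
        grad = np.stack(
            [
                contract(dwx, wy, wz) / self.spacing[0],
                contract(wx, dwy, wz) / self.spacing[1],
                contract(wx, wy, dwz) / self.spacing[2],
            ],
            axis=1,
        )
        return val, grad


def external_field(vol: Volume, sigma_ext: float) -> ExternalField:
    """Build the external energy field and its force sampler for a volume."""
    return ExternalField(vol, sigma_ext)


def chain_parameter_spacing(mesh: TubeMesh) -> float:
    """Parameter step along the apex-to-base chains, in ring-index units.

    Rings are unit-spaced in the angular parameter; the vertical chains are
    several image slices apart, so their parameter step is the mean axial
    ring gap divided by the mean in-ring point spacing.  Using this step in
    the finite differences makes the discrete parametrization approximately
    uniform in arc length across both directions — with unit steps, the
    sparse vertical direction would feel a tension out of all proportion to
    the dense angular one, and the tube would collapse axially.
    """
    gaps = np.linalg.norm(np.diff(mesh.ring_centers(), axis=0), axis=1)
    pt = np.linalg.norm(np.roll(mesh.rings, -1, axis=1) - mesh.rings, axis=2)
    du = float(gaps.mean() / max(pt.mean(), 1e-12))
    return max(du, 1.0)


def _internal_energy_grad(
    rings: np.ndarray,
    apex: np.ndarray,
    alpha: float,
    beta: float,
    chain_du: float = 1.0,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Internal energy terms and their exact gradients.

    Returns (E1, E2, grad_rings, grad_apex) where E1 is the first-order
    (tension) sum and E2 the second-order (rigidity) sum over both the ring
    (circular, unit parameter step) and chain (open, apex-headed, parameter
    step ``chain_du``) directions.  Each term is the standard finite-
    difference quadrature of the continuous 1/2 a |X'|^2 + 1/2 b |X''|^2
    integral: first-order terms carry a factor 1/du, second-order 1/du^3.
    """
    g_r = np.zeros_like(rings)
    g_a = np.zeros(3)

    # --- circular differences along each ring (du = 1) -------------------
    d1 = np.roll(rings, -1, axis=1) - rings  # X_{i+1} - X_i
    e1 = 0.5 * alpha * float((d1**2).sum())
    g_r += alpha * (np.roll(d1, 1, axis=1) - d1)

    d2 = np.roll(rings, -1, axis=1) - 2 * rings + np.roll(rings, 1, axis=1)
    e2 = 0.5 * beta * float((d2**2).sum())
    g_r += beta * (np.roll(d2, 1, axis=1) - 2 * d2 + np.roll(d2, -1, axis=1))

    # --- open chains along z, apex as head of every chain ----------------
    w1 = alpha / chain_du
    w2 = beta / chain_du**3

    a1 = rings[0] - apex[None, :]  # (N, 3)
    e1 += 0.5 * w1 * float((a1**2).sum())
    g_r[0] += w1 * a1
    g_a += -w1 * a1.sum(axis=0)

    c1 = rings[1:] - rings[:-1]  # (M-1, N, 3)
    e1 += 0.5 * w1 * float((c1**2).sum())
    g_r[:-1] += -w1 * c1
    g_r[1:] += w1 * c1

    if rings.shape[0] >= 3:
        s2 = rings[2:] - 2 * rings[1:-1] + rings[:-2]  # (M-2, N, 3)
        e2 += 0.5 * w2 * float((s2**2).sum())
        g_r[:-2] += w2 * s2
        g_r[1:-1] += -2 * w2 * s2
        g_r[2:] += w2 * s2

    return e1, e2, g_r, g_a


def energy_and_grad(
    rings: np.ndarray,
    apex: np.ndarray,
    rings_init: np.ndarray,
    apex_init: np.ndarray,
    params: SnakeParams,
    ext: ExternalField | None,
    chain_du: float = 1.0,
) -> tuple[EnergyBreakdown, np.ndarray, np.ndarray]:
    """Total snake energy and its exact analytic gradient."""
    e1, e2, g_r, g_a = _internal_energy_grad(
        rings, apex, params.alpha, params.beta, chain_du
    )

    e_ext = 0.0
    if ext is not None and params.delta > 0:
        pts = np.vstack([rings.reshape(-1, 3), apex[None, :]])
        vals, grads = ext.value_and_grad(pts)
        e_ext = params.delta * float(vals.sum())
        g_r += params.delta * grads[:-1].reshape(rings.shape)
        g_a += params.delta * grads[-1]

    dr = rings - rings_init
    da = apex - apex_init
    e_init = params.eta * (float((dr**2).sum()) + float((da**2).sum()))
    g_r += 2 * params.eta * dr
    g_a += 2 * params.eta * da

    return EnergyBreakdown(e1, e2, e_ext, e_init), g_r, g_a


def internal_forces(
    mesh: TubeMesh, alpha: float, beta: float, chain_du: float | None = None
) -> np.ndarray:
    """Internal-energy gradient per vertex, shape (M*N + 1, 3).

    Row order matches :attr:`TubeMesh.vertices` (rings flattened ring-major,
    apex last).  The descent force is the negative of this gradient.
    ``chain_du`` defaults to the mesh's own arc-length-uniform parameter step
    (see :func:`chain_parameter_spacing`).
    """
    if chain_du is None:
        chain_du = chain_parameter_spacing(mesh)
    _, _, g_r, g_a = _internal_energy_grad(mesh.rings, mesh.apex, alpha, beta, chain_du)
    return np.vstack([g_r.reshape(-1, 3), g_a[None, :]])


@dataclass
class EvolveResult:
    mesh: TubeMesh
    history: list[EnergyBreakdown]
    iterations: int
    converged: bool
    clamped_vertices: int


def evolve(
    mesh_init: TubeMesh,
    vol: Volume | None,
    params: SnakeParams,
    pin_base_plane: bool = False,
    start: TubeMesh | None = None,
) -> EvolveResult:
    """Explicit-Euler descent X <- X - tau * grad E from the initialization mesh.

    Stops when the mean vertex displacement of an iteration falls below
    ``params.tol`` (mm) or at ``params.max_iters``.  Vertices that would leave
    the volume bounds are clamped to the boundary and counted.  With
    ``pin_base_plane`` the basal (last) ring moves only within its z plane;
    by default the base is free and the spatial regularization (eta > 0) is
    what anchors it — hard-pinning the base would mask exactly the axial
    LV-to-LA drift the regularization term exists to prevent, so the pin is
    opt-in.  ``vol=None`` runs without external energy (delta is ignored
    then).
    ``mesh_init`` is both the regularization anchor X_init and the starting
    state; pass ``start`` to begin the descent elsewhere (the anchor stays
    ``mesh_init``).
    """
    start = start if start is not None else mesh_init
    if start.rings.shape != mesh_init.rings.shape:
        raise ValueError("start mesh must share the ring grid of mesh_init")
    rings = start.rings.copy()
    apex = start.apex.copy()
    rings0 = mesh_init.rings.copy()
    apex0 = mesh_init.apex.copy()
    chain_du = chain_parameter_spacing(mesh_init)

    ext = external_field(vol, params.sigma_ext) if vol is not None else None
    lo = hi = None
    if vol is not None:
        lo = np.asarray(vol.origin)
        hi = lo + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)

    history: list[EnergyBreakdown] = []
    clamped_total = 0
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        bd, g_r, g_a = energy_and_grad(rings, apex, rings0, apex0, params, ext, chain_du)
        if not np.isfinite(bd.total):
            raise RuntimeError(f"snake energy became non-finite at iteration {it}")
        history.append(bd)
        if pin_base_plane:
            g_r[-1, :, 2] = 0.0
        new_rings = rings - params.step_size * g_r
        new_apex = apex - params.step_size * g_a
        if lo is not None:
            clipped = np.clip(new_rings, lo, hi)
            clamped_total += int((clipped != new_rings).any(axis=-1).sum())
            new_rings = clipped
            new_apex = np.clip(new_apex, lo, hi)
        disp = np.linalg.norm(new_rings - rings, axis=-1).sum() + np.linalg.norm(
            new_apex - apex
        )
        mean_disp = disp / (rings.shape[0] * rings.shape[1] + 1)
        rings, apex = new_rings, new_apex
        if mean_disp < params.tol:
            converged = True
            break

    final = TubeMesh(rings, apex)
    return EvolveResult(final, history, it, converged, clamped_total)


def leak_test(mesh_final: TubeMesh, basal_plane_z: float, slice_spacing: float) -> int:
    """Count vertices that crossed the basal plane by more than one slice.

    The basal plane is where the LV opens into the atrium; vertices more than
    one slice spacing beyond it (toward the atrium, +z) have leaked.
    """
    verts = mesh_final.vertices
    return int((verts[:, 2] > basal_plane_z + slice_spacing).sum())
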