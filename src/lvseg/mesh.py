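"""Tube meshes: stacked contour rings with an apical cap.

The left-ventricular surface is represented as M rings of N vertices each
(ordered apex-to-base along z), plus a single apex vertex closing the apical
end with a triangle fan.  The base is left open — the chamber opens into the
atrium there.  This ring parametrization is what both the geometric
initializer produces and the 3D snake evolves: vertex (r, i) of the deformed
mesh always corresponds to vertex (r, i) of the initialization mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = ["TubeMesh"]


@dataclass
class TubeMesh:
    """Ring-parametrized open-base tube surface in mm coordinates.

    Parameters
    ----------
    rings:
        Array of shape (M, N, 3) — M rings of N vertices, ordered from the
        apical ring (index 0) to the basal ring (index M-1).
    apex:
        Single vertex (3,) capping the apical end.
    """

    rings: np.ndarray
    apex: np.ndarray

    def __post_init__(self) -> None:
        self.rings = np.asarray(self.rings, dtype=float)
        self.apex = np.asarray(self.apex, dtype=float)
        if self.rings.ndim != 3 or self.rings.shape[2] != 3:
            raise ValueError(f"rings must have shape (M, N, 3), got {self.rings.shape}")
        if self.rings.shape[0] < 2:
            raise ValueError("need at least 2 rings")
        if self.apex.shape != (3,):
            raise ValueError("apex must be a single 3-vector")

    @property
    def n_rings(self) -> int:
        return self.rings.shape[0]

    @property
    def points_per_ring(self) -> int:
        return self.rings.shape[1]

    @property
    def vertices(self) -> np.ndarray:
        """All vertices, rings flattened ring-major then the apex last; (M*N+1, 3)."""
        return np.vstack([self.rings.reshape(-1, 3), self.apex[None, :]])

    @property
    def faces(self) -> np.ndarray:
        """Triangle index triplets: 2N per inter-ring band plus the N-fan apex cap.

        Winding is consistent: every interior edge is used once in each
        direction, so the surface is an oriented 2-manifold with the topology
        of a disc (open base).
        """
        m, n = self.rings.shape[:2]
        apex_idx = m * n
        faces = []
        for r in range(m - 1):
            a = r * n + np.arange(n)
            b = r * n + (np.arange(n) + 1) % n
            c = (r + 1) * n + np.arange(n)
            d = (r + 1) * n + (np.arange(n) + 1) % n
            faces.append(np.stack([a, b, c], axis=1))
            faces.append(np.stack([b, d, c], axis=1))
        # apex fan onto ring 0 (apical ring)
        a = np.arange(n)
        b = (np.arange(n) + 1) % n
        faces.append(np.stack([b, a, np.full(n, apex_idx)], axis=1))
        return np.concatenate(faces, axis=0)

    def copy(self) -> "TubeMesh":
        return TubeMesh(self.rings.copy(), self.apex.copy())

    def ring_centers(self) -> np.ndarray:
        """Mean vertex of each ring, shape (M, 3)."""
        return self.rings.mean(axis=1)

    def ring_radii(self) -> np.ndarray:
        """Mean in-plane (x, y) distance of each ring's vertices to its center."""
        centers = self.ring_centers()[:, None, :2]
        return np.linalg.norm(self.rings[:, :, :2] - centers, axis=2).mean(axis=1)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def save_ply(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_trimesh().export(str(path), encoding="ascii")
        return path

    @classmethod
    def from_ring_grid(cls, rings: np.ndarray, apex: np.ndarray) -> "TubeMesh":
        return cls(np.asarray(rings, dtype=float), np.asarray(apex, dtype=float))

    @classmethod
    def load_ply(cls, path: str | Path, points_per_ring: int) -> "TubeMesh":
        """Rebuild the ring structure from a PLY written by :meth:`save_ply`.

        Relies on the vertex ordering contract (ring-major, apex last).
        """
        tm = trimesh.load(str(path), process=False)
        verts = np.asarray(tm.vertices, dtype=float)
        n = points_per_ring
        if (len(verts) - 1) % n != 0:
            raise ValueError(
                f"vertex count {len(verts)} incompatible with {n} points per ring"
            )
        m = (len(verts) - 1) // n
        return cls(verts[:-1].reshape(m, n, 3), verts[-1])
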