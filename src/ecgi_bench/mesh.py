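"""Triangulated surface meshes for torso-tank style geometries.

All coordinates are millimetres.  Meshes are closed, consistently outward
oriented triangle surfaces; the epicardial surface is an icosphere and the
torso an anisotropically scaled icosphere, mirroring the concentric
heart-in-tank arrangement of experimental ECGI preparations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class MeshError(ValueError):
    """Raised when a surface violates closedness/orientation requirements."""


@dataclass
class SurfaceMesh:
    """A closed, orientable triangulated surface.

    Parameters
    ----------
    nodes
        ``(N, 3)`` float array of vertex coordinates in mm.
    triangles
        ``(F, 3)`` int array of vertex indices with consistent
        (outward) winding.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    _adjacency: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (F, 3) array")
        if self.triangles.size and self.triangles.max() >= len(self.nodes):
            raise MeshError("triangle index out of range")

    # -- basic quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_coords(self) -> np.ndarray:
        """``(F, 3, 3)`` coordinates of each triangle's vertices."""
        return self.nodes[self.triangles]

    def triangle_areas(self) -> np.ndarray:
        t = self.triangle_coords()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=-1
        )

    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=-1)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def adjacency(self) -> list[np.ndarray]:
        """1-ring neighbour indices for every node."""
        if self._adjacency is None:
            nbrs: list[set] = [set() for _ in range(self.n_nodes)]
            for a, b in self.edges():
                nbrs[a].add(b)
                nbrs[b].add(a)
            self._adjacency = [np.array(sorted(s), dtype=np.int64) for s in nbrs]
        return self._adjacency

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check closedness, consistent winding and non-degeneracy."""
        directed = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        und = np.sort(directed, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise MeshError("surface is not closed: edges not shared by exactly 2 triangles")
        # consistent winding: every directed edge appears exactly once
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        if not np.all(dcounts == 1):
            raise MeshError("inconsistent triangle winding")
        if np.any(self.triangle_areas() < 1e-12):
            raise MeshError("degenerate (zero-area) triangle present")

    def is_closed(self) -> bool:
        try:
            self.validate()
        except MeshError:
            return False
        return True

    # -- conversions & IO -------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.nodes.copy(), self.triangles.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))

    def save(self, path: str | Path) -> None:
        """Write as OFF or PLY (by extension)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceMesh":
        m = trimesh.load_mesh(str(path), process=False)
        return cls.from_trimesh(m)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigid-body transform (3x3 rotation + translation)."""
        return SurfaceMesh(self.nodes @ np.asarray(rotation).T + translation, self.triangles)


@dataclass
class ActivationMap:
    """Per-node activation times (ms) over a surface."""

    times_ms: np.ndarray
    mesh: SurfaceMesh | None = None
    pacing_site_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if not np.all(np.isfinite(self.times_ms)):
            raise ValueError("activation times must be finite")

    @property
    def earliest_node(self) -> int:
        return int(np.argmin(self.times_ms))


def icosphere(subdivisions: int, radius: float) -> SurfaceMesh:
    """Icosahedron-based sphere: ``10 * 4**n + 2`` nodes at level n."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    return SurfaceMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    )


def contains_points(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Inside test for a closed outward-oriented surface via the Gauss
    solid-angle theorem (sum 4*pi inside, 0 outside)."""
    from .bem import solid_angles  # deferred: bem imports this module

    total = solid_angles(mesh.triangle_coords(), np.asarray(points, dtype=float)).sum(axis=1)
    return total > 2 * np.pi


def generate_concentric_meshes(
    epi_subdivisions: int,
    torso_subdivisions: int,
    epi_radius_mm: float,
    torso_radii_mm: tuple[float, float, float],
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Concentric epicardial sphere inside an ellipsoidal torso surface.

    The torso is an icosphere scaled anisotropically to the three semi-axes
    (mm), emulating a heart suspended in a human-shaped tank.  Raises
    ``MeshError`` if the torso does not strictly enclose the epicardium.
    """
    if epi_subdivisions < 1 or torso_subdivisions < 1:
        raise ValueError("subdivision level must be >= 1")
    epi = icosphere(epi_subdivisions, epi_radius_mm)
    torso = icosphere(torso_subdivisions, 1.0)
    torso = SurfaceMesh(torso.nodes * np.asarray(torso_radii_mm, dtype=float), torso.triangles)
    # containment: every epi node strictly inside the torso surface
    inside = contains_points(torso, epi.nodes)
    if not np.all(inside):
        n_out = int(np.sum(~inside))
        raise MeshError(
            f"epicardial surface not enclosed by torso: {n_out}/{epi.n_nodes} "
            f"nodes outside (epi radius {epi_radius_mm} mm vs torso semi-axes "
            f"{tuple(torso_radii_mm)} mm)"
        )
    return epi, torso


def refine_mesh(mesh: SurfaceMesh, target_edge_mm: float) -> SurfaceMesh:
    """Midpoint-subdivide until the mean edge length is <= target.

    Preserves closedness and winding; returns the input unchanged when the
    target is already met.
    """
    mesh.validate()
    current = mesh
    while current.mean_edge_length() > target_edge_mm:
        current = _midpoint_subdivide(current)
    return current


def _midpoint_subdivide(mesh: SurfaceMesh) -> SurfaceMesh:
    nodes = list(mesh.nodes)
    midpoint: dict[tuple[int, int], int] = {}

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in midpoint:
            nodes.append(0.5 * (mesh.nodes[a] + mesh.nodes[b]))
            midpoint[key] = len(nodes) - 1
        return midpoint[key]

    tris = []
    for i, j, k in mesh.triangles:
        ij, jk, ki = mid(i, j), mid(j, k), mid(k, i)
        tris += [[i, ij, ki], [ij, j, jk], [ki, jk, k], [ij, jk, ki]]
    return SurfaceMesh(np.array(nodes), np.array(tris))
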