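"""Boundary-element forward model for the heart-in-tank volume conductor.

The potential transfer matrix ``A`` maps epicardial node potentials to
torso-surface node potentials for a homogeneous medium bounded externally
by the torso (insulated: zero normal current) and internally by the
epicardium.  Discretization is collocation at mesh vertices with
mass-lumped linear interpolation over triangles: double-layer coefficients
come from signed triangle solid angles (van Oosterom-Strackee formula) and
single-layer coefficients from the analytic integral of 1/r over a plane
triangle, each distributed 1/3 per vertex.

The diagonal of each double-layer self-block is set by the row-sum closure
("auto solid angle"), which makes constant-potential transfer exact: row
sums of ``A`` equal 1 to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.io

from .mesh import SurfaceMesh
from .recording import PotentialRecording


class SingularSystemError(np.linalg.LinAlgError):
    """Torso-block system singular beyond deflation."""


@dataclass
class ForwardModel:
    """Transfer matrix ``A`` (M torso leads x N epicardial nodes)."""

    A: np.ndarray
    source_mesh: SurfaceMesh | None = None
    measurement_mesh: SurfaceMesh | None = None
    electrode_rows: np.ndarray | None = None  # measurement-node indices per row
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A has non-finite entries")

    @property
    def n_measurements(self) -> int:
        return self.A.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]

    def save_matrix(self, path: str | Path) -> None:
        """Write A in Matrix Market format."""
        scipy.io.mmwrite(str(path), self.A)

    @classmethod
    def load_matrix(cls, path: str | Path) -> "ForwardModel":
        A = scipy.io.mmread(str(path))
        if hasattr(A, "toarray"):
            A = A.toarray()
        return cls(np.asarray(A))


def solid_angle(triangle: np.ndarray, point: np.ndarray, plane_tol: float = 1e-12) -> float:
    """Signed solid angle (steradians) of one triangle seen from one point.

    Sign follows the triangle winding: a closed outward-oriented surface
    sums to 4*pi for interior points and 0 for exterior points.  A point in
    the triangle's plane (within tolerance, relative to the triangle scale)
    returns 0 with a degeneracy warning.
    """
    tri = np.asarray(triangle, dtype=float)
    p = np.asarray(point, dtype=float)
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    scale = np.linalg.norm(n)
    if scale > 0:
        h = abs(np.dot(n / scale, p - tri[0]))
        if h < plane_tol * max(1.0, np.sqrt(scale)):
            warnings.warn("observation point lies in the triangle plane; solid angle set to 0")
            return 0.0
    return float(solid_angles(tri[None, :, :], p[None, :])[0, 0])


def solid_angles(tri_xyz: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Signed solid angles, vectorized: (P, F) for F triangles, P points."""
    r1 = tri_xyz[None, :, 0, :] - points[:, None, :]
    r2 = tri_xyz[None, :, 1, :] - points[:, None, :]
    r3 = tri_xyz[None, :, 2, :] - points[:, None, :]
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    n3 = np.linalg.norm(r3, axis=-1)
    num = np.einsum("pfi,pfi->pf", r1, np.cross(r2, r3))
    den = (
        n1 * n2 * n3
        + np.einsum("pfi,pfi->pf", r1, r2) * n3
        + np.einsum("pfi,pfi->pf", r1, r3) * n2
        + np.einsum("pfi,pfi->pf", r2, r3) * n1
    )
    return 2.0 * np.arctan2(num, den)


def single_layer_integrals(tri_xyz: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Analytic integral of 1/r over each plane triangle from each point.

    Edge-log closed form plus the solid-angle height term; finite (the
    integrand's singularity is integrable) even when the point lies on the
    triangle, so vertex collocation on the same surface is well defined.
    Returns (P, F).
    """
    v0, v1, v2 = tri_xyz[:, 0], tri_xyz[:, 1], tri_xyz[:, 2]
    n = np.cross(v1 - v0, v2 - v0)
    area2 = np.linalg.norm(n, axis=-1)
    nhat = n / area2[:, None]
    h = np.einsum("fi,pfi->pf", nhat, points[:, None, :] - v0[None])
    # signed plane-triangle solid angle always opposes the height sign,
    # so h * omega == -|h| * |omega|
    out = h * solid_angles(tri_xyz, points)
    verts = [v0, v1, v2]
    for e in range(3):
        a, b = verts[e], verts[(e + 1) % 3]
        t = b - a
        length = np.linalg.norm(t, axis=-1)
        that = t / length[:, None]
        m = np.cross(that, nhat)
        c = verts[(e + 2) % 3]
        sgn = np.sign(np.einsum("fi,fi->f", m, a - c))
        m = m * sgn[:, None]
        pa = a[None] - points[:, None, :]
        pb = b[None] - points[:, None, :]
        Ra = np.linalg.norm(pa, axis=-1)
        Rb = np.linalg.norm(pb, axis=-1)
        sa = np.einsum("pfi,fi->pf", pa, that)
        sb = np.einsum("pfi,fi->pf", pb, that)
        t0 = np.einsum("pfi,fi->pf", pa, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.log((Rb + sb) / (Ra + sa))
        lg = np.where(np.abs(t0) < 1e-12 * length[None], 0.0, np.nan_to_num(lg, posinf=0.0, neginf=0.0))
        out = out + t0 * lg
    return out


def _lumped_block(src: SurfaceMesh, per_triangle: np.ndarray) -> np.ndarray:
    """Distribute per-triangle coefficients 1/3 to each triangle vertex."""
    out = np.zeros((per_triangle.shape[0], src.n_nodes))
    for c in range(3):
        np.add.at(out.T, src.triangles[:, c], per_triangle.T / 3.0)
    return out


def build_transfer_matrix(
    epi: SurfaceMesh,
    torso: SurfaceMesh,
    deflate: bool | str = "auto",
    cond_limit: float = 1e12,
) -> ForwardModel:
    """Assemble the epicardium-to-torso potential transfer matrix.

    Green's-identity collocation on both surfaces; the epicardial normal
    gradient is eliminated through the epicardial single-layer block,
    leaving ``W phi_torso = Mr phi_epi``.  If the torso-side system is
    rank-deficient, rank-1 deflation (a constant 1/M added to the torso
    self-block) is applied; a system singular beyond deflation raises
    ``SingularSystemError`` with a conditioning report.
    """
    from .mesh import contains_points

    for m in (epi, torso):
        m.validate()
    if not np.all(contains_points(torso, epi.nodes)):
        raise ValueError("torso surface must enclose the epicardial surface")

    tri_e = epi.triangle_coords()
    tri_t = torso.triangle_coords()
    pts_e, pts_t = epi.nodes, torso.nodes
    four_pi = 4 * np.pi

    D_BB = _lumped_block(torso, solid_angles(tri_t, pts_t) / four_pi)
    D_BH = _lumped_block(epi, solid_angles(tri_e, pts_t) / four_pi)
    D_HB = _lumped_block(torso, solid_angles(tri_t, pts_e) / four_pi)
    D_HH = _lumped_block(epi, solid_angles(tri_e, pts_e) / four_pi)
    S_BH = _lumped_block(epi, single_layer_integrals(tri_e, pts_t) / four_pi)
    S_HH = _lumped_block(epi, single_layer_integrals(tri_e, pts_e) / four_pi)

    # auto-diagonal row-sum closure: constant potentials transfer exactly
    P_BB = D_BB.copy()
    P_BB[np.diag_indices_from(P_BB)] -= P_BB.sum(axis=1) + D_BH.sum(axis=1)
    P_HH = D_HH.copy()
    P_HH[np.diag_indices_from(P_HH)] -= P_HH.sum(axis=1) + D_HB.sum(axis=1)

    G = np.linalg.solve(S_HH, np.hstack([D_HB, P_HH]))
    G_HB, G_HH = G[:, : torso.n_nodes], G[:, torso.n_nodes :]
    W = P_BB - S_BH @ G_HB
    Mr = S_BH @ G_HH - D_BH

    conds = [np.linalg.cond(W)]
    if deflate is True or (deflate == "auto" and conds[0] > cond_limit):
        W = W + np.ones_like(W) / W.shape[0]
        conds.append(np.linalg.cond(W))
    if conds[-1] > cond_limit:
        raise SingularSystemError(
            f"torso-block system singular beyond deflation (cond={conds})"
        )
    A = np.linalg.solve(W, Mr)
    return ForwardModel(
        A,
        source_mesh=epi,
        measurement_mesh=torso,
        metadata={"conductivity_ohm_cm": 500.0, "cond_W": conds[-1], "deflated": len(conds) > 1},
    )


def sample_electrode_rows(forward: ForwardModel, electrode_nodes) -> ForwardModel:
    """Reduce A to the rows of the given measurement nodes, in order."""
    idx = np.asarray(electrode_nodes, dtype=np.int64)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate electrode indices")
    if idx.size and (idx.min() < 0 or idx.max() >= forward.n_measurements):
        raise ValueError("electrode index out of range")
    return replace(forward, A=forward.A[idx].copy(), electrode_rows=idx)


def exclude_bad_leads(
    recording: PotentialRecording, forward: ForwardModel, bad
) -> tuple[PotentialRecording, ForwardModel]:
    """Drop poor-quality torso leads consistently from the recording and A.

    Removal leaving fewer torso leads than epicardial sources is allowed
    but flagged with an under-determined warning.
    """
    bad = np.asarray(bad, dtype=np.int64)
    if recording.n_leads != forward.n_measurements:
        raise ValueError("recording leads and forward rows differ")
    if bad.size and (bad.min() < 0 or bad.max() >= recording.n_leads):
        raise ValueError("bad-lead index out of range")
    keep = np.setdiff1d(np.arange(recording.n_leads), bad)
    if keep.size < forward.n_sources:
        warnings.warn(
            f"lead exclusion leaves {keep.size} torso leads for {forward.n_sources} "
            "epicardial sources: system is under-determined"
        )
    rec = PotentialRecording(
        recording.values[keep].copy(),
        recording.fs_hz,
        [recording.lead_ids[i] for i in keep],
        recording.bad_leads[keep].copy(),
        recording.segmentation,
        recording.line_freq_hz,
    )
    fwd = replace(forward, A=forward.A[keep].copy(),
                  electrode_rows=None if forward.electrode_rows is None else forward.electrode_rows[keep].copy())
    return rec, fwd


def read_electrode_list(path) -> np.ndarray:
    """One 0-based measurement-node index per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return np.array([int(ln) for ln in lines if ln], dtype=np.int64)


def write_electrode_list(path, indices) -> None:
    Path(path).write_text("\n".join(str(int(i)) for i in indices) + "\n")
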