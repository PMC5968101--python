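"""Triangulated-surface utilities: solid angles, icospheres, mesh I/O.

The boundary-element solver needs signed solid angles of mesh triangles seen
from collocation points; these are computed with the van Oosterom-Strackee
formula, vectorized over triangles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

__all__ = ["triangle_solid_angles", "icosphere", "load_mesh", "save_mesh"]


def triangle_solid_angles(obs: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Signed solid angles of triangles seen from observation points.

    Parameters
    ----------
    obs : (n_obs, 3)
    tri : (n_tri, 3, 3) triangle vertices in face order.

    Returns
    -------
    (n_obs, n_tri) array; positive when the triangle's oriented normal faces
    away from the observer (outward-oriented closed surfaces sum to 4*pi from
    interior points, 0 from exterior points).
    """
    obs = np.asarray(obs, dtype=float)
    tri = np.asarray(tri, dtype=float)
    # r_k: (n_obs, n_tri, 3)
    r1 = tri[None, :, 0, :] - obs[:, None, :]
    r2 = tri[None, :, 1, :] - obs[:, None, :]
    r3 = tri[None, :, 2, :] - obs[:, None, :]
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    n3 = np.linalg.norm(r3, axis=-1)
    num = np.einsum("otk,otk->ot", r1, np.cross(r2, r3))
    den = (
        n1 * n2 * n3
        + np.einsum("otk,otk->ot", r1, r2) * n3
        + np.einsum("otk,otk->ot", r1, r3) * n2
        + np.einsum("otk,otk->ot", r2, r3) * n1
    )
    return 2.0 * np.arctan2(num, den)


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> trimesh.Trimesh:
    """Geodesic sphere mesh (42, 162, 642, 2562... vertices)."""
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Read an OFF or ASCII-PLY triangulated surface."""
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangulated surface")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write OFF or ASCII-PLY depending on the file extension."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    elif path.suffix.lower() == ".off":
        path.write_text(trimesh.exchange.off.export_off(mesh))
    else:
        raise ValueError("mesh format must be .off or .ply")
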