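"""Surface boundary-element EEG forward model.

Double-layer collocation BEM on nested closed triangulated surfaces
(innermost first, e.g. cortex / inner skull / outer skull / scalp).  Each
vertex carries one potential value; the solid angle subtended by a triangle
at a collocation vertex is distributed equally to the triangle's vertices.
The exterior Neumann problem has a rank-1 null space (a global potential
offset), removed by Lynn-Timlake deflation before the dense solve.

Triangles containing the collocation vertex subtend zero solid angle from a
point in their own plane, so the own-surface diagonal deficit equals the
interior vertex solid angle; no ad hoc auto-element correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import trimesh

from ..errors import GeometryError, ModelError
from .geometry import triangle_solid_angles
from .leadfield import LeadField
from .montage import Montage, SourceSpace

__all__ = ["SurfaceSet", "bem_leadfield"]

logger = logging.getLogger(__name__)

_MM = 1e-3
_NAM = 1e-9
_UV = 1e6

_CHUNK = 256  # observation vertices per solid-angle block


@dataclass
class SurfaceSet:
    """Nested closed surfaces with per-compartment conductivities (S/m).

    ``surfaces`` is ordered innermost to outermost; ``conductivities[j]`` is
    the conductivity of the compartment bounded by ``surfaces[j]`` (outside
    the outermost surface is non-conducting air).
    """

    surfaces: list[trimesh.Trimesh]
    conductivities: np.ndarray

    def __post_init__(self) -> None:
        self.conductivities = np.asarray(self.conductivities, dtype=float).reshape(-1)
        if len(self.surfaces) != self.conductivities.size:
            raise ModelError("need one conductivity per surface compartment")
        if np.any(self.conductivities <= 0):
            raise ModelError("conductivities must be strictly positive")
        for k, mesh in enumerate(self.surfaces):
            if not mesh.is_watertight:
                raise GeometryError(f"surface {k} is not closed")
            if not mesh.is_winding_consistent:
                raise GeometryError(f"surface {k} has inconsistent winding")
            if mesh.volume <= 0:
                raise GeometryError(f"surface {k} normals are not outward")

    @property
    def n_surfaces(self) -> int:
        return len(self.surfaces)

    def scaled(self, factor: float) -> "SurfaceSet":
        """Same geometry with all conductivities multiplied by ``factor``."""
        return SurfaceSet(self.surfaces, self.conductivities * factor)


def _assemble_system(surfaces: SurfaceSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the deflated collocation matrix.

    Returns (A, all_vertices, vertex_surface_index).  A includes the
    half-jump diagonal, the weighted double-layer operator, and the
    deflation term.
    """
    meshes = surfaces.surfaces
    sig = surfaces.conductivities
    m = len(meshes)
    sig_in = sig
    sig_out = np.append(sig[1:], 0.0)

    verts = [np.asarray(mesh.vertices, dtype=float) * _MM for mesh in meshes]
    n_per = [v.shape[0] for v in verts]
    offsets = np.concatenate([[0], np.cumsum(n_per)])
    n_total = offsets[-1]
    all_verts = np.vstack(verts)
    vert_surf = np.concatenate([np.full(n, k, dtype=int) for k, n in enumerate(n_per)])

    # triangle vertex coordinates and sparse (tri -> vertex, weight 1/3) maps
    tris = []
    weights = []
    tri_surf = []
    for k, mesh in enumerate(meshes):
        faces = np.asarray(mesh.faces, dtype=int)
        tris.append(verts[k][faces])
        nt = faces.shape[0]
        rows = np.repeat(np.arange(nt), 3)
        cols = (faces + offsets[k]).ravel()
        w = scipy.sparse.csr_matrix(
            (np.full(3 * nt, 1.0 / 3.0), (rows, cols)), shape=(nt, n_total)
        )
        weights.append(w)
        tri_surf.append(np.full(nt, k, dtype=int))
    all_tris = np.vstack(tris)
    tri_surf = np.concatenate(tri_surf)
    W = scipy.sparse.vstack(weights).tocsc()

    # per-triangle multiplier: -(sigma_in - sigma_out)/(4 pi) of the
    # triangle's surface
    tri_factor = -(sig_in[tri_surf] - sig_out[tri_surf]) / (4.0 * np.pi)

    A = np.empty((n_total, n_total))
    nesting_sums = np.zeros((n_total, m))
    for start in range(0, n_total, _CHUNK):
        stop = min(start + _CHUNK, n_total)
        omega = triangle_solid_angles(all_verts[start:stop], all_tris)
        for k in range(m):
            nesting_sums[start:stop, k] = omega[:, tri_surf == k].sum(axis=1)
        A[start:stop, :] = (omega * tri_factor[None, :]) @ W

    # nesting check reuses the solid-angle closure: a surface enclosing the
    # observation vertex subtends 4*pi, an enclosed one 0
    for k in range(m):
        for l in range(m):
            sums = nesting_sums[vert_surf == k, l]
            if l > k and not np.allclose(sums, 4 * np.pi, atol=1e-6):
                raise GeometryError(f"surface {l} does not enclose surface {k}")
            if l < k and not np.allclose(sums, 0.0, atol=1e-6):
                raise GeometryError(f"surface {l} is not inside surface {k}")

    diag = 0.5 * (sig_in + sig_out)[vert_surf]
    A[np.arange(n_total), np.arange(n_total)] += diag

    # Lynn-Timlake deflation of the constant null vector
    scale = float(np.mean(sig))
    A += scale / n_total
    return A, all_verts, vert_surf


def _infinite_medium_potential(verts: np.ndarray, r0: np.ndarray) -> np.ndarray:
    """sigma*V_inf rows for the three unit moments: (n_verts, 3), SI."""
    d = verts - r0[None, :]
    dist3 = np.linalg.norm(d, axis=1) ** 3
    return _NAM * d / (4.0 * np.pi * dist3[:, None])


def bem_leadfield(
    surfaces: SurfaceSet,
    montage: Montage,
    sources: SourceSpace,
    snap_tol_mm: float = 2.0,
) -> LeadField:
    """Lead field (uV per nA*m) from a double-layer collocation BEM.

    Electrodes are snapped to the nearest scalp vertex; a snap farther than
    ``snap_tol_mm`` raises a geometry error.
    """
    src_mm = np.atleast_2d(sources.positions)
    inner = surfaces.surfaces[0]
    # winding-number containment: a closed outward surface subtends 4*pi
    # from interior points
    tri = np.asarray(inner.vertices, dtype=float)[np.asarray(inner.faces)]
    total = triangle_solid_angles(src_mm, tri).sum(axis=1)
    if not np.allclose(total, 4 * np.pi, atol=1e-6):
        raise GeometryError("sources must lie inside the innermost surface")

    A, all_verts, vert_surf = _assemble_system(surfaces)
    lu = scipy.linalg.lu_factor(A, overwrite_a=True)

    src = src_mm * _MM
    n_src = src.shape[0]
    n_total = all_verts.shape[0]
    b = np.empty((n_total, 3 * n_src))
    for i in range(n_src):
        b[:, 3 * i : 3 * i + 3] = _infinite_medium_potential(all_verts, src[i])
    v_all = scipy.linalg.lu_solve(lu, b) * _UV

    # electrode extraction: nearest scalp vertex
    scalp_idx = np.where(vert_surf == surfaces.n_surfaces - 1)[0]
    scalp = all_verts[scalp_idx] / _MM
    elec = montage.positions
    d2 = ((elec[:, None, :] - scalp[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    snap = np.sqrt(d2[np.arange(len(elec)), nearest])
    if snap.max() > snap_tol_mm:
        raise GeometryError(
            f"electrode snap distance {snap.max():.2f} mm exceeds {snap_tol_mm} mm"
        )
    logger.info("electrode snap distances: max %.3f mm", snap.max())

    gain = v_all[scalp_idx[nearest], :]
    lf = LeadField(gain, n_src, orientation="free", referenced=False)
    if sources.fixed_orientation:
        lf = lf.fix_orientation(sources.orientations)
    return lf
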