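"""Analytic multi-shell concentric-sphere EEG forward model.

The potential of a current dipole inside nested conducting spherical shells
(air outside) is expanded in Legendre harmonics.  Per harmonic degree n the
radial profile in each shell is ``A r^n + B r^-(n+1)``; coefficients are
propagated across shell interfaces by enforcing continuity of potential and
of radial current density, and the outer boundary carries zero normal
current.  The series is truncated adaptively once terms stop contributing.

For equal shell conductivities the model collapses to the classical
homogeneous-sphere solution, which serves as an independent closed-form
oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import GeometryError, ModelError
from .leadfield import LeadField
from .montage import Montage, SourceSpace

__all__ = ["SphereModel", "sphere_leadfield"]

# fixed package units: mm, S/m, nA*m, uV
_MM = 1e-3
_NAM = 1e-9
_UV = 1e6


@dataclass
class SphereModel:
    """Concentric-shell sphere head model.

    Parameters
    ----------
    center : 3-vector, mm
    radii : ascending shell radii, mm (innermost first, scalp last)
    conductivities : per-shell values, S/m (innermost first)
    series_terms : maximum Legendre degree; the series stops early once the
        running contribution falls below ``tol`` of the accumulated value.
    tol : relative early-stop tolerance.
    """

    center: np.ndarray
    radii: np.ndarray
    conductivities: np.ndarray
    series_terms: int = 200
    tol: float = 1e-12

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.conductivities = np.asarray(self.conductivities, dtype=float).reshape(-1)
        if self.radii.size < 1 or np.any(np.diff(self.radii) <= 0):
            raise ModelError("shell radii must be strictly increasing")
        if np.any(self.radii <= 0):
            raise ModelError("shell radii must be positive")
        if self.conductivities.size != self.radii.size:
            raise ModelError("need one conductivity per shell")
        if np.any(self.conductivities <= 0):
            raise ModelError("conductivities must be strictly positive")
        if self.series_terms < 1:
            raise ModelError("series_terms must be >= 1")

    @property
    def n_shells(self) -> int:
        return self.radii.size


def _harmonic_surface_coeffs(model: SphereModel, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Surface value of the harmonic-n radial profile, per unit source strength.

    Returns ``(v_rad, v_tan)`` arrays over n = 1..n_max where the layer-1
    primary field is ``s * r^-(n+1)`` with s = n*b^(n-1) (radial moment) or
    b^(n-1) (tangential moment), radii normalized by the outer radius.
    """
    sig = model.conductivities
    rad = model.radii / model.radii[-1]
    m = model.n_shells
    ns = np.arange(1, n_max + 1, dtype=float)

    # propagate (A, B) with A1 = 1, B1 = 0 and A1 = 0, B1 = 1 to build the
    # 2x2 transfer map per degree n
    A = np.stack([np.ones_like(ns), np.zeros_like(ns)])  # two basis starts
    B = np.stack([np.zeros_like(ns), np.ones_like(ns)])
    for j in range(m - 1):
        r = rad[j]
        k = sig[j] / sig[j + 1]
        c1 = A * r**ns + B * r ** -(ns + 1)
        c2 = k * (ns * A * r ** (ns - 1) - (ns + 1) * B * r ** -(ns + 2))
        B = (ns * c1 / r - c2) * r ** (ns + 2) / (2 * ns + 1)
        A = (c1 - B * r ** -(ns + 1)) / r**ns
    M11, M21 = A[0], B[0]
    M12, M22 = A[1], B[1]

    # outer boundary (normalized outer radius = 1, air outside):
    # n*A_N = (n+1)*B_N  =>  solve for A1 given B1 = s
    denom = (ns + 1) * M21 - ns * M11
    if np.any(np.abs(denom) < 1e-300):
        raise ModelError("degenerate shell system in sphere model")
    a1_per_s = (ns * M12 - (ns + 1) * M22) / denom
    a_out = M11 * a1_per_s + M12
    b_out = M21 * a1_per_s + M22
    v_per_s = a_out + b_out  # A_N * 1^n + B_N * 1^-(n+1)
    return ns, v_per_s


def sphere_leadfield(
    model: SphereModel, montage: Montage, sources: SourceSpace
) -> LeadField:
    """Lead field of the multi-shell sphere model (uV per nA*m).

    Sources must lie strictly inside the innermost shell; electrodes must sit
    on the outer shell within 5% of its radius (they are used through their
    radial direction only).
    """
    elec = montage.positions - model.center
    src = sources.positions - model.center
    r_out = model.radii[-1]
    r_in = model.radii[0]

    e_norm = np.linalg.norm(elec, axis=1)
    if np.any(np.abs(e_norm - r_out) > 0.05 * r_out):
        raise GeometryError("electrodes must lie on the outer shell (5% tolerance)")
    s_norm = np.linalg.norm(src, axis=1)
    if np.any(s_norm >= r_in):
        raise GeometryError("sources must lie strictly inside the innermost shell")

    e_hat = elec / e_norm[:, None]
    n_elec, n_src = elec.shape[0], src.shape[0]
    gain = np.zeros((n_elec, 3 * n_src))

    n_max = model.series_terms
    ns, v_per_s = _harmonic_surface_coeffs(model, n_max)
    # prefactor: 1/(4 pi sigma_1 R^2) with R in metres, unit moment 1 nA*m,
    # output in microvolts
    pref = _NAM * _UV / (4 * np.pi * model.conductivities[0] * (r_out * _MM) ** 2)

    for i_src in range(n_src):
        b_vec = src[i_src]
        b = s_norm[i_src]
        f = b / r_out
        if b < 1e-12 * r_out:
            b_hat = np.array([0.0, 0.0, 1.0])
            f = 0.0
        else:
            b_hat = b_vec / b

        x = np.clip(e_hat @ b_hat, -1.0, 1.0)
        # Legendre recurrences: P_n(x) and P_n'(x)
        p_prev = np.ones_like(x)   # P_0
        p_cur = x.copy()           # P_1
        dp_prev = np.zeros_like(x)  # P_0'
        dp_cur = np.ones_like(x)   # P_1'

        # moment basis: unit dipoles along x, y, z
        q_r = np.eye(3) @ b_hat                      # radial components
        p_t = np.eye(3) - np.outer(q_r, b_hat)       # tangential vectors
        t_proj = e_hat @ p_t.T                       # (n_elec, 3): e_hat . p_t

        acc = np.zeros((n_elec, 3))
        running = 0.0
        f_pow = 1.0  # f^(n-1)
        quiet = 0
        for idx, n in enumerate(ns):
            v = v_per_s[idx]
            term = (
                v * n * f_pow * np.outer(p_cur, q_r)
                + v * f_pow * dp_cur[:, None] * t_proj
            )
            acc += term
            tmax = np.abs(term).max()
            running = max(running, np.abs(acc).max())
            if running > 0 and tmax < model.tol * running:
                quiet += 1
                if quiet >= 3:
                    break
            else:
                quiet = 0
            # advance recurrences to degree n+1
            p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
            dp_next = dp_prev + (2 * n + 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            f_pow *= f

        gain[:, 3 * i_src : 3 * i_src + 3] = pref * acc

    lf = LeadField(gain, n_src, orientation="free", referenced=False)
    if sources.fixed_orientation:
        lf = lf.fix_orientation(sources.orientations)
    return lf
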