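"""Forward-model checks: analytic sphere vs closed form, BEM vs sphere,
average referencing, and mesh handling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irritmap.errors import GeometryError, ModelError, ReferenceError_
from irritmap.headmodel import (
    LeadField,
    Montage,
    SourceSpace,
    SphereModel,
    SurfaceSet,
    apply_average_reference,
    bem_leadfield,
    sphere_leadfield,
)
from irritmap.headmodel.geometry import icosphere, load_mesh, save_mesh
from irritmap.recording import Recording

from conftest import RADII_MM, SIGMA, random_interior_sources

MM, NAM, UV = 1e-3, 1e-9, 1e6


def homogeneous_sphere_oracle(elec_mm, r0_mm, p_nam, sigma, r_out_mm):
    """Closed-form dipole potential (uV) in a homogeneous conducting sphere.

    Independent of the package's Legendre-series implementation: the series
    sums in closed form via the generating functions of P_n and P_n'.
    """
    out = np.zeros(len(elec_mm))
    r_si = r_out_mm * MM
    pref = NAM * UV / (4 * np.pi * sigma * r_si**2)
    b = np.linalg.norm(r0_mm)
    for i, e in enumerate(elec_mm):
        r_hat = e / np.linalg.norm(e)
        if b < 1e-12:
            out[i] = pref * 3.0 * (p_nam @ r_hat)
            continue
        b_hat = r0_mm / b
        f = b / r_out_mm
        x = float(np.clip(r_hat @ b_hat, -1.0, 1.0))
        g = np.sqrt(1.0 - 2.0 * f * x + f * f)
        q_r = p_nam @ b_hat
        p_t = p_nam - q_r * b_hat
        radial = 2.0 * (x - f) / g**3 + (1.0 / f) * (1.0 / g - 1.0)
        tangential = 2.0 / g**3 + (1.0 + g) / (g * (1.0 - f * x + g))
        out[i] = pref * (q_r * radial + (r_hat @ p_t) * tangential)
    return out


def rdm_mag(v, w):
    """Shape (RDM) and scale (MAG) discrepancy after average reference."""
    v = v - v.mean()
    w = w - w.mean()
    rdm = np.linalg.norm(v / np.linalg.norm(v) - w / np.linalg.norm(w))
    return rdm, np.linalg.norm(v) / np.linalg.norm(w)


class TestSphereModel:
    def test_matches_closed_form_oracle(self, equal_sigma_sphere, surface_montage):
        """Equal-conductivity shells reproduce the homogeneous-sphere
        closed form to 1e-6 relative error up to eccentricity 0.9."""
        rng = np.random.default_rng(11)
        sources = random_interior_sources(25, 0.9, seed=12)
        lf = sphere_leadfield(equal_sigma_sphere, surface_montage, sources)
        for i in range(sources.n_sources):
            p = rng.normal(size=3)
            v_model = lf.gain[:, 3 * i : 3 * i + 3] @ p
            v_oracle = homogeneous_sphere_oracle(
                surface_montage.positions, sources.positions[i], p, SIGMA,
                RADII_MM[-1],
            )
            rel = np.linalg.norm(v_model - v_oracle) / np.linalg.norm(v_oracle)
            assert rel < 1e-6

    def test_zero_moment_gives_zero_potential(self, equal_sigma_sphere, surface_montage):
        sources = random_interior_sources(3, 0.7, seed=1)
        lf = sphere_leadfield(equal_sigma_sphere, surface_montage, sources)
        assert np.allclose(lf.gain[:, :3] @ np.zeros(3), 0.0)

    def test_linearity_in_moment(self, equal_sigma_sphere, surface_montage):
        sources = random_interior_sources(5, 0.8, seed=3)
        lf = sphere_leadfield(equal_sigma_sphere, surface_montage, sources)
        rng = np.random.default_rng(4)
        for i in range(5):
            g = lf.gain[:, 3 * i : 3 * i + 3]
            p1, p2 = rng.normal(size=3), rng.normal(size=3)
            assert np.allclose(g @ (p1 + p2), g @ p1 + g @ p2, atol=1e-12)

    def test_central_dipole_cosine_profile(self, equal_sigma_sphere, surface_montage):
        """A central dipole's surface potential is proportional to cos(theta)."""
        src = SourceSpace(positions=np.zeros((1, 3)))
        lf = sphere_leadfield(equal_sigma_sphere, surface_montage, src)
        cos_t = surface_montage.positions[:, 2] / RADII_MM[-1]
        ratio = lf.gain[:, 2] / cos_t
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_rotation_invariance(self, equal_sigma_sphere):
        """Rotating dipole and electrodes together leaves potentials fixed."""
        rng = np.random.default_rng(7)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        elec = rng.normal(size=(16, 3))
        elec /= np.linalg.norm(elec, axis=1, keepdims=True)
        elec *= RADII_MM[-1]
        r0 = np.array([2.0, 1.0, -3.0])
        p = np.array([1.0, -2.0, 0.5])
        m1 = Montage([f"E{i}" for i in range(16)], elec)
        m2 = Montage([f"E{i}" for i in range(16)], elec @ rot.T)
        v1 = sphere_leadfield(
            equal_sigma_sphere, m1, SourceSpace(positions=r0[None])
        ).gain[:, :3] @ p
        v2 = sphere_leadfield(
            equal_sigma_sphere, m2, SourceSpace(positions=(rot @ r0)[None])
        ).gain[:, :3] @ (rot @ p)
        assert np.allclose(v1, v2, atol=1e-9 * np.abs(v1).max())

    def test_invalid_geometry_raises(self, equal_sigma_sphere, surface_montage):
        outside = SourceSpace(positions=np.array([[0.0, 0.0, 9.0]]))
        with pytest.raises(GeometryError):
            sphere_leadfield(equal_sigma_sphere, surface_montage, outside)
        with pytest.raises(ModelError):
            SphereModel(np.zeros(3), [10.0, 9.0, 8.0], [SIGMA] * 3)
        with pytest.raises(ModelError):
            SphereModel(np.zeros(3), [8.0, 9.0, 10.0], [SIGMA, -1.0, SIGMA])


@pytest.fixture(scope="module")
def concentric_meshes():
    return [icosphere(2, r) for r in RADII_MM]


class TestBEM:
    def test_agrees_with_analytic_sphere(self, concentric_meshes, equal_sigma_sphere):
        """Collocation BEM on spherical meshes reproduces the analytic
        multi-shell solution in shape and magnitude."""
        cond = np.array([0.33, 0.165, 0.33])
        surf = SurfaceSet(concentric_meshes, cond)
        sphere = SphereModel(np.zeros(3), np.array(RADII_MM), cond)
        scalp = np.asarray(concentric_meshes[-1].vertices)
        rng = np.random.default_rng(21)
        idx = rng.choice(len(scalp), size=32, replace=False)
        montage = Montage([f"E{i}" for i in range(32)], scalp[idx])
        sources = random_interior_sources(6, 0.6, seed=22)
        lf_b = bem_leadfield(surf, montage, sources)
        lf_s = sphere_leadfield(sphere, montage, sources)
        for i in range(sources.n_sources):
            p = rng.normal(size=3)
            rdm, mag = rdm_mag(
                lf_b.gain[:, 3 * i : 3 * i + 3] @ p,
                lf_s.gain[:, 3 * i : 3 * i + 3] @ p,
            )
            assert rdm < 0.08
            assert 0.75 < mag < 1.1

    def test_conductivity_scaling_halves_potentials(self, concentric_meshes):
        """Doubling all conductivities halves all potentials (sigma*V fixed)."""
        cond = np.array([0.33, 0.165, 0.33])
        surf1 = SurfaceSet(concentric_meshes, cond)
        surf2 = surf1.scaled(2.0)
        scalp = np.asarray(concentric_meshes[-1].vertices)
        montage = Montage([f"E{i}" for i in range(16)], scalp[:16])
        sources = random_interior_sources(2, 0.5, seed=30)
        g1 = bem_leadfield(surf1, montage, sources).gain
        g2 = bem_leadfield(surf2, montage, sources).gain
        assert np.allclose(g2, g1 / 2.0, rtol=1e-8)

    def test_source_outside_inner_surface_rejected(self, concentric_meshes):
        surf = SurfaceSet(concentric_meshes, np.array([0.33, 0.165, 0.33]))
        scalp = np.asarray(concentric_meshes[-1].vertices)
        montage = Montage([f"E{i}" for i in range(8)], scalp[:8])
        bad = SourceSpace(positions=np.array([[0.0, 0.0, 8.9]]))
        with pytest.raises(GeometryError):
            bem_leadfield(surf, montage, bad)

    def test_non_nested_surfaces_rejected(self):
        meshes = [icosphere(1, 8.5), icosphere(1, 9.2)]
        shifted = meshes[0].copy()
        shifted.apply_translation([6.0, 0.0, 0.0])  # pokes outside
        with pytest.raises(GeometryError):
            surf = SurfaceSet([shifted, meshes[1]], np.array([0.33, 0.33]))
            montage = Montage(["A", "B", "C"], np.asarray(meshes[1].vertices)[:3])
            bem_leadfield(surf, montage, SourceSpace(positions=np.zeros((1, 3))))


class TestAverageReference:
    def test_two_electrode_mean_subtraction(self):
        rec = Recording(np.array([[3.0], [1.0]]), sampling_rate=1.0)
        ref = apply_average_reference(rec)
        assert np.allclose(ref.data, [[1.0], [-1.0]])

    def test_common_mode_removed(self):
        rec = Recording(np.full((5, 10), 7.3), sampling_rate=1.0)
        assert np.allclose(apply_average_reference(rec).data, 0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(2, 12), st.integers(1, 20), st.integers(0, 10_000))
    def test_idempotent_and_zero_sum(self, n_ch, n_s, seed):
        rng = np.random.default_rng(seed)
        rec = Recording(rng.normal(size=(n_ch, n_s)), sampling_rate=100.0)
        once = apply_average_reference(rec)
        twice = apply_average_reference(once)
        assert np.allclose(once.data.sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(once.data, twice.data)

    def test_leadfield_columns_sum_to_zero(self, equal_sigma_sphere, surface_montage):
        sources = random_interior_sources(4, 0.6, seed=40)
        lf = sphere_leadfield(equal_sigma_sphere, surface_montage, sources)
        ref = apply_average_reference(lf)
        assert ref.referenced
        assert np.abs(ref.gain.sum(axis=0)).max() < 1e-9 * np.abs(ref.gain).max()

    def test_single_electrode_rejected(self):
        rec = Recording(np.ones((1, 5)), sampling_rate=1.0)
        with pytest.raises(ReferenceError_):
            apply_average_reference(rec)


class TestMeshAndLeadFieldIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_mesh_round_trip(self, tmp_path, ext):
        mesh = icosphere(1, 5.0)
        path = tmp_path / f"m.{ext}"
        save_mesh(mesh, path)
        back = load_mesh(path)
        assert np.allclose(np.sort(back.vertices, 0), np.sort(mesh.vertices, 0), atol=1e-5)
        assert back.faces.shape == mesh.faces.shape

    def test_leadfield_round_trip(self, tmp_path):
        gain = np.arange(12.0).reshape(3, 4)
        lf = LeadField(gain, n_sources=4, orientation="fixed")
        lf.save(tmp_path / "lf")
        back = LeadField.load(tmp_path / "lf")
        assert np.array_equal(back.gain, gain)
        assert back.orientation == "fixed" and back.n_sources == 4

    def test_montage_round_trip(self, tmp_path):
        m = Montage(["Fz", "Cz"], np.array([[0.0, 1.0, 2.0], [3.0, 4.0, 5.0]]))
        m.save(tmp_path / "m.txt")
        back = Montage.load(tmp_path / "m.txt")
        assert back.names == m.names
        assert np.allclose(back.positions, m.positions)
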