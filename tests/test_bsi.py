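"""Source imaging: sLORETA, latency, parcel lookup, target selection,
and sectioning arithmetic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irritmap.bsi import (
    Parcellation,
    SectioningPlan,
    atlas_to_specimen,
    default_parcellation,
    localize_subtypes,
    parcel_label,
    select_target,
    shrink_factor,
    sloreta,
    twothirds_latency,
)
from irritmap.errors import (
    ContractError,
    GeometryError,
    LatencyError,
    LookupError_,
    SelectionError,
)
from irritmap.headmodel import LeadField, apply_average_reference
from irritmap.iedclass.cluster import MeanIED


def _dense_sloreta_oracle(g, v, lam_rel):
    """Brute-force sLORETA on a fixed-orientation gain, straight from the
    definition with dense linear algebra."""
    n = g.shape[0]
    ggt = g @ g.T
    lam = lam_rel * np.trace(ggt) / n
    h = np.eye(n) - np.ones((n, n)) / n
    m_inv = np.linalg.pinv(ggt + lam * h)
    j = g.T @ m_inv @ v
    s = g.T @ m_inv @ g
    return j**2 / np.diag(s)


class TestSloreta:
    def test_zero_localization_error_exhaustive(self, study_head):
        """The standardized map peaks at the true source for every source
        in the study space (noiseless, the method's defining property)."""
        lf = study_head.leadfield
        errors = 0
        for i in range(lf.n_sources):
            sm = sloreta(lf, lf.gain[:, i], lambda_rel=1e-6)
            errors += sm.peak_source != i
        assert errors == 0

    def test_zero_topography_gives_zero_power(self, study_head):
        sm = sloreta(study_head.leadfield, np.zeros(32), lambda_rel=1e-4)
        assert np.allclose(sm.power, 0.0)

    def test_matches_dense_oracle_on_hand_built_system(self):
        rng = np.random.default_rng(31)
        g = rng.normal(size=(4, 3))
        g = g - g.mean(axis=0)
        lf = LeadField(g, n_sources=3, orientation="fixed", referenced=True)
        v = g @ np.array([0.0, 2.0, 0.0])
        sm = sloreta(lf, v, lambda_rel=1e-3)
        oracle = _dense_sloreta_oracle(g, v, 1e-3)
        assert np.allclose(sm.power, oracle, rtol=1e-10, atol=1e-12)

    def test_power_argmax_invariant_under_topography_rescaling(self, study_head):
        lf = study_head.leadfield
        topo = lf.gain[:, 17]
        a = sloreta(lf, topo, 1e-3).power
        b = sloreta(lf, 5.0 * topo, 1e-3).power
        assert np.argmax(a) == np.argmax(b)
        assert np.allclose(b, 25.0 * a, rtol=1e-8)

    def test_unreferenced_inputs_rejected(self, study_head):
        lf = study_head.leadfield
        raw = LeadField(lf.gain + 1.0, lf.n_sources, "fixed", referenced=False)
        with pytest.raises(ContractError):
            sloreta(raw, np.zeros(32), 1e-3)
        with pytest.raises(ContractError):
            sloreta(lf, np.ones(32), 1e-3)  # non-zero-mean topography


def _mean_ied(time_course, fs=500.0, kind="spike", n=10):
    return MeanIED(np.asarray(time_course, dtype=float), kind, n, fs, 300.0)


class TestTwoThirdsLatency:
    def test_triangular_gfp_crossing_exact(self):
        """Symmetric triangular GFP peaking at 150 ms with value 3: the
        2/3 crossing (GFP = 2) lies at 100 ms by similar triangles."""
        fs = 1000.0
        n = 301
        peak = 150
        tri = np.minimum(np.arange(n), 2 * peak - np.arange(n)) / peak * 3.0
        tri = np.clip(tri, 0.0, None)
        # two channels +/- the profile: GFP equals |profile|
        mean = _mean_ied(np.vstack([tri, -tri]), fs=fs)
        lat = twothirds_latency(mean)
        assert lat == pytest.approx(100.0, abs=1.0)

    def test_flat_epoch_rejected(self):
        with pytest.raises(LatencyError):
            twothirds_latency(_mean_ied(np.zeros((3, 100))))

    def test_monotone_rise_warns_and_stays_in_window(self, caplog):
        ramp = np.linspace(0, 1, 200)
        mean = _mean_ied(np.vstack([ramp, -ramp]))
        with caplog.at_level("WARNING"):
            lat = twothirds_latency(mean)
        assert 0 <= lat <= 200 / 500.0 * 1000.0

    def test_template_crossing_precedes_peak(self):
        from irritmap.iedsim import make_ied_template

        tpl = make_ied_template("sharp_wave", 120.0, 500.0)
        mean = _mean_ied(np.vstack([tpl.waveform, -tpl.waveform]))
        lat = twothirds_latency(mean)
        assert lat < tpl.peak_index / 500.0 * 1000.0


class TestParcellation:
    @pytest.mark.parametrize(
        "pid,name,hemi",
        [(1, "AID", "right"), (49, "AID", "left"), (79, "S1BF", "left"),
         (19, "M1", "right"), (67, "M1", "left"), (96, "VIEnt", "left")],
    )
    def test_lookup_follows_the_atlas_convention(self, pid, name, hemi):
        assert parcel_label(pid) == (name, hemi)

    def test_contralateral_pairing(self):
        parc = default_parcellation()
        assert parc.contralateral(67) == 19
        assert parc.contralateral(19) == 67
        with pytest.raises(LookupError_):
            parc.contralateral(200)

    def test_unknown_id_rejected(self):
        with pytest.raises(LookupError_):
            parcel_label(0)

    def test_round_trip_csv(self, tmp_path):
        parc = default_parcellation()
        parc.save(tmp_path / "p.csv")
        back = Parcellation.load(tmp_path / "p.csv")
        assert back.table == parc.table


class TestLocalizeAndSelect:
    def test_single_subtype_localizes_to_true_parcel(self, study_head):
        lf = study_head.leadfield
        src = int(study_head.parcellation.sources_in(43)[0])
        from irritmap.iedsim import make_ied_template

        tpl = make_ied_template("spike", 45.0, 500.0)
        course = np.outer(lf.gain[:, src], tpl.waveform)
        mean = _mean_ied(course)
        locs = localize_subtypes(lf, [mean], study_head.parcellation)
        assert locs[0].peak_parcel == 43

    def test_mirrored_sources_give_mirrored_parcels(self, study_head):
        lf = study_head.leadfield
        parc = study_head.parcellation
        right = int(parc.sources_in(20)[0])
        pos = study_head.sources.positions[right]
        mirrored = pos * np.array([-1.0, 1.0, 1.0])
        d = np.linalg.norm(study_head.sources.positions - mirrored, axis=1)
        left = int(np.argmin(d))
        from irritmap.iedsim import make_ied_template

        tpl = make_ied_template("spike", 45.0, 500.0)
        means = [
            _mean_ied(np.outer(lf.gain[:, right], tpl.waveform)),
            _mean_ied(np.outer(lf.gain[:, left], tpl.waveform)),
        ]
        locs = localize_subtypes(lf, means, parc)
        assert parc.contralateral(locs[0].peak_parcel) == locs[1].peak_parcel

    def test_empty_subtype_list(self, study_head):
        assert localize_subtypes(study_head.leadfield, [], study_head.parcellation) == []
        with pytest.raises(SelectionError):
            select_target([], study_head.parcellation)

    def test_single_active_parcel_is_target_with_true_verdict(self, study_head):
        lf = study_head.leadfield
        src = int(study_head.parcellation.sources_in(20)[0])
        from irritmap.iedsim import make_ied_template

        tpl = make_ied_template("spike", 45.0, 500.0)
        mean = _mean_ied(np.outer(lf.gain[:, src], tpl.waveform))
        locs = localize_subtypes(lf, [mean], study_head.parcellation)
        report = select_target(locs, study_head.parcellation)
        assert report.target_parcel == 20
        assert report.control_parcel == 68
        assert report.silence_verdict

    def test_verdict_monotone_in_silence_ratio(self, study_head):
        lf = study_head.leadfield
        src = int(study_head.parcellation.sources_in(43)[0])
        from irritmap.iedsim import make_ied_template

        tpl = make_ied_template("spike", 45.0, 500.0)
        mean = _mean_ied(np.outer(lf.gain[:, src], tpl.waveform))
        locs = localize_subtypes(lf, [mean], study_head.parcellation)
        verdicts = [
            select_target(locs, study_head.parcellation, silence_ratio=r).silence_verdict
            for r in (0.001, 0.05, 0.2, 0.5, 1.0)
        ]
        assert verdicts == sorted(verdicts)  # loosening never flips true->false


class TestSectioning:
    def test_no_shrinkage_when_lengths_match(self):
        assert shrink_factor(15.0, 5.6, -9.4) == pytest.approx(1.0)

    def test_linear_in_specimen_length(self):
        a = shrink_factor(12.0, 5.6, -9.4)
        assert shrink_factor(6.0, 5.6, -9.4) == pytest.approx(a / 2.0)

    def test_invalid_extents_rejected(self):
        with pytest.raises(GeometryError):
            shrink_factor(10.0, -2.0, 5.0)
        with pytest.raises(GeometryError):
            shrink_factor(-1.0, 5.6, -9.4)

    def test_printed_bregma_offset_scales(self):
        """The published scaling: a Bregma offset of -0.63 mm maps to
        -0.63 * 0.741 mm on a specimen with alpha = 0.741."""
        assert atlas_to_specimen(-0.63, 0.741) == pytest.approx(-0.46683)
        assert atlas_to_specimen(0.0, 0.741) == 0.0
        assert atlas_to_specimen(3.2, 1.0) == pytest.approx(3.2)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.1, 20.0), st.floats(0.2, 1.2),
    )
    def test_atlas_specimen_round_trip(self, offset, alpha):
        specimen = atlas_to_specimen(offset, alpha)
        back = atlas_to_specimen(specimen, 1.0 / alpha)
        assert back == pytest.approx(offset, abs=1e-12 * max(1.0, offset))

    def test_plan_consistency(self):
        plan = SectioningPlan(
            length_mm=11.1, a_mm=5.6, p_mm=-9.4, block_center_mm=-0.63
        )
        assert plan.alpha == pytest.approx(11.1 / 15.0)
        assert plan.b2_mm == pytest.approx(plan.alpha * 5.6)
        lo, hi = plan.block_bounds()
        assert hi - lo == pytest.approx(plan.alpha * plan.block_thickness_mm)
        assert plan.alpha * (5.6 - (-9.4)) == pytest.approx(11.1)
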