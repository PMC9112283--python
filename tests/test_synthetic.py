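"""Generator unit/property tests: trains, templates, coupling, conditions."""
import numpy as np
import pytest

from nmspont.model import DFF_THRESHOLD, EventParams
from nmspont.synthetic import (
    CONDITION_NAMES,
    PRESET_NAMES,
    apply_condition,
    build_preset,
    couple_traces,
    decay_tau,
    generate_traces,
    get_condition,
    render_trace,
    sample_event_train,
    transient_profile,
)


class TestEventTrain:
    def test_zero_rate_gives_empty_train(self, rng):
        assert len(sample_event_train(0.0, 900.0, rng)) == 0

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError, match="rate"):
            sample_event_train(-0.1, 900.0, rng)

    def test_times_within_support_and_sorted(self, rng):
        for _ in range(50):
            t = sample_event_train(0.05, 300.0, rng)
            assert np.all(t >= 0) and np.all(t < 300.0)
            assert np.all(np.diff(t) > 0)

    def test_poisson_mean_count(self, rng):
        # mean count over 10^4 draws ~ lambda * T = 9.0 within 3 SE
        counts = [len(sample_event_train(0.01, 900.0, rng)) for _ in range(10_000)]
        assert abs(np.mean(counts) - 9.0) < 0.1


class TestTransientTemplate:
    def test_above_threshold_time_equals_duration(self):
        # fine sampling: measured time above 0.10 matches the configured
        # duration to within one sample
        A, rise, D = 0.5, 3.0, 14.22
        tau = decay_tau(A, D, rise)
        dt = 0.005
        t = np.arange(0, 120, dt)
        h = transient_profile(t, A, rise, tau)
        measured = np.sum(h > DFF_THRESHOLD) * dt
        assert abs(measured - D) <= dt + 1e-9

    def test_tau_undefined_below_threshold(self):
        with pytest.raises(ValueError, match="amplitude"):
            decay_tau(0.08, 10.0, 3.0)

    def test_profile_zero_before_event(self):
        assert transient_profile(np.array([-1.0, -0.01]), 0.5, 3.0, 5.0).sum() == 0


class TestRenderTrace:
    def test_no_events_no_noise_is_flat_baseline(self):
        p = EventParams(0.0, 0.5, 9.06, noise_sd_dff=0.0, baseline_f=123.0)
        tr = render_trace(np.empty(0), p, 3.0, 900.0, np.random.default_rng(0))
        assert np.all(tr.F == 123.0)

    def test_measured_above_threshold_time(self):
        p = EventParams(0.001, 0.5, 14.22, noise_sd_dff=0.0)
        tr = render_trace(np.array([50.0]), p, 0.01, 300.0, np.random.default_rng(0))
        dff = (tr.F - p.baseline_f) / p.baseline_f
        assert abs(np.sum(dff > DFF_THRESHOLD) * 0.01 - 14.22) <= 0.01

    def test_overlapping_transients_superpose(self):
        p = EventParams(0.001, 0.5, 9.06, noise_sd_dff=0.0)
        rng = np.random.default_rng(0)
        both = render_trace(np.array([30.0, 35.0]), p, 1.0, 200.0, rng)
        one = render_trace(np.array([30.0]), p, 1.0, 200.0, rng)
        other = render_trace(np.array([35.0]), p, 1.0, 200.0, rng)
        assert np.all(both.F >= one.F - 1e-9)
        assert np.all(both.F >= other.F - 1e-9)

    def test_subthreshold_amplitude_rejected(self):
        with pytest.raises(ValueError):
            EventParams(0.01, 0.05, 9.06)


class TestCoupling:
    def test_phi_one_identical_traces(self, hc_params):
        p = EventParams(0.012, 0.8, 14.22, noise_sd_dff=0.0)
        trs = couple_traces(p, 1.0, 4, 3.0, 900.0, np.random.default_rng(3))
        for tr in trs[1:]:
            np.testing.assert_allclose(tr.activity, trs[0].activity)
            assert np.corrcoef(tr.F, trs[0].F)[0, 1] == pytest.approx(1.0)

    def test_phi_zero_independent(self):
        p = EventParams(0.012, 0.8, 14.22, noise_sd_dff=0.0)
        trs = couple_traces(p, 0.0, 2, 1.0, 50_000.0, np.random.default_rng(4))
        r = np.corrcoef(trs[0].activity, trs[1].activity)[0, 1]
        assert abs(r) < 0.05

    def test_phi_outside_unit_interval_rejected(self, hc_params):
        with pytest.raises(ValueError, match="phi"):
            couple_traces(hc_params, 1.2, 2, 3.0, 900.0, np.random.default_rng(0))

    @pytest.mark.parametrize("phi", [0.28, 0.5, 0.8])
    def test_shared_variance_identity(self, phi):
        # Monte-Carlo check: pairwise R of noiseless activity ~ phi at
        # 1e5 frames
        p = EventParams(0.012, 0.8, 14.22, noise_sd_dff=0.0)
        trs = couple_traces(p, phi, 4, 1.0, 100_000.0, np.random.default_rng(5))
        rs = [
            np.corrcoef(trs[i].activity, trs[j].activity)[0, 1]
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        assert abs(np.mean(rs) - phi) < 0.02

    def test_noise_attenuation_closed_form(self):
        # R = phi / (1 + rho) for noise variance ratio rho
        rho = 0.05
        p = EventParams(
            0.012, 0.8, 14.22, noise_sd_dff=0.0, noise_variance_ratio=rho
        )
        trs = couple_traces(p, 1.0, 6, 1.0, 50_000.0, np.random.default_rng(6))
        rs = [
            np.corrcoef(trs[i].F, trs[j].F)[0, 1]
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert abs(np.mean(rs) - 1.0 / (1.0 + rho)) < 0.02


class TestPresets:
    def test_unknown_preset_lists_catalog(self):
        with pytest.raises(ValueError) as exc:
            build_preset("nope", seed=1)
        for name in PRESET_NAMES:
            assert name in str(exc.value)

    def test_supporting_day3_durations(self):
        m = build_preset("supporting_day3", seed=1)
        assert all(c.cell_type == "supporting_cell" for c in m.cells)
        assert all(
            c.compartments["soma"].duration_s == 9.06 for c in m.cells
        )

    def test_hair_cell_day3_geometry_and_duration(self):
        m = build_preset("hair_cell_day3", seed=1)
        assert len(m.cells) == 10
        assert all(
            c.compartments["soma"].duration_s == 14.22 for c in m.cells
        )
        groups = m.coupling_groups()
        assert len(groups) == 1 and groups[0].phi == 0.28

    def test_two_color_hc_sc_cross_class_uncoupled(self):
        m = build_preset("two_color_hc_sc", seed=2)
        by_id = {c.cell_id: c.cell_type for c in m.cells}
        for a, b, phi in m.coupling:
            assert by_id[a[0]] == by_id[b[0]]  # no HC-SC pairs at all

    def test_condition_suffix_equivalent_to_keyword(self):
        a = build_preset("supporting_day3+FFA", seed=3)
        b = build_preset("supporting_day3", seed=3, condition="FFA")
        assert a.coupling == b.coupling
        assert a.condition.name == b.condition.name == "FFA"

    def test_isradipine_spares_the_bundle(self):
        m = build_preset("hair_cell_day3", seed=1, condition="isradipine")
        for c in m.cells:
            assert c.compartments["presynapse"].rate_per_s == 0.0
            assert c.compartments["bundle"].rate_per_s == pytest.approx(0.012)


class TestConditions:
    def test_unknown_condition_lists_catalog(self):
        with pytest.raises(ValueError) as exc:
            get_condition("nope")
        for name in CONDITION_NAMES:
            assert name in str(exc.value)

    def test_abtx_apamin_is_identity_on_hair_cells(self):
        m = build_preset("hair_cell_day3", seed=5)
        m2 = apply_condition(m, "aBtx_apamin")
        b1, b2 = generate_traces(m), generate_traces(m2)
        for k in b1.traces:
            np.testing.assert_array_equal(b1.traces[k].F, b2.traces[k].F)

    def test_day6_leaves_supporting_cells_unchanged(self):
        m = build_preset("supporting_day3", seed=5)
        m2 = apply_condition(m, "day6")
        b1, b2 = generate_traces(m), generate_traces(m2)
        for k in b1.traces:
            np.testing.assert_array_equal(b1.traces[k].F, b2.traces[k].F)

    def test_day6_reduces_hair_cell_and_efferent_rates(self):
        m = apply_condition(build_preset("hair_cell_day3", seed=5), "day6")
        for c in m.cells:
            for p in c.compartments.values():
                assert p.rate_per_s == pytest.approx(0.0012)

    def test_mrs2500_and_thapsigargin_silence_supporting_cells(self):
        m = build_preset("supporting_day3", seed=5)
        for cond in ("MRS2500", "thapsigargin"):
            m2 = apply_condition(m, cond)
            assert all(
                c.compartments["soma"].rate_per_s == 0.0 for c in m2.cells
            )
        m3 = apply_condition(m, "thapsigargin")
        assert all(
            c.compartments["soma"].baseline_f
            == pytest.approx(3.0 * 100.0)
            for c in m3.cells
        )

    def test_tip_link_disruption_residual_fraction(self):
        for cond in ("BAPTA", "pcdh15a"):
            m = build_preset("hair_cell_day3", seed=5, condition=cond)
            for c in m.cells:
                assert c.compartments["bundle"].rate_per_s == pytest.approx(
                    0.0012
                )
                assert c.compartments["presynapse"].rate_per_s == pytest.approx(
                    0.0012
                )
                assert c.compartments["soma"].rate_per_s == pytest.approx(0.012)

    def test_ffa_overrides_sc_coupling_only(self):
        m = build_preset("two_color_hc_sc", seed=5, condition="FFA")
        by_id = {c.cell_id: c.cell_type for c in m.cells}
        for a, b, phi in m.coupling:
            if by_id[a[0]] == "supporting_cell":
                assert phi == 0.08
            else:
                assert phi == 0.28


class TestDeterminism:
    def test_same_seed_identical_traces(self):
        b1 = generate_traces(build_preset("hair_cell_day3", seed=11))
        b2 = generate_traces(build_preset("hair_cell_day3", seed=11))
        for k in b1.traces:
            np.testing.assert_array_equal(b1.traces[k].F, b2.traces[k].F)

    def test_different_seed_differs(self):
        b1 = generate_traces(build_preset("hair_cell_day3", seed=11))
        b2 = generate_traces(build_preset("hair_cell_day3", seed=12))
        assert any(
            not np.array_equal(b1.traces[k].F, b2.traces[k].F)
            for k in b1.traces
        )


class TestFixtureBundle:
    def test_roundtrip_and_byte_determinism(self, tmp_path):
        from nmspont.synthetic import default_rois, write_fixture_bundle
        from nmspont.traces import read_rois

        m = build_preset("supporting_day3", seed=21, n_cells=4)
        p1 = write_fixture_bundle(m, tmp_path / "a", mode="traces")
        p2 = write_fixture_bundle(m, tmp_path / "b", mode="traces")
        assert (
            p1["traces"].read_bytes() == p2["traces"].read_bytes()
        ), "same seed must reproduce the trace CSV byte for byte"
        rois = read_rois(p1["rois"])
        expected = default_rois(m)
        assert [r.cell_id for r in rois] == [r.cell_id for r in expected]
        np.testing.assert_allclose(
            [(r.x_px, r.y_px) for r in rois],
            [(r.x_px, r.y_px) for r in expected],
            rtol=1e-8,
        )
        import json

        manifest = json.loads(p1["manifest"].read_text())
        assert manifest["seed"] == m.seed
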