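"""Activity maps, ΔF snapshots, onset latency, profile FWHM."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmspont.events import average_magnitude
from nmspont.imaging_io import PlaneSeries, max_project
from nmspont.spatial import (
    delta_f_series,
    fwhm_profile,
    mean_dff_map,
    onset_latency,
)


def _plane(data, dt=1.0):
    return PlaneSeries(np.asarray(data, float), dt, 0.325)


class TestMeanDffMap:
    def test_constant_movie_zero_map(self):
        amap = mean_dff_map(_plane(np.full((30, 6, 6), 50.0)), 11)
        assert np.all(amap.mean_dff == 0.0)
        np.testing.assert_array_equal(amap.reference, 50.0)

    def test_blinking_pixel_matches_trace_statistic(self):
        data = np.full((60, 5, 5), 100.0)
        data[[10, 11, 30], 2, 3] = 125.0  # dff 0.25 on three frames
        amap = mean_dff_map(_plane(data), 21, theta=0.10)
        trace_dff = (data[:, 2, 3] - 100.0) / 100.0
        assert amap.mean_dff[2, 3] == pytest.approx(
            average_magnitude(trace_dff, 0.10)
        )
        others = amap.mean_dff.copy()
        others[2, 3] = 0.0
        assert np.all(others == 0.0)

    def test_zero_baseline_pixels_masked_and_counted(self):
        data = np.full((20, 4, 4), 10.0)
        data[:, 0, 0] = 0.0
        amap = mean_dff_map(_plane(data), 5)
        assert amap.n_masked_pixels == 1
        assert amap.mean_dff[0, 0] == 0.0

    def test_roi_mean_agrees_with_trace_level(self):
        # map restricted to the ROI pixels vs the extracted-trace value
        from nmspont.synthetic import build_preset, default_rois, render_movie
        from nmspont.traces import extract_raw_trace, trace_from_raw

        m = build_preset("supporting_day3", seed=33, n_cells=2)
        m.recording_s = 300.0
        series, _ = render_movie(m, include_noise=False)
        plane = max_project(series, "all")[0]
        amap = mean_dff_map(plane, 41)
        roi = default_rois(m, series.voxel_spacing_um[1])[0]
        yy, xx = np.ogrid[: plane.data.shape[1], : plane.data.shape[2]]
        r_px = (roi.diameter_um / 2) / plane.pixel_spacing_um
        mask = (yy - roi.y_px) ** 2 + (xx - roi.x_px) ** 2 <= r_px**2
        map_value = amap.mean_dff[mask].mean()
        tr = trace_from_raw(extract_raw_trace(plane, roi), 3.0, 41)
        trace_value = tr.dff.mean()
        assert map_value == pytest.approx(trace_value, rel=0.10)

    def test_supporting_cell_silencing_flips_map(self):
        # P2ry1 block: post-treatment map mean collapses below 10% of pre
        from nmspont.synthetic import build_preset, render_movie

        kw = dict(n_cells=3)
        pre_model = build_preset("supporting_day3", seed=34, **kw)
        post_model = build_preset(
            "supporting_day3", seed=34, condition="MRS2500", **kw
        )
        for mdl in (pre_model, post_model):
            mdl.recording_s = 450.0
        # bright acquisition (shot noise a few percent) so the map
        # contrast reflects the condition, not photon statistics
        pre, _ = render_movie(pre_model, image_shape=(8, 64, 64),
                              photon_scale=100.0)
        post, _ = render_movie(post_model, image_shape=(8, 64, 64),
                               photon_scale=100.0)
        m_pre = mean_dff_map(max_project(pre, "all")[0], 41, theta=0.10)
        m_post = mean_dff_map(max_project(post, "all")[0], 41, theta=0.10)
        assert m_pre.mean_dff.mean() > 0
        assert m_post.mean_dff.mean() < 0.10 * m_pre.mean_dff.mean()


class TestDeltaFSeries:
    def test_reference_frame_is_zero(self, rng):
        plane = _plane(rng.random((10, 4, 4)))
        out = delta_f_series(plane, 3)
        np.testing.assert_array_equal(out[3], 0.0)

    def test_global_brightening_uniform_positive(self):
        base = np.full((4, 4), 10.0)
        data = np.stack([base + t for t in range(5)])
        out = delta_f_series(_plane(data), 0)
        for t in range(1, 5):
            np.testing.assert_allclose(out[t], float(t))

    def test_wave_apical_rows_lead(self):
        from nmspont.synthetic import build_preset, render_movie

        m = build_preset("sc_wave_singleplane", seed=16)
        series, meta = render_movie(m)
        plane = max_project(series, "all")[0]
        ev0 = None
        from nmspont.synthetic import generate_traces

        ev0 = generate_traces(m).traces[("sc1", "top")].event_times[0]
        ref = int(ev0 / m.frame_interval_s) - 2
        out = delta_f_series(plane, ref)
        probe = ref + 6  # 0.6 s into the 3 s rise
        top_rows = out[probe, 15:25, :].mean()
        bottom_rows = out[probe, 50:60, :].mean()
        assert top_rows > bottom_rows

    def test_reference_out_of_range(self, rng):
        with pytest.raises(ValueError):
            delta_f_series(_plane(rng.random((5, 3, 3))), 9)


class TestOnsetLatency:
    def test_identical_traces_zero(self):
        x = np.concatenate([np.zeros(20), np.linspace(0, 1, 30)])
        assert onset_latency(x, x, 0.1) == 0.0

    def test_constructed_three_frame_shift(self):
        x = np.concatenate([np.zeros(20), np.linspace(0, 1, 30),
                            np.zeros(30)])
        shifted = np.roll(x, 3)
        assert onset_latency(x, shifted, 0.1) == pytest.approx(0.300, abs=1e-9)

    def test_antisymmetry(self, rng):
        a = np.convolve(rng.random(200), np.ones(5) / 5, "same")
        b = np.convolve(rng.random(200), np.ones(5) / 5, "same")
        assert onset_latency(a, b, 0.1) == pytest.approx(
            -onset_latency(b, a, 0.1)
        )

    def test_no_event_rejected(self):
        with pytest.raises(ValueError, match="no event"):
            onset_latency(np.zeros(50), np.ones(50), 0.1)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            onset_latency(np.ones(10), np.ones(10), 0.1, onset_fraction=1.5)

    def test_wave_preset_recovery(self):
        """Programmed 300 ms apex->base delay recovered from the movie."""
        from nmspont.imaging_io import max_project
        from nmspont.synthetic import build_preset, default_rois, render_movie
        from nmspont.traces import trace_from_plane

        m = build_preset("sc_wave_singleplane", seed=16)
        series, meta = render_movie(m)
        plane = max_project(series, "all")[0]
        rois = {
            r.compartment: r
            for r in default_rois(m, series.voxel_spacing_um[1])
        }
        top = trace_from_plane(plane, rois["top"], 401)
        bottom = trace_from_plane(plane, rois["bottom"], 401)
        lat = onset_latency(top.dff, bottom.dff, m.frame_interval_s, 0.2)
        assert lat == pytest.approx(meta["programmed_delay_s"], abs=0.1)


class TestFwhm:
    def test_gaussian_analytic_width(self):
        x = np.arange(0, 20, 0.05)
        sigma = 1.0
        profile = np.exp(-0.5 * ((x - 10) / sigma) ** 2)
        assert fwhm_profile(profile, 0.05) == pytest.approx(
            2.355 * sigma, rel=0.01
        )

    def test_symmetric_triangle(self):
        up = np.linspace(0, 1, 41)
        profile = np.concatenate([up, up[-2::-1]])  # base 4 um at 0.05 um
        assert fwhm_profile(profile, 0.05) == pytest.approx(2.0, rel=0.01)

    def test_scale_equivariance(self, rng):
        x = np.arange(0, 30, 0.1)
        profile = np.exp(-0.5 * ((x - 15) / 2.0) ** 2) + 0.05
        w1 = fwhm_profile(profile, 0.1)
        w2 = fwhm_profile(profile, 0.2)
        assert w2 == pytest.approx(2 * w1, rel=1e-9)

    @given(st.floats(0.5, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_gaussian_family(self, sigma):
        x = np.arange(0, 40, 0.02)
        profile = 7.0 + 3.0 * np.exp(-0.5 * ((x - 20) / sigma) ** 2)
        assert fwhm_profile(profile, 0.02) == pytest.approx(
            2.3548 * sigma, rel=0.01
        )

    def test_no_crossing_rejected(self):
        with pytest.raises(ValueError, match="crossing"):
            fwhm_profile(np.linspace(0, 1, 50), 0.1)

    def test_rendered_bead_blob(self):
        # a static rendered blob's profile has FWHM = its configured
        # diameter (sigma = d / 2.355)
        from nmspont.model import CellSpec, EventParams, NeuromastModel
        from nmspont.synthetic import render_movie

        params = EventParams(0.0, 0.5, 9.06, noise_sd_dff=0.0)
        cell = CellSpec("bead", "supporting_cell", (5.0, 5.0, 4.0),
                        {"soma": params})
        model = NeuromastModel("beads", [cell], [], 10.0, 5.0, seed=1)
        series, _ = render_movie(
            model, image_shape=(8, 48, 48), include_noise=False
        )
        frame = series.data[0]
        y_px = 5.0 / 0.325
        profile = frame[4, :, int(round(y_px))]
        width = fwhm_profile(profile, 0.325)
        assert width == pytest.approx(3.0, rel=0.05)  # 3 um soma diameter
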