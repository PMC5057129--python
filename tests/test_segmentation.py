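import itertools

import numpy as np
import pytest

from nita.segmentation import (PiecewiseModel, bail_check, bic, fit_pixel,
                               initial_fit, interpolate, knot_value,
                               lognormal_loglik, nita_build, nita_subtract,
                               orthogonal_distances)
from nita.timeseries import (DAYS_PER_YEAR, InsufficientDataError, NITAParams,
                             PixelSeries)


def series_from(dates, values, valid=None):
    return PixelSeries.from_arrays(np.asarray(dates), values, valid)


def bare_model(bx, by):
    return PiecewiseModel(np.asarray(bx), np.asarray(by), np.empty(0),
                          np.nan, np.nan, 2, np.nan)


class TestKnotValue:
    def test_constant_window_any_percentile(self):
        s = series_from(np.arange(9), np.full(9, 0.7))
        for c in (0, 4, 8):
            assert knot_value(s, c, 90, 3) == pytest.approx(0.7)

    def test_median_of_three(self):
        s = series_from([0, 1, 2], [0.2, 0.4, 0.6])
        assert knot_value(s, 1, 50, 1) == pytest.approx(0.4)

    def test_maximum_percentile(self):
        s = series_from([0, 1], [0.0, 1.0])
        assert knot_value(s, 0, 100, 3) == pytest.approx(1.0)

    def test_calendar_positions_narrow_the_window(self):
        # three valid points at calendar slots 0, 5, 6: slot-0 point is alone
        # in a +/-3 window while index-space would see all three
        s = series_from([0, 80, 96], [0.1, 0.8, 0.9])
        pos = np.array([0, 5, 6])
        assert knot_value(s, 0, 100, 3, pos) == pytest.approx(0.1)
        assert knot_value(s, 0, 100, 3) == pytest.approx(0.9)


class TestInterpolate:
    def test_exact_at_breakpoints_and_linear_between(self):
        m = bare_model([0, 100, 200], [0.8, 0.8, 0.2])
        assert interpolate(m, 100) == pytest.approx(0.8)
        assert interpolate(m, 150) == pytest.approx(0.5)
        assert interpolate(m, 50) == pytest.approx(0.8)

    def test_midpoint_of_single_segment(self):
        m = bare_model([0, 100], [0.0, 1.0])
        assert interpolate(m, 50) == pytest.approx(0.5)

    def test_out_of_span_raises(self):
        m = bare_model([0, 100], [0.0, 1.0])
        with pytest.raises(ValueError):
            interpolate(m, 101)


class TestOrthogonalDistances:
    def test_point_on_segment_is_zero(self):
        m = bare_model([0, 36525], [0.2, 0.8])
        s = series_from([18263], [np.interp(18263, m.bx, m.by)])
        assert orthogonal_distances(m, s)[0] == pytest.approx(0.0, abs=1e-12)

    def test_vertical_offset_to_horizontal_line(self):
        m = bare_model([0, 36525], [0.5, 0.5])
        s = series_from([1000, 20000], [0.7, 0.7])
        for xy in (0.5, 1.0, 4.0):
            assert orthogonal_distances(m, s, xy) == pytest.approx([0.2, 0.2])

    def test_forty_five_degree_segment(self):
        # xy_scale=100 maps the 36525-day span to exactly 1 x-unit, so the
        # segment rises at 45 degrees and a vertical offset of 0.2 projects
        # to 0.2/sqrt(2)
        m = bare_model([0, 36525], [0.0, 1.0])
        s = series_from([18263], [18263 / 36525 + 0.2])
        assert orthogonal_distances(m, s, xy_scale=100.0)[0] == \
            pytest.approx(0.2 / np.sqrt(2))


class TestInitialFit:
    def test_noiseless_line_fits_exactly(self):
        dates = np.arange(0, 800, 16)
        vals = 0.2 + dates * 1e-4
        m = initial_fit(series_from(dates, vals), NITAParams(filt_dist=0))
        assert np.max(m.distances) == pytest.approx(0.0, abs=1e-12)

    def test_endpoint_percentile_resists_outlier(self):
        vals = np.full(12, 0.8)
        vals[-1] = 0.2
        m = initial_fit(series_from(np.arange(12), vals),
                        NITAParams(prctile=90, filt_dist=3))
        # 90th percentile of the last window {0.8, 0.8, 0.8, 0.2} stays high
        assert m.by[-1] == pytest.approx(0.8)

    def test_two_point_series_passes_through_both(self):
        m = initial_fit(series_from([0, 100], [0.3, 0.6]),
                        NITAParams(filt_dist=0))
        assert m.by == pytest.approx([0.3, 0.6])

    def test_single_point_raises(self):
        with pytest.raises(InsufficientDataError):
            initial_fit(series_from([0], [0.5]), NITAParams())


class TestBailCheck:
    def test_perfect_fit_bails(self):
        m = bare_model([0, 10], [0, 0])
        object.__setattr__(m, "distances", np.zeros(5))
        assert bail_check(m, noise=0.3, bail_thresh=1.0)

    def test_high_error_ratio_continues(self):
        m = bare_model([0, 10], [0, 0])
        object.__setattr__(m, "distances", np.full(5, 0.4))
        assert not bail_check(m, noise=0.1, bail_thresh=2.0)   # ratio 4 > 2

    def test_boundary_ratio_bails(self):
        m = bare_model([0, 10], [0, 0])
        object.__setattr__(m, "distances", np.full(5, 0.1))
        assert bail_check(m, noise=0.1, bail_thresh=1.0)       # ratio 1 <= 1

    def test_zero_noise_bails_only_on_zero_error(self):
        m = bare_model([0, 10], [0, 0])
        object.__setattr__(m, "distances", np.full(5, 1e-3))
        assert not bail_check(m, noise=0.0, bail_thresh=5.0)


class TestLognormalLoglik:
    def test_closed_form_two_distances(self):
        # d = {1, e^2}: mu=1, sigma=1; hand-computed log-pdf sum
        ll = lognormal_loglik(np.array([1.0, np.exp(2.0)]))
        assert ll == pytest.approx(-4.837877066, abs=1e-8)

    def test_degenerate_spread_stays_finite(self):
        ll = lognormal_loglik(np.full(10, 0.3))
        assert np.isfinite(ll) and ll > 0    # sigma floored -> sharp density

    def test_zero_distances_floored(self):
        assert np.isfinite(lognormal_loglik(np.zeros(5)))


class TestBic:
    def test_single_observation_zero(self):
        assert bic(0.0, 1, 1, 1.0) == pytest.approx(0.0)

    def test_plug_in_arithmetic(self):
        # 4 * 3 * ln(100) + 20
        assert bic(-10.0, 3, 100, 4.0) == pytest.approx(75.2620422, abs=1e-6)

    def test_penalty_scales_complexity_term_only(self):
        base = bic(-5.0, 4, 50, 1.0)
        double = bic(-5.0, 4, 50, 2.0)
        assert double - base == pytest.approx(4 * np.log(50))


class TestBuild:
    def test_first_insertion_matches_filtered_error_oracle(self, noiseless_inundation):
        series, bx, by = noiseless_inundation
        params = NITAParams(prctile=50, filt_dist=3, max_segment=2)
        first = initial_fit(series, params)
        # independent oracle: brute-force median filter of the distances
        d = first.distances
        fd = params.filt_dist
        filtered = np.array([np.median(d[max(0, i - fd):i + fd + 1])
                             for i in range(d.size)])
        filtered[0] = filtered[-1] = -np.inf    # endpoints are breakpoints
        expected_date = series.dates[int(np.argmax(filtered))]
        built = nita_build(series, params)
        assert built.segments == 2
        assert built.bx[1] == expected_date
        # lands near a true vertex
        assert min(abs(built.bx[1] - bx[1]), abs(built.bx[1] - bx[2])) <= \
            fd * np.median(np.diff(series.dates))

    def test_straight_line_stays_flat(self):
        dates = np.arange(0, 3200, 16)
        vals = 0.1 + dates * 2e-4
        built = nita_build(series_from(dates, vals),
                           NITAParams(prctile=50, filt_dist=0, max_segment=6))
        grid = np.linspace(dates[0], dates[-1], 500)
        assert np.allclose(interpolate(built, grid),
                           np.interp(grid, dates, vals), atol=1e-9)

    def test_max_segment_one_equals_initial_fit(self, noiseless_inundation):
        series, _, _ = noiseless_inundation
        params = NITAParams(max_segment=1)
        built = nita_build(series, params)
        first = initial_fit(series, params)
        assert np.array_equal(built.bx, first.bx)
        assert built.by == pytest.approx(first.by)


def exhaustive_subtract_oracle(model, series, params):
    """Best BIC over every subset of interior breakpoints (endpoints kept)."""
    from nita.segmentation import _polyline_distances
    s = series.drop_invalid()
    x, y = s.dates, s.values
    interior = list(range(1, model.bx.size - 1))
    best = np.inf
    for r in range(len(interior) + 1):
        for keep in itertools.combinations(interior, r):
            idx = [0] + list(keep) + [model.bx.size - 1]
            d = _polyline_distances(model.bx[idx], model.by[idx], x, y,
                                    params.xy_scale)
            cand = bic(lognormal_loglik(d), len(idx) - 1, x.size, params.penalty)
            best = min(best, cand)
    return best


class TestSubtract:
    def test_two_breakpoints_returned_unchanged(self):
        s = series_from([0, 100, 200], [0.1, 0.2, 0.3])
        m = initial_fit(s, NITAParams())
        out = nita_subtract(m, s, NITAParams())
        assert np.array_equal(out.bx, m.bx)

    def test_recovers_true_segments_and_matches_exhaustive(self, noiseless_inundation,
                                                           exact_params):
        series, bx, by = noiseless_inundation
        params = exact_params.replace(max_segment=6)
        built = nita_build(series, params)
        assert built.segments == 6
        out = nita_subtract(built, series, params)
        assert out.segments == 3
        assert np.array_equal(out.bx, bx)
        assert out.bic == pytest.approx(
            exhaustive_subtract_oracle(built, series, params), rel=1e-12)

    def test_huge_penalty_collapses_pure_noise(self, rng):
        dates = np.arange(0, 1600, 16)
        vals = 0.5 + rng.normal(0, 0.1, dates.size)
        s = series_from(dates, vals)
        params = NITAParams(penalty=500.0, max_segment=6)
        out = nita_subtract(nita_build(s, params), s, params)
        assert out.segments == 1

    def test_greedy_never_beats_exhaustive(self, rng):
        params = NITAParams(prctile=50, filt_dist=1, max_segment=5, penalty=2.0)
        for _ in range(10):
            dates = np.sort(rng.choice(np.arange(0, 4000, 16), 30, replace=False))
            vals = np.interp(dates, [0, 2000, 4000], [0.8, 0.2, 0.3])
            vals = vals + rng.normal(0, 0.05, dates.size)
            s = series_from(dates, vals)
            built = nita_build(s, params)
            out = nita_subtract(built, s, params)
            assert out.bic >= exhaustive_subtract_oracle(built, s, params) - 1e-9
            assert out.bic <= built.bic + 1e-9


class TestFitPixel:
    def test_noiseless_line_is_single_exact_segment(self, exact_params):
        dates = np.arange(0, 800, 16)
        vals = 0.75 - dates * 1e-5
        m = fit_pixel(series_from(dates, vals), exact_params)
        assert m.segments == 1
        assert interpolate(m, dates) == pytest.approx(vals, abs=1e-12)

    def test_noiseless_inundation_recovered_exactly(self, noiseless_inundation,
                                                    exact_params):
        series, bx, by = noiseless_inundation
        m = fit_pixel(series, exact_params)
        assert m.segments == 3
        assert np.array_equal(m.bx, bx)
        assert m.by == pytest.approx(by, abs=1e-12)

    def test_gapped_noisy_inundation_mostly_recovered(self, noiseless_inundation):
        from nita.classify import classify_trajectory
        from nita.simulate import GapModel, NoiseModel
        series, bx, by = noiseless_inundation
        cal = series.dates
        truth = np.interp(cal, bx, by)
        gap, nm = GapModel(), NoiseModel()
        near, detected = 0, 0
        rng = np.random.default_rng(99)
        for _ in range(20):
            mask = gap.sample_mask(cal.size, rng)
            vals = np.where(mask, truth + nm.draw(cal.size, rng), np.nan)
            s = PixelSeries.from_arrays(cal, vals, mask)
            m = fit_pixel(s, NITAParams.study())
            near += abs(m.segments - 3) <= 1
            detected += any(r.event_class == "disturbance"
                            for r in classify_trajectory(m))
        # under 55% gaps and SD-0.2 noise the structure survives in the
        # large majority of draws
        assert near >= 16
        assert detected >= 14

    def test_deterministic(self, noiseless_inundation):
        series, _, _ = noiseless_inundation
        a = fit_pixel(series, NITAParams.study())
        b = fit_pixel(series, NITAParams.study())
        assert np.array_equal(a.bx, b.bx)
        assert np.array_equal(a.by, b.by)
        assert a.bic == b.bic

    def test_below_two_valid_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_pixel(series_from([0, 16], [0.5, 0.6], valid=[True, False]))

    def test_subtract_bic_never_above_build_bic(self, noiseless_inundation):
        series, _, _ = noiseless_inundation
        params = NITAParams.study()
        built = nita_build(series, params)
        final = nita_subtract(built, series, params)
        assert final.bic <= built.bic + 1e-9


def test_model_text_round_trip(tmp_path, noiseless_inundation, exact_params):
    series, _, _ = noiseless_inundation
    m = fit_pixel(series, exact_params)
    path = tmp_path / "model.txt"
    m.to_text(path)
    back = PiecewiseModel.from_text(path)
    assert np.array_equal(back.bx, m.bx)
    assert back.by == pytest.approx(m.by)
    assert back.bic == pytest.approx(m.bic)
    assert back.segments == m.segments
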