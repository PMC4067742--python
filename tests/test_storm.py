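"""Single-molecule detection, Gaussian fitting, rendering, resolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimstorm import (CameraModel, EmitterSet, Localization, SpotRejection,
                       detect_candidates, estimate_resolution, fit_spot,
                       localize_stack, render_density,
                       simulate_blinking_movie, thompson_precision)
from flimstorm.storm import LocalizationTable, StormParams, SuperResImage


def _table(x, y, precision=10.0, pixel_size=100.0, field=(32, 32)):
    n = len(x)
    df = pd.DataFrame({"frame": np.arange(n), "x_nm": x, "y_nm": y,
                       "photons": np.full(n, 1000.0),
                       "sigma_nm": np.full(n, 150.0),
                       "background": np.full(n, 2.0),
                       "precision_nm": np.full(n, precision)})
    return LocalizationTable(data=df, pixel_size=pixel_size, field_shape=field)


class TestThompsonPrecision:
    def test_shot_noise_limit(self):
        # b = 0, a -> 0: only s/sqrt(N) survives
        assert thompson_precision(10_000, 150.0, 0.01, 0.0) == pytest.approx(
            1.500, abs=1e-3)

    def test_monotone_decreasing_in_photons(self):
        values = [thompson_precision(n, 150.0, 100.0, 3.0)
                  for n in (100, 200, 500, 2000, 10_000)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_hand_expanded_three_term_sum(self):
        # s=150, a=100, N=500, b=3: terms written out by hand
        s2_term = 150.0 ** 2 / 500
        pix_term = 100.0 ** 2 / (12 * 500)
        bg_term = 8 * np.pi * 150.0 ** 4 * 3.0 ** 2 / (100.0 ** 2 * 500 ** 2)
        expected = np.sqrt(s2_term + pix_term + bg_term)
        assert thompson_precision(500, 150.0, 100.0, 3.0) == pytest.approx(
            expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            thompson_precision(0, 150.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            thompson_precision(100, -1.0, 100.0, 1.0)


class TestDetectCandidates:
    def test_constant_frame_empty(self):
        assert detect_candidates(np.full((32, 32), 7.0)) == []

    def test_single_bright_spot(self, rng):
        frame = rng.poisson(2.0, (32, 32)).astype(float)
        frame[16, 10] += 50 * 1.5  # ~50x the background sigma
        cands = detect_candidates(frame, threshold_k=6.0)
        assert cands == [(16, 10)]

    def test_matches_exhaustive_scan_oracle(self, rng):
        frame = rng.normal(100.0, 1.0, (64, 64))
        spots = [(8, 8), (8, 24), (8, 40), (8, 56), (24, 8), (24, 24),
                 (40, 40), (40, 56), (56, 8), (56, 32)]
        for r, c in spots:
            frame[r, c] += 100.0
        cands = detect_candidates(frame, threshold_k=6.0)
        assert sorted(cands) == sorted(spots)
        # oracle: exhaustive all-pixels scan for strict 8-neighbour maxima
        med = np.median(frame)
        thr = med + 6.0 * 1.4826 * np.median(np.abs(frame - med))
        oracle = []
        for i in range(1, 63):
            for j in range(1, 63):
                neigh = [frame[i + di, j + dj] for di in (-1, 0, 1)
                         for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
                if frame[i, j] > max(neigh) and frame[i, j] > thr:
                    oracle.append((i, j))
        assert sorted(oracle) == sorted(cands)

    def test_duplicate_suppression_keeps_brighter(self):
        frame = np.zeros((16, 16))
        frame[8, 8] = 100.0
        frame[8, 10] = 80.0   # within 5 px of the brighter peak
        cands = detect_candidates(frame, threshold_k=3.0)
        assert cands == [(8, 8)]


class TestFitSpot:
    PARAMS = StormParams(pixel_size=100.0, psf_sigma=150.0)

    def _render(self, row0, col0, i0=100.0, bg=2.0, shape=(21, 21)):
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        s = 1.5  # px
        return i0 * np.exp(-((rows - row0) ** 2 + (cols - col0) ** 2)
                           / (2 * s ** 2)) + bg

    def test_noiseless_subpixel_recovery(self):
        frame = self._render(10.3, 9.7)
        loc = fit_spot(frame, (10, 10), self.PARAMS)
        assert isinstance(loc, Localization)
        # pixel centers: true center (row 10.3, col 9.7) -> nm coordinates
        assert loc.x == pytest.approx((9.7 + 0.5) * 100.0, abs=0.1)
        assert loc.y == pytest.approx((10.3 + 0.5) * 100.0, abs=0.1)
        assert loc.photons == pytest.approx(2 * np.pi * 100.0 * 1.5 ** 2,
                                            rel=1e-3)

    def test_too_few_photons_rejected(self):
        frame = self._render(10.0, 10.0, i0=2.0)  # N ~ 28 < 100
        out = fit_spot(frame, (10, 10), self.PARAMS)
        assert isinstance(out, SpotRejection)
        assert out.reason == "too-few-photons"

    def test_border_candidate_rejected(self):
        frame = self._render(1.0, 1.0)
        out = fit_spot(frame, (1, 1), self.PARAMS)
        assert isinstance(out, SpotRejection)
        assert out.reason == "border"

    def test_rmse_matches_thompson_prediction(self):
        """Monte-Carlo localization error within 20% of the closed form."""
        cam = CameraModel(pixel_size=100.0, psf_sigma=150.0,
                          background_rate=5.0)
        true_xy = (1050.0, 950.0)
        em = EmitterSet(positions=[list(true_xy)], photons_mean=2000.0,
                        on_probability=1.0)
        movie = simulate_blinking_movie(em, cam, 500, (21, 21), 99)
        params = StormParams(pixel_size=100.0, psf_sigma=150.0,
                             threshold_k=6.0)
        table = localize_stack(movie, params)
        assert len(table) >= 450
        err = np.sqrt((table.data.x_nm - true_xy[0]) ** 2
                      + (table.data.y_nm - true_xy[1]) ** 2)
        rmse_1d = np.sqrt((err ** 2).mean() / 2)  # per-axis RMSE
        predicted = thompson_precision(2000, 150.0, 100.0, np.sqrt(5.0))
        assert 0.8 * predicted <= rmse_1d <= 1.2 * predicted


class TestLocalizeStack:
    def test_dark_movie_empty(self, rng):
        movie = rng.poisson(2.0, (50, 16, 16)).astype(float)
        table = localize_stack(movie)
        assert len(table) == 0

    def test_false_positive_rate_low(self, rng):
        movie = rng.poisson(2.0, (1000, 32, 32)).astype(float)
        table = localize_stack(movie)
        assert len(table) <= 1  # at most 1 per 1000 background frames

    def test_blink_count_matches_binomial(self):
        cam = CameraModel(background_rate=2.0)
        em = EmitterSet(positions=[[800.0, 800.0]], photons_mean=2000.0,
                        on_probability=0.3)
        movie = simulate_blinking_movie(em, cam, 1000, (16, 16), 4)
        table = localize_stack(movie)
        expected = 1000 * 0.3
        tol = 3 * np.sqrt(1000 * 0.3 * 0.7)
        assert abs(len(table) - expected) <= tol

    def test_frame_order_independence(self):
        cam = CameraModel(background_rate=2.0)
        em = EmitterSet(positions=[[800.0, 800.0]], photons_mean=2000.0,
                        on_probability=0.5)
        movie = simulate_blinking_movie(em, cam, 40, (16, 16), 5)
        fwd = localize_stack(movie)
        rev = localize_stack(movie[::-1])
        key = lambda t: np.sort(np.round(t.data.x_nm.to_numpy(), 6))
        np.testing.assert_allclose(key(fwd), key(rev))

    def test_detection_recall_on_bright_emitters(self):
        cam = CameraModel(background_rate=2.0)
        em = EmitterSet(positions=[[700.0, 700.0], [2500.0, 2500.0]],
                        photons_mean=2000.0, on_probability=1.0)
        movie = simulate_blinking_movie(em, cam, 200, (32, 32), 6)
        table = localize_stack(movie)
        assert len(table) >= 0.99 * 2 * 200


class TestRenderDensity:
    def test_single_localization(self):
        sr = render_density(_table([155.0], [203.0]), bin_size=10.0)
        assert sr.total == 1
        assert sr.counts[20, 15] == 1

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 1000),
           bin_size=st.sampled_from([5.0, 10.0, 37.0, 100.0]))
    def test_counts_conserved(self, seed, bin_size):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 200))
        table = _table(r.uniform(0, 3200, n), r.uniform(0, 3200, n))
        assert render_density(table, bin_size).total == n

    def test_disc_support_matches_naive_binning_oracle(self, rng):
        n = 10_000
        r = 80.0 * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        x, y = 1600 + r * np.cos(th), 1600 + r * np.sin(th)
        sr = render_density(_table(x, y), bin_size=10.0)
        occupied = np.argwhere(sr.counts > 0)
        extent = occupied.max(axis=0) - occupied.min(axis=0) + 1
        assert np.all(np.abs(extent - 16) <= 1)
        # naive double-loop binning oracle
        oracle = np.zeros_like(sr.counts)
        for xi, yi in zip(x, y):
            oracle[int(yi // 10), int(xi // 10)] += 1
        np.testing.assert_array_equal(sr.counts, oracle)


class TestEstimateResolution:
    def test_precision_limited_dense_sample(self, rng):
        n = 20_000
        table = _table(rng.uniform(1500, 1700, n), rng.uniform(1500, 1700, n),
                       precision=25.0)
        sr = render_density(table, bin_size=10.0)
        res = estimate_resolution(table, sr)
        assert res == pytest.approx(2.355 * 25.0, rel=1e-6)
        assert 55.0 <= res <= 70.0

    def test_precision_term_linear(self, rng):
        n = 20_000
        x = rng.uniform(1500, 1700, n)
        y = rng.uniform(1500, 1700, n)
        sr = render_density(_table(x, y, precision=20.0), bin_size=10.0)
        r1 = estimate_resolution(_table(x, y, precision=20.0), sr)
        r2 = estimate_resolution(_table(x, y, precision=40.0), sr)
        assert r2 == pytest.approx(2 * r1, rel=1e-6)

    def test_sampling_limited_sparse_table(self, rng):
        # 100 localizations over ~1 um^2 at 5 nm precision: Nyquist wins
        n = 100
        x = rng.uniform(0, 1000.0, n)
        y = rng.uniform(0, 1000.0, n)
        table = _table(x, y, precision=5.0, field=(10, 10))
        # force full 1 um^2 support so density = 100 / 1e6 nm^-2 exactly
        sr = SuperResImage(counts=np.ones((10, 10), int), bin_size=100.0)
        assert estimate_resolution(table, sr) == pytest.approx(200.0)

    def test_empty_table_rejected(self):
        table = _table([], [])
        sr = SuperResImage(counts=np.zeros((4, 4), int), bin_size=10.0)
        with pytest.raises(ValueError):
            estimate_resolution(table, sr)
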