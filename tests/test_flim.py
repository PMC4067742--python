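"""TCSPC decay fitting, adaptive binning and lifetime-map summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flimstorm.flim as flim
from flimstorm import (DecayTruth, Irf, MonoExpDecayModel, bin_cube,
                       choose_binning, fit_decay, fit_lifetime_map,
                       lifetime_histogram, region_mean_lifetime,
                       simulate_decay, simulate_tcspc_image)
from flimstorm.flim import (DecayCube, DecayCurve, FlimConfig,
                            InsufficientPhotonsError, LifetimeMap)
from .conftest import grid_search_tau, make_uniform_cube, naive_bin_cube


def _noiseless_curve(tau, irf, total=1_000_000, signal_fraction=1.0):
    """Expected counts (rounded) under the package's own channel model."""
    shape = flim._model_shape(tau, np.fft.rfft(irf.amplitudes),
                              irf.n_channels, irf.channel_width)
    q = signal_fraction * shape + (1 - signal_fraction) / irf.n_channels
    return DecayCurve(counts=np.rint(total * q).astype(int),
                      channel_width=irf.channel_width)


def _map_from_tau(tau_values, mask=None):
    """Construct a LifetimeMap directly from a tau array (summary tests)."""
    tau = np.asarray(tau_values, float)
    ones = np.ones_like(tau)
    converged = np.isfinite(tau)
    if mask is None:
        mask = np.ones_like(tau, dtype=bool)
    return LifetimeMap(tau=tau, amplitude=ones, background=0 * ones,
                       chi2_reduced=ones, photons=ones, converged=converged,
                       mask=np.asarray(mask, bool), binning_factor=0)


class TestChooseBinning:
    def test_matches_direct_arithmetic_oracle(self):
        # uniform 400 photons/pixel: 9 * 400 = 3600 falls in [3500, 5000]
        cube = make_uniform_cube((16, 16), 400)
        assert choose_binning(cube, target_min=3500, target_max=5000) == 1
        # oracle: first b with (2b+1)^2 * 400 >= 3500 for an interior pixel
        oracle = next(b for b in range(4) if (2 * b + 1) ** 2 * 400 >= 3500)
        assert oracle == 1

    def test_no_binning_needed(self):
        cube = make_uniform_cube((16, 16), 4000)
        assert choose_binning(cube) == 0

    def test_cap_reached_for_dim_image(self):
        cube = make_uniform_cube((16, 16), 10)
        assert choose_binning(cube, max_factor=3) == 3

    def test_empty_mask_rejected(self):
        cube = make_uniform_cube((4, 4), 100)
        with pytest.raises(ValueError, match="mask"):
            choose_binning(cube, mask=np.zeros((4, 4), bool))


class TestBinCube:
    def test_zero_factor_is_identity(self, rng):
        cube = DecayCube(counts=rng.integers(0, 50, (4, 4, 8)),
                         channel_width=0.1)
        np.testing.assert_array_equal(bin_cube(cube, 0).counts, cube.counts)

    def test_center_pixel_sums_all_nine(self, rng):
        cube = DecayCube(counts=rng.integers(0, 50, (3, 3, 8)),
                         channel_width=0.1)
        out = bin_cube(cube, 1)
        np.testing.assert_array_equal(out.counts[1, 1],
                                      cube.counts.sum(axis=(0, 1)))

    @pytest.mark.parametrize("b", [1, 2])
    def test_matches_naive_summation_oracle(self, b, rng):
        counts = rng.integers(0, 30, (7, 6, 5))
        cube = DecayCube(counts=counts, channel_width=0.1)
        np.testing.assert_array_equal(bin_cube(cube, b).counts,
                                      naive_bin_cube(counts, b))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), b=st.integers(1, 2))
    def test_linearity(self, seed, b):
        r = np.random.default_rng(seed)
        c1 = r.integers(0, 20, (5, 5, 4))
        c2 = r.integers(0, 20, (5, 5, 4))
        lhs = bin_cube(DecayCube(counts=c1 + c2, channel_width=0.1), b).counts
        rhs = (bin_cube(DecayCube(counts=c1, channel_width=0.1), b).counts
               + bin_cube(DecayCube(counts=c2, channel_width=0.1), b).counts)
        np.testing.assert_array_equal(lhs, rhs)


class TestFitDecay:
    def test_exact_recovery_noiseless(self, delta_irf):
        curve = _noiseless_curve(2.0, delta_irf)
        fit = fit_decay(curve, delta_irf)
        assert fit.converged
        assert fit.tau == pytest.approx(2.0, abs=1e-3)
        assert fit.background < 1.0  # B ~ 0 at 1e6 signal photons

    def test_lsq_recovery_noiseless(self, gauss_irf):
        curve = _noiseless_curve(3.7, gauss_irf, signal_fraction=0.9)
        fit = fit_decay(curve, gauss_irf, method="lsq")
        assert fit.tau == pytest.approx(3.7, abs=0.01)

    def test_agrees_with_grid_search_oracle(self, gauss_irf):
        tau_grid = np.arange(3.0, 4.4, 0.001)
        for seed, tau in [(1, 3.7), (2, 3.3), (3, 3.5)]:
            truth = DecayTruth(tau=tau, amplitude_fraction=0.9,
                               n_photons=5000)
            curve = simulate_decay(truth, gauss_irf, seed)
            fit = fit_decay(curve, gauss_irf)
            tau_oracle, _ = grid_search_tau(curve, gauss_irf, tau_grid)
            assert abs(fit.tau - tau_oracle) <= 0.01

    @pytest.mark.parametrize("tau", [2.5, 3.0, 3.3, 3.7, 4.0])
    def test_parameter_recovery_across_lifetimes(self, tau, gauss_irf):
        """|bias| <= 0.05 ns and SD <= 0.15 ns at 3500-5000 photons."""
        fits = []
        for seed in range(40):
            truth = DecayTruth(tau=tau, amplitude_fraction=0.92,
                               n_photons=4200)
            fits.append(fit_decay(simulate_decay(truth, gauss_irf,
                                                 1000 + seed), gauss_irf).tau)
        fits = np.array(fits)
        assert abs(fits.mean() - tau) <= 0.05
        assert fits.std() <= 0.15

    def test_insufficient_photons_rejected(self, gauss_irf):
        curve = DecayCurve(counts=np.ones(256, int) * 0, channel_width=25 / 256)
        with pytest.raises(InsufficientPhotonsError):
            MonoExpDecayModel(curve, gauss_irf)

    def test_grid_mismatch_rejected(self, gauss_irf):
        curve = DecayCurve(counts=np.full(128, 10), channel_width=25 / 128)
        with pytest.raises(ValueError, match="grid"):
            MonoExpDecayModel(curve, gauss_irf)

    def test_summary_mentions_tau(self, gauss_irf):
        curve = _noiseless_curve(3.3, gauss_irf, total=5000)
        text = fit_decay(curve, gauss_irf).summary()
        assert "tau" in text and "ns" in text


class TestFitLifetimeMap:
    def test_two_region_separation_and_order(self, gauss_irf):
        # monomer-like (3.7 ns) left half vs fibril-like (3.3 ns) right half
        truth = [[DecayTruth(tau=3.7 if j < 4 else 3.3,
                             amplitude_fraction=0.95, n_photons=500)
                  for j in range(8)] for _ in range(8)]
        cube = simulate_tcspc_image(truth, gauss_irf, 0)
        lt = fit_lifetime_map(cube, gauss_irf)
        assert lt.binning_factor >= 1
        left = np.zeros((8, 8), bool); left[:, :4] = True
        mean_left = lt.region_values(left).mean()
        mean_right = lt.region_values(~left).mean()
        assert mean_left > mean_right
        # interior pixels are uncontaminated; edge binning mixes regions
        assert mean_left - mean_right >= 0.3 * 0.75

    def test_all_zero_cube_never_converges(self, gauss_irf):
        cube = DecayCube(counts=np.zeros((4, 4, 256), int),
                         channel_width=25 / 256)
        lt = fit_lifetime_map(cube, gauss_irf)
        assert not lt.converged.any()
        with pytest.raises(ValueError):
            region_mean_lifetime([lt])

    def test_deterministic(self, gauss_irf):
        truth = [[DecayTruth(tau=3.5, n_photons=600)] * 4] * 4
        cube = simulate_tcspc_image(truth, gauss_irf, 3)
        a = fit_lifetime_map(cube, gauss_irf)
        b = fit_lifetime_map(cube, gauss_irf)
        np.testing.assert_array_equal(a.tau, b.tau)


class TestLifetimeHistogram:
    def test_point_mass(self):
        lt = _map_from_tau(np.full((5, 5), 3.5))
        edges, counts, norm = lifetime_histogram(lt, bin_width=0.05)
        assert (counts > 0).sum() == 1
        assert norm.max() == 1.0

    def test_counts_conserved(self, rng):
        lt = _map_from_tau(rng.normal(3.5, 0.1, (10, 10)))
        _, counts, _ = lifetime_histogram(lt, bin_width=0.02)
        assert counts.sum() == 100

    def test_mixture_broader_than_pure(self, rng):
        pure_a = rng.normal(3.3, 0.05, (10, 10))
        pure_b = rng.normal(3.7, 0.05, (10, 10))
        mix = np.concatenate([pure_a[:5], pure_b[:5]])
        sd = lambda m: _map_from_tau(m).region_values().std()
        assert sd(mix) > sd(pure_a) and sd(mix) > sd(pure_b)

    def test_empty_region_allowed(self):
        lt = _map_from_tau(np.full((3, 3), 3.5))
        edges, counts, _ = lifetime_histogram(lt, region=np.zeros((3, 3), bool))
        assert counts.size == 0


class TestRegionMeanLifetime:
    def test_single_uniform_map(self):
        summary = region_mean_lifetime([_map_from_tau(np.full((4, 4), 3.5))])
        assert summary.mean_tau == pytest.approx(3.5)
        assert summary.sem_tau == 0.0
        assert summary.n_images == 1

    def test_hand_checked_three_image_sem(self):
        maps = [_map_from_tau(np.full((3, 3), v)) for v in (3.4, 3.5, 3.6)]
        summary = region_mean_lifetime(maps)
        assert summary.mean_tau == pytest.approx(3.5)
        # direct arithmetic: sd([3.4,3.5,3.6], ddof=1)/sqrt(3) = 0.1/sqrt(3)
        assert summary.sem_tau == pytest.approx(0.1 / np.sqrt(3), rel=1e-9)

    def test_images_weighted_equally_not_by_pixels(self):
        small = _map_from_tau(np.full((2, 2), 3.0))
        big = _map_from_tau(np.full((20, 20), 4.0))
        summary = region_mean_lifetime([small, big])
        assert summary.mean_tau == pytest.approx(3.5)
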