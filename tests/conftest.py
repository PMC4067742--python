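"""Shared fixtures and independent brute-force oracles.

The oracles deliberately recompute quantities by a different route than the
package (direct integration, exhaustive scans, naive loops, grid searches)
so that agreement is evidence of correctness rather than shared code.
"""

import numpy as np
import pytest

from flimstorm import Irf, simulate_irf
from flimstorm.flim import DecayCube


@pytest.fixture(scope="session")
def gauss_irf():
    """Standard instrument response: Gaussian, 0.2 ns FWHM, 256ch/25ns."""
    return simulate_irf(fwhm=0.2, n_channels=256, window=25.0)


@pytest.fixture(scope="session")
def delta_irf():
    """Idealized single-channel IRF at the start of the window."""
    return Irf.delta(n_channels=256, window=25.0, channel=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def truncated_exp_mean(tau: float, window: float) -> float:
    """Mean of an exponential(tau) folded into [0, window), by direct
    numerical integration of the truncated density (independent of the
    closed form asserted in tests)."""
    from scipy.integrate import quad
    norm = 1.0 - np.exp(-window / tau)
    val, _ = quad(lambda x: x * np.exp(-x / tau) / tau / norm, 0, window)
    return val


def grid_search_tau(curve, irf, tau_grid, n_sub: int = 32):
    """Brute-force Poisson-likelihood grid search over tau (B profiled).

    The model shape is rebuilt from scratch: the folded-exponential channel
    kernel is computed by sub-channel quadrature (averaging the plain
    edge-difference kernel over ``n_sub`` in-channel IRF offsets) instead of
    the package's closed form, and the signal fraction is profiled by a
    vectorized golden-section search (concave likelihood).
    Returns (tau_hat, loglik) at the grid maximum.
    """
    counts = np.asarray(curve.counts, float)
    n = counts.size
    dt = curve.channel_width
    window = n * dt

    shapes = _oracle_shape_matrix(tuple(np.round(tau_grid, 9)), irf, n, dt,
                                  window, n_sub)
    # golden-section over signal fraction f, vectorized across tau rows
    lo = np.zeros(len(tau_grid))
    hi = np.ones(len(tau_grid))
    phi = (np.sqrt(5.0) - 1.0) / 2.0

    def loglik(f):
        q = f[:, None] * shapes + (1.0 - f)[:, None] / n
        return (counts * np.log(q)).sum(axis=1)

    for _ in range(70):
        m1 = hi - phi * (hi - lo)
        m2 = lo + phi * (hi - lo)
        better = loglik(m1) > loglik(m2)
        hi = np.where(better, m2, hi)
        lo = np.where(better, lo, m1)
    f_best = 0.5 * (lo + hi)
    ll = loglik(f_best)
    k = int(np.argmax(ll))
    return float(tau_grid[k]), float(ll[k])


_SHAPE_CACHE = {}


def _oracle_shape_matrix(tau_key, irf, n, dt, window, n_sub):
    key = (tau_key, id(irf), n_sub)
    if key not in _SHAPE_CACHE:
        taus = np.asarray(tau_key)
        edges = np.arange(n + 1) * dt
        shapes = np.zeros((taus.size, n))
        offsets = (np.arange(n_sub) + 0.5) / n_sub * dt
        for it, tau in enumerate(taus):
            k = np.zeros(n)
            for u in offsets:  # average over in-channel IRF offset
                e = np.exp(-np.mod(edges - u, window) / tau)
                prob = e[:-1] - e[1:]
                prob[prob < 0] += np.exp(-0.0 / tau) - np.exp(-window / tau)
                k += prob
            k /= k.sum()
            # circular convolution with the IRF, direct FFT
            shapes[it] = np.maximum(np.fft.irfft(
                np.fft.rfft(irf.amplitudes) * np.fft.rfft(k), n=n), 1e-300)
        _SHAPE_CACHE[key] = shapes
    return _SHAPE_CACHE[key]


def flood_fill_label(binary: np.ndarray) -> np.ndarray:
    """Hand-written 8-connected component labelling by BFS flood fill."""
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    ny, nx = binary.shape
    for i0 in range(ny):
        for j0 in range(nx):
            if binary[i0, j0] and labels[i0, j0] == 0:
                current += 1
                stack = [(i0, j0)]
                labels[i0, j0] = current
                while stack:
                    i, j = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii, jj = i + di, j + dj
                            if (0 <= ii < ny and 0 <= jj < nx
                                    and binary[ii, jj] and labels[ii, jj] == 0):
                                labels[ii, jj] = current
                                stack.append((ii, jj))
    return labels


def max_pairwise_distance(points: np.ndarray) -> float:
    """Exhaustive O(n^2) maximum pairwise distance."""
    points = np.asarray(points, float)
    best = 0.0
    for i in range(len(points) - 1):
        d = np.sqrt(((points[i + 1:] - points[i]) ** 2).sum(axis=1))
        best = max(best, float(d.max()))
    return best


def naive_bin_cube(counts: np.ndarray, b: int) -> np.ndarray:
    """Naive nested-loop sliding-window channel-wise summation."""
    ny, nx, nt = counts.shape
    out = np.zeros_like(counts)
    for i in range(ny):
        for j in range(nx):
            acc = np.zeros(nt, dtype=counts.dtype)
            for di in range(-b, b + 1):
                for dj in range(-b, b + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx:
                        acc += counts[ii, jj]
            out[i, j] = acc
    return out


def make_uniform_cube(shape, photons_per_pixel, n_channels=16,
                      channel_width=25.0 / 16):
    """Cube with all photons in channel 0 (photon-count plumbing tests)."""
    counts = np.zeros(shape + (n_channels,), dtype=np.int64)
    counts[..., 0] = photons_per_pixel
    return DecayCube(counts=counts, channel_width=channel_width)
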