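"""Seeded generators for every input the analysis pipeline consumes.

The simulators reproduce the photon statistics the downstream analysis
assumes: per-pixel TCSPC photon-arrival histograms under a monoexponential
decay convolved with a finite-width instrument response and Poisson counting
noise; widefield movies of stochastically blinking fluorophores decorating
compact aggregate shapes with camera noise; and sigmoidal lifetime-versus-
time aggregation traces with a lag phase.

Conventions
-----------
* Times are in nanoseconds (TCSPC) or hours (kinetics), positions in nm.
* The TCSPC window is set by the pulsed-laser repetition rate; the default
  40 MHz source gives a 25 ns window, discretized into 256 channels.
* Photons arriving after the end of the window fold back periodically
  (incomplete decay), which makes the per-period arrival distribution an
  exactly truncated exponential.  Re-excitation pile-up is not modelled:
  count rates in the emulated experiments are kept below 1% of the
  repetition rate, where pile-up is negligible.
* Camera pixel (i, j) covers [j*a, (j+1)*a) x [i*a, (i+1)*a) nm (half-open,
  0-based); x runs along columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .flim import DecayCube, DecayCurve
from .kinetics import KineticTrace

__all__ = [
    "Irf",
    "DecayTruth",
    "EmitterSet",
    "CameraModel",
    "simulate_irf",
    "sample_arrival_times",
    "simulate_decay",
    "simulate_tcspc_image",
    "simulate_aggregate_emitters",
    "simulate_blinking_movie",
    "simulate_lifetime_timecourse",
]

DEFAULT_WINDOW_NS = 25.0  # 1 / 40 MHz
DEFAULT_N_CHANNELS = 256


@dataclass(frozen=True)
class Irf:
    """Discretized instrument-response function on the TCSPC channel grid.

    Attributes
    ----------
    channel_width : float
        Width of one TCSPC channel in ns.
    amplitudes : ndarray
        Non-negative per-channel amplitudes, normalized to sum to 1.
    """

    channel_width: float
    amplitudes: np.ndarray

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1 or amps.size < 1:
            raise ValueError("IRF amplitudes must be a 1-D array")
        if np.any(amps < 0):
            raise ValueError("IRF amplitudes must be non-negative")
        total = amps.sum()
        if total <= 0:
            raise ValueError("IRF amplitudes must not all be zero")
        object.__setattr__(self, "amplitudes", amps / total)

    @property
    def n_channels(self) -> int:
        return self.amplitudes.size

    @property
    def window(self) -> float:
        return self.channel_width * self.n_channels

    @property
    def centroid(self) -> float:
        """First moment of the IRF in ns (channel centers)."""
        centers = (np.arange(self.n_channels) + 0.5) * self.channel_width
        return float(np.dot(self.amplitudes, centers))

    @classmethod
    def delta(cls, n_channels: int = DEFAULT_N_CHANNELS,
              window: float = DEFAULT_WINDOW_NS, channel: int = 0) -> "Irf":
        """An idealized single-channel (delta) IRF, mainly for testing."""
        amps = np.zeros(n_channels)
        amps[channel] = 1.0
        return cls(channel_width=window / n_channels, amplitudes=amps)


@dataclass(frozen=True)
class DecayTruth:
    """Ground truth for one pixel's photon-arrival histogram.

    ``amplitude_fraction`` of the photons follow IRF (x) exp(-t/tau); the
    remaining ``1 - amplitude_fraction`` are uniform background counts.
    """

    tau: float
    amplitude_fraction: float = 1.0
    n_photons: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.amplitude_fraction <= 1.0:
            raise ValueError("amplitude_fraction must lie in [0, 1]")
        if self.n_photons < 0:
            raise ValueError("n_photons must be non-negative")

    @property
    def background_fraction(self) -> float:
        return 1.0 - self.amplitude_fraction


@dataclass(frozen=True)
class EmitterSet:
    """Ground-truth blinking fluorophores decorating aggregate shapes."""

    positions: np.ndarray          # (n, 2) float nm, columns (x, y)
    photons_mean: float            # expected photons per on-frame
    on_probability: float          # per-frame Bernoulli on-probability
    shape_label: np.ndarray = field(default=None)  # aggregate id per emitter

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2) in nm")
        object.__setattr__(self, "positions", pos)
        if not 0.0 <= self.on_probability <= 1.0:
            raise ValueError("on_probability must lie in [0, 1]")
        if self.photons_mean <= 0:
            raise ValueError("photons_mean must be positive")
        labels = self.shape_label
        if labels is None:
            labels = np.zeros(len(pos), dtype=int)
        labels = np.asarray(labels)
        if labels.shape != (len(pos),):
            raise ValueError("one shape_label per emitter required")
        object.__setattr__(self, "shape_label", labels)

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def concatenate(cls, sets: list["EmitterSet"]) -> "EmitterSet":
        """Merge emitter sets (sharing photon/on parameters), relabelling shapes."""
        pos = np.vstack([s.positions for s in sets])
        labels = np.concatenate(
            [np.full(len(s), i, dtype=int) for i, s in enumerate(sets)])
        return cls(positions=pos, photons_mean=sets[0].photons_mean,
                   on_probability=sets[0].on_probability, shape_label=labels)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera and optics parameters for the blinking-movie simulator.

    The gain register is approximated by Gaussian read noise on top of
    Poisson photon statistics, which is adequate at the photon levels
    simulated here (hundreds to thousands of photons per localization).
    """

    pixel_size: float = 100.0        # nm / pixel
    psf_sigma: float = 150.0         # nm, Gaussian PSF standard deviation
    background_rate: float = 2.0     # photons / pixel / frame
    read_noise_sd: float = 0.0       # photons, Gaussian approximation

    def __post_init__(self):
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.background_rate < 0 or self.read_noise_sd < 0:
            raise ValueError("noise rates must be non-negative")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_irf(fwhm: float, n_channels: int = DEFAULT_N_CHANNELS,
                 window: float = DEFAULT_WINDOW_NS) -> Irf:
    """Gaussian surrogate for a measured instrument response.

    The IRF is a Gaussian of the given FWHM (ns) centred at ``window / 4``,
    integrated over each TCSPC channel and normalized to unit sum.
    """
    if fwhm <= 0 or window <= 0:
        raise ValueError("fwhm and window must be positive")
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    center = window / 4.0
    edges = np.linspace(0.0, window, n_channels + 1)
    cdf = 0.5 * (1.0 + erf((edges - center) / (sigma * np.sqrt(2.0))))
    amps = np.diff(cdf)
    return Irf(channel_width=window / n_channels, amplitudes=amps)


def sample_arrival_times(truth: DecayTruth, irf: Irf, seed) -> np.ndarray:
    """Draw continuous photon-arrival times (ns) within the TCSPC window.

    Signal photons are the sum of an IRF-distributed excitation delay and an
    exponential(tau) emission delay, folded periodically into the window;
    background photons are uniform over the window.
    """
    rng = _as_rng(seed)
    n = truth.n_photons
    window = irf.window
    n_signal = rng.binomial(n, truth.amplitude_fraction) if n else 0
    # IRF delay: channel index from the discrete amplitudes, uniform within.
    channels = rng.choice(irf.n_channels, size=n_signal, p=irf.amplitudes)
    t_irf = (channels + rng.random(n_signal)) * irf.channel_width
    t_signal = np.mod(t_irf + rng.exponential(truth.tau, size=n_signal), window)
    t_background = rng.uniform(0.0, window, size=n - n_signal)
    times = np.concatenate([t_signal, t_background])
    rng.shuffle(times)
    return times


def simulate_decay(truth: DecayTruth, irf: Irf, seed) -> DecayCurve:
    """Simulate one pixel's TCSPC histogram with exactly ``n_photons`` counts."""
    times = sample_arrival_times(truth, irf, seed)
    edges = np.linspace(0.0, irf.window, irf.n_channels + 1)
    counts, _ = np.histogram(times, bins=edges)
    return DecayCurve(counts=counts, channel_width=irf.channel_width)


def simulate_tcspc_image(truth_map, irf: Irf, seed) -> DecayCube:
    """Assemble per-pixel decays into the image cube that FLIM fitting consumes.

    Parameters
    ----------
    truth_map : nested sequence of DecayTruth
        Rectangular (rows x cols) grid of per-pixel ground truths.
    """
    rng = _as_rng(seed)
    rows = list(truth_map)
    if not rows:
        raise ValueError("truth_map must be non-empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("truth_map must be rectangular")
    counts = np.zeros((len(rows), width, irf.n_channels), dtype=np.int64)
    for i, row in enumerate(rows):
        for j, truth in enumerate(row):
            counts[i, j] = simulate_decay(truth, irf, rng).counts
    return DecayCube(counts=counts, channel_width=irf.channel_width)


def simulate_aggregate_emitters(kind: str, size: float, n_fluorophores: int,
                                center=(0.0, 0.0), seed=None) -> EmitterSet:
    """Scatter fluorophore positions uniformly over a compact aggregate shape.

    ``sphere`` places emitters uniformly in a disc of diameter ``size`` (the
    2-D projection of a spherical aggregate).  ``rod`` places them in an
    elongated rectangle of width ``size / 3`` whose diagonal equals ``size``,
    so the longest dimension (Feret diameter) of either shape is ``size``.
    Orientation of rods is randomized.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if n_fluorophores < 1:
        raise ValueError("need at least one fluorophore")
    rng = _as_rng(seed)
    cx, cy = center
    if kind == "sphere":
        r = 0.5 * size * np.sqrt(rng.random(n_fluorophores))
        theta = rng.uniform(0, 2 * np.pi, n_fluorophores)
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    elif kind == "rod":
        width = size / 3.0
        length = np.sqrt(size ** 2 - width ** 2)
        local = np.column_stack([
            rng.uniform(-length / 2, length / 2, n_fluorophores),
            rng.uniform(-width / 2, width / 2, n_fluorophores),
        ])
        phi = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        xy = local @ rot.T
    else:
        raise ValueError(f"unknown aggregate kind {kind!r}")
    xy += np.array([cx, cy])
    return EmitterSet(positions=xy, photons_mean=2000.0, on_probability=0.01)


def simulate_blinking_movie(emitters: EmitterSet, camera: CameraModel,
                            n_frames: int, shape, seed) -> np.ndarray:
    """Render a widefield movie of stochastically blinking fluorophores.

    Each emitter turns on independently per frame with ``on_probability``
    (memoryless blinking).  On-emitters emit Poisson(photons_mean) photons
    whose detected positions are Gaussian around the true position with the
    camera's PSF sigma, binned into pixels.  Poisson background and Gaussian
    read noise are added; the returned stack is clipped to be non-negative.

    Parameters
    ----------
    shape : (ny, nx)
        Frame size in pixels.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _as_rng(seed)
    ny, nx = shape
    a = camera.pixel_size
    movie = np.zeros((n_frames, ny, nx), dtype=float)
    n_em = len(emitters)
    for f in range(n_frames):
        frame = rng.poisson(camera.background_rate, size=(ny, nx)).astype(float)
        on = rng.random(n_em) < emitters.on_probability
        for idx in np.flatnonzero(on):
            n_ph = rng.poisson(emitters.photons_mean)
            if n_ph == 0:
                continue
            x0, y0 = emitters.positions[idx]
            px = rng.normal(x0, camera.psf_sigma, n_ph)
            py = rng.normal(y0, camera.psf_sigma, n_ph)
            cols = np.floor(px / a).astype(int)
            rows = np.floor(py / a).astype(int)
            keep = (cols >= 0) & (cols < nx) & (rows >= 0) & (rows < ny)
            np.add.at(frame, (rows[keep], cols[keep]), 1.0)
        if camera.read_noise_sd > 0:
            frame += rng.normal(0.0, camera.read_noise_sd, size=(ny, nx))
        movie[f] = frame
    return np.clip(movie, 0.0, None)


def simulate_lifetime_timecourse(params, times, noise_sd: float, seed=None,
                                 kind: str = "lifetime") -> KineticTrace:
    """Sigmoidal lifetime-versus-time aggregation trace with Gaussian noise.

    Parameters
    ----------
    params : mapping or object with L0, Linf, k, t50
        Decreasing-sigmoid truth: L(t) = Linf + (L0-Linf)/(1+exp(k (t-t50))).
    times : array-like, hours, sorted ascending
    noise_sd : float, ns
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    get = params.get if hasattr(params, "get") else lambda k: getattr(params, k)
    L0, Linf, k, t50 = (float(get(name)) for name in ("L0", "Linf", "k", "t50"))
    values = Linf + (L0 - Linf) / (1.0 + np.exp(k * (times - t50)))
    if noise_sd > 0:
        values = values + _as_rng(seed).normal(0.0, noise_sd, size=times.size)
    return KineticTrace(times=times, values=values, kind=kind)
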