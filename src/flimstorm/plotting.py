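"""Diagnostic plots for fits, lifetime maps and reconstructions."""

from __future__ import annotations

import numpy as np


def plot_decay_fit(curve, irf, fit, ax=None):
    """Observed histogram, fitted model and residual panel (log counts)."""
    import matplotlib.pyplot as plt
    from .flim import _model_shape

    if ax is None:
        _, ax = plt.subplots()
    t = (np.arange(curve.n_channels) + 0.5) * curve.channel_width
    ax.semilogy(t, np.maximum(curve.counts, 0.5), ".", ms=3, color="0.5",
                label="photons")
    shape = _model_shape(fit.tau, np.fft.rfft(irf.amplitudes),
                         curve.n_channels, curve.channel_width)
    model = fit.amplitude * shape + fit.background
    ax.semilogy(t, np.maximum(model, 0.5), "-", color="C3",
                label=f"fit: tau = {fit.tau:.2f} ns")
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("counts / channel")
    ax.legend(frameon=False)
    return ax


def plot_lifetime_map(lifetime_map, ax=None, vmin=3.0, vmax=4.0):
    """Color-coded lifetime image (ns); non-converged pixels masked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tau = np.where(lifetime_map.converged, lifetime_map.tau, np.nan)
    im = ax.imshow(tau, cmap="rainbow_r", vmin=vmin, vmax=vmax)
    ax.figure.colorbar(im, ax=ax, label="lifetime (ns)")
    ax.set_title(f"binning factor {lifetime_map.binning_factor}")
    return ax


def plot_superres(sr_image, ax=None):
    """Localization density histogram (the superresolution image)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent_x = sr_image.counts.shape[1] * sr_image.bin_size
    extent_y = sr_image.counts.shape[0] * sr_image.bin_size
    im = ax.imshow(sr_image.counts, cmap="hot", origin="lower",
                   extent=(0, extent_x, 0, extent_y))
    ax.figure.colorbar(im, ax=ax, label="localizations / bin")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    return ax


def plot_sigmoid_fit(trace, fit, ax=None):
    """Kinetic trace with its sigmoid fit and the lag-time tangent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.times, trace.values, "o", ms=4, color="0.3", label="data")
    dense = np.linspace(trace.times[0], trace.times[-1], 200)
    ax.plot(dense, fit.predict(dense), "-", color="C0",
            label=f"fit: lag = {fit.lag:.2f} hr")
    if fit.lag > 0:
        ax.axvline(fit.lag, ls=":", color="C3")
    ax.set_xlabel("time (hr)")
    ax.set_ylabel(trace.kind)
    ax.legend(frameon=False)
    return ax
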