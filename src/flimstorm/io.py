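"""Readers and writers for the pipeline's on-disk formats.

TCSPC cubes and movies travel as multi-page TIFF (16-bit counts); lifetime
maps as float32 TIFF (ns) with a per-pixel CSV; IRFs and kinetic traces as
two-/multi-column CSV; localization tables as CSV following common SMLM
column conventions; superresolution images as 16-bit TIFF with a JSON
metadata sidecar.  Every writer round-trips losslessly through its paired
reader (counts exactly, floats to full precision in CSV).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim import DecayCube, LifetimeMap
from .kinetics import KineticTrace
from .storm import LocalizationTable, SuperResImage


# -- TCSPC cubes ------------------------------------------------------------

def write_decay_cube(path, cube: DecayCube) -> None:
    """Write a (Y, X, T) cube as a T-page TIFF of uint16 counts."""
    pages = np.moveaxis(cube.counts, 2, 0)
    if pages.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed 16-bit range")
    tifffile.imwrite(path, pages.astype(np.uint16),
                     metadata={"channel_width_ns": cube.channel_width})


def read_decay_cube(path, channel_width: float = None) -> DecayCube:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if channel_width is None:
        channel_width = float(meta.get("channel_width_ns"))
    return DecayCube(counts=np.moveaxis(pages, 0, 2).astype(np.int64),
                     channel_width=channel_width)


# -- movies -----------------------------------------------------------------

def write_movie(path, movie: np.ndarray) -> None:
    """Write a (frames, ny, nx) stack as multi-page uint16 TIFF."""
    tifffile.imwrite(path, np.clip(np.rint(movie), 0, 65535).astype(np.uint16))


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


# -- IRF --------------------------------------------------------------------

def write_irf(path, irf) -> None:
    """Two-column CSV (time_ns, amplitude), channel centers."""
    t = (np.arange(irf.n_channels) + 0.5) * irf.channel_width
    pd.DataFrame({"time_ns": t, "amplitude": irf.amplitudes}).to_csv(
        path, index=False)


def read_irf(path):
    from .synth import Irf
    df = pd.read_csv(path)
    t = df["time_ns"].to_numpy(float)
    dt = t[1] - t[0]
    return Irf(channel_width=float(dt), amplitudes=df["amplitude"].to_numpy(float))


# -- lifetime maps ----------------------------------------------------------

def write_lifetime_map(path_tiff, path_csv, lifetime_map: LifetimeMap) -> None:
    tifffile.imwrite(path_tiff, lifetime_map.tau.astype(np.float32),
                     metadata={"binning_factor": lifetime_map.binning_factor})
    ii, jj = np.nonzero(lifetime_map.mask)
    pd.DataFrame({
        "row": ii, "col": jj,
        "tau_ns": lifetime_map.tau[ii, jj],
        "amplitude": lifetime_map.amplitude[ii, jj],
        "background": lifetime_map.background[ii, jj],
        "chi2_reduced": lifetime_map.chi2_reduced[ii, jj],
        "photons": lifetime_map.photons[ii, jj],
        "converged": lifetime_map.converged[ii, jj],
    }).to_csv(path_csv, index=False)


# -- localization tables ----------------------------------------------------

def write_localizations(path, table: LocalizationTable) -> None:
    table.data.to_csv(path, index=False)
    meta = {"pixel_size_nm": table.pixel_size,
            "field_shape": list(table.field_shape),
            "n_detected": table.n_detected, "n_rejected": table.n_rejected}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_localizations(path) -> LocalizationTable:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return LocalizationTable(data=df, pixel_size=meta["pixel_size_nm"],
                             field_shape=tuple(meta["field_shape"]),
                             n_detected=meta.get("n_detected", 0),
                             n_rejected=meta.get("n_rejected", 0))


# -- superresolution images -------------------------------------------------

def write_sr_image(path_tiff, sr: SuperResImage) -> None:
    tifffile.imwrite(path_tiff, np.clip(sr.counts, 0, 65535).astype(np.uint16))
    meta = {"bin_size_nm": sr.bin_size, "origin_nm": list(sr.origin)}
    Path(str(path_tiff) + ".json").write_text(json.dumps(meta))


def read_sr_image(path_tiff) -> SuperResImage:
    counts = tifffile.imread(path_tiff).astype(np.int64)
    meta = json.loads(Path(str(path_tiff) + ".json").read_text())
    return SuperResImage(counts=counts, bin_size=meta["bin_size_nm"],
                         origin=tuple(meta["origin_nm"]))


# -- kinetic traces ---------------------------------------------------------

def write_trace(path, trace: KineticTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace(path) -> KineticTrace:
    return KineticTrace.from_frame(pd.read_csv(path))
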