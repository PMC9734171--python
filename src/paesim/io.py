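"""File exchange: HDF5 traces and phantoms, CSV spectra, TIFF maps."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .imaging import FunctionalMaps
from .phantom import Phantom, VesselSegment
from .trace import SpectralDensity, TimeTrace

__all__ = [
    "save_trace", "load_trace",
    "save_spectrum", "load_spectrum",
    "save_maps", "load_maps",
    "save_phantom", "load_phantom",
]


def save_trace(path, trace: TimeTrace, name: str = "trace") -> None:
    """Write a trace to HDF5 with sample_rate/unit/t0 attributes."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=trace.samples)
        ds.attrs["sample_rate"] = trace.sample_rate
        ds.attrs["unit"] = trace.unit
        ds.attrs["t0"] = trace.t0


def load_trace(path, name: str = "trace") -> TimeTrace:
    with h5py.File(path, "r") as f:
        ds = f[name]
        return TimeTrace(ds[...], float(ds.attrs["sample_rate"]),
                         str(ds.attrs["unit"]), float(ds.attrs["t0"]))


def save_spectrum(path, spectrum: SpectralDensity) -> None:
    """Write a spectral density as CSV with columns freq_hz, value, unit."""
    pd.DataFrame({
        "freq_hz": spectrum.freqs,
        "value": spectrum.values,
        "unit": spectrum.unit,
    }).to_csv(path, index=False)


def load_spectrum(path) -> SpectralDensity:
    df = pd.read_csv(path)
    return SpectralDensity(df["freq_hz"].to_numpy(),
                           df["value"].to_numpy(), str(df["unit"].iloc[0]))


def save_maps(path, maps: FunctionalMaps) -> None:
    """Write the functional maps as a multi-page TIFF.

    Page order: C_Hb, depth, sO2, mask (float32; NaN preserved).
    """
    pages = np.stack([
        np.asarray(maps.chb_map, dtype=np.float32),
        np.asarray(maps.depth_map, dtype=np.float32),
        np.asarray(maps.so2_map, dtype=np.float32),
        np.asarray(maps.mask, dtype=np.float32),
    ])
    tifffile.imwrite(path, pages, photometric="minisblack")


def load_maps(path) -> FunctionalMaps:
    pages = tifffile.imread(path)
    return FunctionalMaps(pages[0], pages[1], pages[2],
                          pages[3] > 0.5, geometry=None)


def save_phantom(path, phantom: Phantom) -> None:
    """Serialize vessel segments to HDF5 groups (one group per segment)."""
    with h5py.File(path, "w") as f:
        f.attrs["bounds"] = phantom.bounds
        for i, seg in enumerate(phantom.segments):
            g = f.create_group(f"segment_{i:04d}")
            g.create_dataset("centerline", data=seg.centerline)
            g.attrs["radius"] = seg.radius
            g.attrs["sO2"] = seg.sO2
            g.attrs["c_hb"] = seg.c_hb
            g.attrs["kind"] = seg.kind


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        segments = []
        for name in sorted(k for k in f if k.startswith("segment_")):
            g = f[name]
            segments.append(VesselSegment(
                g["centerline"][...], float(g.attrs["radius"]),
                float(g.attrs["sO2"]), float(g.attrs["c_hb"]),
                str(g.attrs["kind"])))
        return Phantom(segments=segments, bounds=np.asarray(f.attrs["bounds"]))
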