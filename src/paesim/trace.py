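"""Core signal containers: uniformly sampled time traces and one-sided spectra.

Every signal in the simulation chain — acoustic pressure, optical phase,
heterodyne carrier, hydrophone voltage — is a :class:`TimeTrace`: a uniformly
sampled array with a sample rate and a unit tag.  Spectral quantities
(phase-noise density, acoustic response, noise-equivalent pressure density)
are :class:`SpectralDensity` objects on a one-sided frequency grid.  Masked
(unreliable) spectral bins are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Recognised unit tags for time traces.
TRACE_UNITS = ("Pa", "rad", "carrier-arb", "V")


@dataclass
class TimeTrace:
    """A uniformly sampled real or complex signal.

    Parameters
    ----------
    samples
        Signal values; real for pressure/phase/carrier/voltage records.
    sample_rate
        Sampling rate in Hz (> 0).
    unit
        One of ``"Pa"``, ``"rad"``, ``"carrier-arb"``, ``"V"``.
    t0
        Start time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    unit: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.unit not in TRACE_UNITS:
            raise ValueError(f"unit must be one of {TRACE_UNITS}, got {self.unit!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    def with_samples(self, samples: np.ndarray, unit: str | None = None,
                     t0: float | None = None) -> "TimeTrace":
        """Return a copy with replaced samples (and optionally unit/t0)."""
        return replace(
            self,
            samples=np.asarray(samples),
            unit=self.unit if unit is None else unit,
            t0=self.t0 if t0 is None else t0,
        )

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.abs(self.samples) ** 2)))


@dataclass
class SpectralDensity:
    """Amplitude density on a one-sided frequency grid.

    ``values`` carries an amplitude density (e.g. rad·Hz^-1/2, Pa·Hz^-1/2) or
    an amplitude-response ratio (rad/Pa).  NaN marks masked bins.
    """

    freqs: np.ndarray
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must be congruent 1-D arrays")
        if self.freqs.size and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        """Boolean selector of bins inside ``band`` (inclusive)."""
        lo, hi = band
        return (self.freqs >= lo) & (self.freqs <= hi)

    def band_mean(self, band: tuple[float, float]) -> float:
        """Mean of unmasked values inside ``band``."""
        sel = self.band_slice(band)
        vals = self.values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no unmasked bins in requested band")
        return float(vals.mean())

    def interp_to(self, freqs: np.ndarray) -> np.ndarray:
        """Linearly interpolate values onto ``freqs`` (NaN outside support)."""
        freqs = np.asarray(freqs, dtype=float)
        good = np.isfinite(self.values)
        out = np.interp(freqs, self.freqs[good], self.values[good],
                        left=np.nan, right=np.nan)
        out[(freqs < self.freqs[0]) | (freqs > self.freqs[-1])] = np.nan
        return out


@dataclass(frozen=True)
class AcousticTone:
    """A single-frequency acoustic stimulus p(t) = -p0 cos(Omega t + phase)."""

    p0: float
    Omega: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ValueError("p0 must be non-negative")
        if not self.Omega > 0:
            raise ValueError("Omega must be positive")

    def sample(self, n: int, sample_rate: float, t0: float = 0.0) -> TimeTrace:
        """Render the tone as a pressure trace of ``n`` samples."""
        t = t0 + np.arange(n) / sample_rate
        return TimeTrace(-self.p0 * np.cos(self.Omega * t + self.phase),
                         sample_rate, "Pa", t0)
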