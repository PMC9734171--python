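"""Laser ultrasound sensor model.

A short linear-cavity fiber laser converts acoustic pressure into an optical
phase modulation.  Pressure p modulates the round-trip optical path
dL/dp = S_m·L_opt; the cavity resonance condition (omega0/c)·L_opt = 2·pi·m
then turns the path change into a lasing-frequency shift
d(omega0)/dL = -omega0/L_opt.  Integrating the frequency shift yields a phase
modulation amplified by the gain factor G(Omega) = omega0/Omega — the ratio of
the optical carrier frequency to the acoustic frequency, ~2e7 at 10 MHz.

The two orthogonal polarization modes of the fiber lase at slightly different
frequencies (beat omega_b ≈ 2·pi×1.74 GHz) and experience opposite phase
shifts ±dtheta under the torsional-radial acoustic deformation, so the
heterodyne beat at the photodetector carries the doubled modulation
2·dtheta(t).  The beat is synthesized here directly at a configurable
intermediate frequency, mirroring the downshift-to-baseband receiver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import C_LIGHT
from .trace import TimeTrace

__all__ = [
    "SensorSpec",
    "gain_factor",
    "sm_spectrum",
    "phase_response_spectrum",
    "pressure_to_phase",
    "synthesize_beat",
]


@dataclass
class SensorSpec:
    """Physical and optical parameters of the laser ultrasound sensor.

    Attributes
    ----------
    L_opt
        Round-trip optical path length (m).  Default: 2 mm grating spacing,
        4 mm physical round trip, effective index 1.468 → 5.872e-3 m.
    omega0
        Lasing angular frequency (rad/s), default 2·pi×193 THz (1550 nm).
    Sm_base
        Low-frequency acoustic modulation coefficient (fractional path change
        per Pa).  Default 2e-12 Pa^-1 (~2e-6 per MPa, typical for bare silica
        sensors), which reproduces an in-band phase response of ~1e-4 rad/Pa.
    f_res, Q_res
        Mechanical resonance of the silica fiber (Hz) and its quality factor.
    omega_b
        Polarization beat angular frequency (rad/s); metadata describing the
        physical carrier, the simulated carrier sits at an IF.
    Nq_density
        Quadrature (phase) noise amplitude density, rad·Hz^-1/2.
    Ni_density
        In-phase (relative intensity) noise density, Hz^-1/2.
    f_relax, relax_depth
        Relaxation-oscillation frequency (Hz) and relative intensity
        modulation depth of the laser.
    oneoverf_corner
        Optional corner frequency (Hz) below which excess low-frequency phase
        noise rises as 1/f; 0 disables it.
    """

    L_opt: float = 5.872e-3
    omega0: float = 2 * math.pi * 193e12
    Sm_base: float = 2e-12
    f_res: float = 22e6
    Q_res: float = 5.0
    omega_b: float = 2 * math.pi * 1.74e9
    Nq_density: float = 1.5e-7
    Ni_density: float = 0.0
    f_relax: float = 1.7e6
    relax_depth: float = 0.0
    oneoverf_corner: float = 0.0

    def __post_init__(self) -> None:
        if not (self.omega0 > 0 and self.L_opt > 0 and self.omega_b > 0):
            raise ValueError("omega0, L_opt and omega_b must be positive")
        if self.Nq_density < 0 or self.Ni_density < 0 or self.relax_depth < 0:
            raise ValueError("noise densities must be non-negative")
        if not (self.f_res > 0 and self.Q_res > 0):
            raise ValueError("f_res and Q_res must be positive")

    @property
    def mode_number(self) -> int:
        """Longitudinal mode index m from (omega0/c)·L_opt = 2·pi·m."""
        m = int(round(self.omega0 * self.L_opt / (2 * math.pi * C_LIGHT)))
        return m

    def resonance_mismatch(self) -> float:
        """Fractional deviation of omega0·L_opt/c from the nearest 2·pi·m."""
        x = self.omega0 * self.L_opt / (2 * math.pi * C_LIGHT)
        return abs(x - round(x)) / x

    def quiet(self) -> "SensorSpec":
        """Copy with all noise sources disabled (for noiseless round trips)."""
        return replace(self, Nq_density=0.0, Ni_density=0.0, relax_depth=0.0,
                       oneoverf_corner=0.0)


def _check_omega(Omega) -> np.ndarray:
    Omega = np.asarray(Omega, dtype=float)
    if np.any(Omega <= 0):
        raise ValueError("acoustic angular frequency must be positive")
    return Omega


def gain_factor(spec: SensorSpec, Omega) -> np.ndarray | float:
    """Frequency-to-phase transduction gain G(Omega) = omega0/Omega.

    Scalar in, scalar out; array in, array out.  Raises ``ValueError`` for
    non-positive frequencies.
    """
    Om = _check_omega(Omega)
    g = spec.omega0 / Om
    return float(g) if np.isscalar(Omega) else g


def sm_spectrum(spec: SensorSpec, Omega) -> np.ndarray | float:
    """Acoustic modulation coefficient S_m(Omega) in Pa^-1.

    Modeled as the base coefficient times the magnitude of a single-pole
    (second-order) mechanical resonance with unit low-frequency gain:

        H(Omega) = 1 / (1 - (Omega/Omega_r)^2 + i·Omega/(Q·Omega_r))

    peaking at f_res with |H| = Q on resonance and rolling off ∝ Omega^-2
    above it.
    """
    Om = _check_omega(Omega)
    x = Om / (2 * math.pi * spec.f_res)
    h = 1.0 / np.sqrt((1.0 - x**2) ** 2 + (x / spec.Q_res) ** 2)
    s = spec.Sm_base * h
    return float(s) if np.isscalar(Omega) else s


def phase_response_spectrum(spec: SensorSpec, Omega) -> np.ndarray | float:
    """Doubled phase response Theta(Omega) = 2·S_m(Omega)·G(Omega) (rad/Pa).

    The factor 2 comes from the opposite phase shifts of the two polarization
    modes: the heterodyne beat carries 2·dtheta.
    """
    theta = 2.0 * np.multiply(sm_spectrum(spec, Omega), gain_factor(spec, Omega))
    return float(theta) if np.isscalar(Omega) else theta


def pressure_to_phase(spec: SensorSpec, p: TimeTrace) -> TimeTrace:
    """Single-polarization laser phase modulation dtheta(t) from pressure.

    Computed in the frequency domain: each spectral component of p is scaled
    by S_m(Omega)·G(Omega) and rotated by +pi/2 (the frequency-to-phase
    integration turns a -cos pressure into a +sin phase).  The DC component
    maps to zero.  The heterodyne carrier applies ±dtheta to the two
    polarizations; see :func:`synthesize_beat`.
    """
    if p.unit != "Pa":
        raise ValueError(f"expected a pressure trace (Pa), got unit {p.unit!r}")
    n = len(p)
    spec_p = np.fft.rfft(p.samples)
    f = np.fft.rfftfreq(n, d=p.dt)
    h = np.zeros_like(spec_p)
    pos = f > 0
    Om = 2 * math.pi * f[pos]
    # +i = e^{+i pi/2}: p = -p0 cos(Omega t) -> dtheta = p0 Sm G sin(Omega t)
    h[pos] = 1j * sm_spectrum(spec, Om) * gain_factor(spec, Om)
    dtheta = np.fft.irfft(spec_p * h, n=n)
    return p.with_samples(dtheta, unit="rad")


def synthesize_beat(
    spec: SensorSpec,
    dtheta: TimeTrace,
    f_if: float,
    rng_seed: int,
    extra_carrier_phase: np.ndarray | None = None,
) -> TimeTrace:
    """Synthesize the heterodyne beat carrier at an intermediate frequency.

    Returns the real carrier

        v(t) = A(t)·cos(2·pi·f_if·t + 2·dtheta(t) + phi_n(t) + theta0)

    where ``A(t) = 1 + relax_depth·sin(2·pi·f_relax·t) + n_i(t)`` carries the
    laser intensity noise (relaxation-oscillation tone plus white amplitude
    noise of density ``Ni_density``) and ``phi_n(t)`` is white quadrature
    phase noise of density ``Nq_density`` (optionally with a 1/f excess below
    ``oneoverf_corner``).  ``theta0`` is drawn uniformly from [0, 2·pi).

    ``extra_carrier_phase`` adds a common-mode carrier phase (e.g. a slow
    frequency drift shared by both polarizations) that is *not* doubled.

    Raises ``ValueError`` if ``f_if`` does not clear the modulation bandwidth
    or violates Nyquist.
    """
    if dtheta.unit != "rad":
        raise ValueError("dtheta must be a phase trace (rad)")
    fs = dtheta.sample_rate
    if not (0 < f_if < fs / 2):
        raise ValueError(f"f_if={f_if} violates Nyquist for sample rate {fs}")
    # the modulation must fit under the carrier: f_if > 2 x max signal freq
    # is the caller's contract; enforce the hard Nyquist part plus headroom
    if f_if > 0.45 * fs:
        raise ValueError("f_if leaves no room for modulation sidebands below Nyquist")

    rng = np.random.default_rng(rng_seed)
    theta0 = rng.uniform(0.0, 2 * math.pi)
    t = dtheta.times
    n = len(dtheta)

    phase = 2 * math.pi * f_if * t + 2.0 * dtheta.samples + theta0
    if extra_carrier_phase is not None:
        phase = phase + np.asarray(extra_carrier_phase)

    if spec.Nq_density > 0:
        sigma = spec.Nq_density * math.sqrt(fs / 2.0)
        phi_n = rng.normal(0.0, sigma, n)
        if spec.oneoverf_corner > 0:
            # shape an extra component as 1/f below the corner frequency
            w = np.fft.rfft(rng.normal(0.0, sigma, n))
            f = np.fft.rfftfreq(n, d=1.0 / fs)
            shape = np.zeros_like(f)
            lo = (f > 0) & (f < spec.oneoverf_corner)
            shape[lo] = np.sqrt(spec.oneoverf_corner / f[lo]) - 1.0
            phi_n = phi_n + np.fft.irfft(w * shape, n=n)
        phase = phase + phi_n

    amp = np.ones(n)
    if spec.relax_depth > 0:
        amp = amp + spec.relax_depth * np.sin(2 * math.pi * spec.f_relax * t)
    if spec.Ni_density > 0:
        amp = amp + rng.normal(0.0, spec.Ni_density * math.sqrt(fs / 2.0), n)

    return dtheta.with_samples(amp * np.cos(phase), unit="carrier-arb")
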