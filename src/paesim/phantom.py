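"""Digital phantoms and the optical-acoustic forward model.

Phantoms are collections of 3-D vessel segments (polyline centerline, radius,
per-vessel oxygen saturation and relative hemoglobin concentration) in a
tissue slab, plus an optional blade-edge (half-plane) absorber used for
resolution characterization.  The forward model emulates optical-resolution
photoacoustic excitation: a focused Gaussian beam (waist FWHM at the focal
plane, width growing with defocus through a configurable Rayleigh range)
deposits energy in absorbers; each illuminated absorber element emits a
bipolar (Gaussian-derivative) pressure pulse that reaches the unfocused
sensor after a time of flight depth/c_sound.  Two excitation wavelengths are
fired per A-line, interleaved by a fixed delay, and share one record.

Coordinates: x, y lateral (m), z depth (m, positive away from the probe).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .constants import C_SOUND, EPS_HB, EPS_HBO2
from .trace import TimeTrace

__all__ = [
    "VesselSegment",
    "BladeEdge",
    "Phantom",
    "OpticalModel",
    "make_vessel_phantom",
    "add_capillaries",
    "make_blade_edge",
    "forward_aline",
    "rasterize_footprint",
]

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma


@dataclass
class VesselSegment:
    """A cylindrical vessel around a 3-D polyline centerline."""

    centerline: np.ndarray          # (N, 3) points in m
    radius: float                   # m
    sO2: float                      # oxygenated hemoglobin fraction, 0..1
    c_hb: float = 1.0               # relative total hemoglobin concentration
    kind: str = "vessel"            # trunk | branch | capillary | vessel

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (N, 3) array")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.sO2 <= 1.0:
            raise ValueError("sO2 must lie in [0, 1]")
        if self.c_hb < 0:
            raise ValueError("c_hb must be non-negative")

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each (M, 3) point to the centerline polyline."""
        pts = np.atleast_2d(points)
        best = np.full(pts.shape[0], np.inf)
        cl = self.centerline
        if cl.shape[0] == 1:
            return np.linalg.norm(pts - cl[0], axis=1)
        for a, b in zip(cl[:-1], cl[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                d = np.linalg.norm(pts - a, axis=1)
            else:
                t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
                d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
            np.minimum(best, d, out=best)
        return best

    def bbox(self) -> np.ndarray:
        """Axis-aligned bounds inflated by the radius, shape (2, 3)."""
        lo = self.centerline.min(axis=0) - self.radius
        hi = self.centerline.max(axis=0) + self.radius
        return np.stack([lo, hi])


@dataclass
class BladeEdge:
    """Half-plane absorber: a thin uniform sheet bounded by a straight edge.

    Absorbing where (r_xy - position)·n >= 0 with n = (cos o, sin o),
    o = ``orientation_deg``; orientation 0 puts the edge along y with the
    absorber toward +x, 90 degrees swaps the axes.
    """

    position: tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0
    depth: float = 0.2e-3           # sheet depth (m)
    thickness: float = 12e-6        # sheet thickness along z (m)
    absorption: float = 1.0         # wavelength-independent, arbitrary units

    def inside(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        o = math.radians(self.orientation_deg)
        n = np.array([math.cos(o), math.sin(o)])
        side = (pts[:, :2] - np.asarray(self.position)) @ n >= 0.0
        zin = (pts[:, 2] >= self.depth) & (pts[:, 2] <= self.depth + self.thickness)
        return side & zin


@dataclass
class Phantom:
    """Vessel segments and/or a blade edge inside a bounded slab."""

    segments: list[VesselSegment] = field(default_factory=list)
    blade: BladeEdge | None = None
    bounds: np.ndarray = field(
        default_factory=lambda: np.array([[-3e-3, 3e-3], [-3e-3, 3e-3], [0.0, 1e-3]]))

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (3, 2):
            raise ValueError("bounds must be a (3, 2) array of (lo, hi) per axis")

    def contains_pose(self, x: float, y: float) -> bool:
        (x0, x1), (y0, y1) = self.bounds[0], self.bounds[1]
        return x0 <= x <= x1 and y0 <= y <= y1

    def concentrations(self, points: np.ndarray,
                       segments: list[VesselSegment] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(C_HbO2, C_Hb) at each point, summed over enclosing vessels."""
        pts = np.atleast_2d(points)
        c_oxy = np.zeros(pts.shape[0])
        c_deoxy = np.zeros(pts.shape[0])
        for seg in (self.segments if segments is None else segments):
            inside = seg.distance(pts) <= seg.radius
            if np.any(inside):
                c_oxy[inside] += seg.c_hb * seg.sO2
                c_deoxy[inside] += seg.c_hb * (1.0 - seg.sO2)
        return c_oxy, c_deoxy


@dataclass
class OpticalModel:
    """Dual-wavelength excitation and beam geometry.

    ``beam_waist_fwhm`` is the lateral intensity FWHM at the focal plane
    (this is the system's lateral resolution); ``rayleigh_range`` sets the
    defocus growth FWHM(z) = FWHM0·sqrt(1 + ((z-z_f)/z_R)^2) and is kept an
    independent parameter so the depth-dependent resolution of a real probe
    (beyond the ideal diffraction limit) can be matched by configuration.
    """

    wavelengths: tuple[float, float] = (532e-9, 558e-9)
    eps_hbo2: tuple[float, float] = (EPS_HBO2[532e-9], EPS_HBO2[558e-9])
    eps_hb: tuple[float, float] = (EPS_HB[532e-9], EPS_HB[558e-9])
    beam_waist_fwhm: float = 7.4e-6
    rayleigh_range: float = 1.2e-4
    focus_depth: float = 0.2e-3
    pulse_energy: float = 250e-9          # J, per pulse at each wavelength
    energy_ratio: float = 1.0             # E(lambda2)/E(lambda1)
    pulse_delay: float = 1500e-9          # s, wavelength interleave
    pulse_width: float = 30e-9            # s, Gaussian-derivative width (FWHM)
    pressure_scale: float = 2.5e-2        # Pa per unit absorbed-energy density

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2 or self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("two distinct wavelengths are required")
        if any(e <= 0 for e in (*self.eps_hbo2, *self.eps_hb)):
            raise ValueError("extinction coefficients must be positive")
        if not (self.beam_waist_fwhm > 0 and self.rayleigh_range > 0):
            raise ValueError("beam parameters must be positive")

    def beam_fwhm(self, z) -> np.ndarray | float:
        """Lateral intensity FWHM at depth z (m)."""
        dz = (np.asarray(z, dtype=float) - self.focus_depth) / self.rayleigh_range
        w = self.beam_waist_fwhm * np.sqrt(1.0 + dz**2)
        return float(w) if np.isscalar(z) else w

    def mu_a(self, c_oxy: np.ndarray, c_deoxy: np.ndarray, wl_index: int
             ) -> np.ndarray:
        """Absorption coefficient (arbitrary units) at one wavelength."""
        return (self.eps_hbo2[wl_index] * np.asarray(c_oxy)
                + self.eps_hb[wl_index] * np.asarray(c_deoxy))


# ---------------------------------------------------------------------------
# phantom generators

def make_vessel_phantom(
    rng_seed: int,
    n_trunks: int = 3,
    branches_per_trunk: int = 3,
    capillaries_per_trunk: int = 2,
    extent: float = 0.8e-3,
    depth_range: tuple[float, float] = (0.12e-3, 0.3e-3),
    trunk_radius: float = 22e-6,
    branch_radius: float = 12e-6,
    capillary_radius: float = 6e-6,
    so2_artery: tuple[float, float] = (0.92, 0.98),
    so2_vein: tuple[float, float] = (0.58, 0.72),
    so2_capillary: tuple[float, float] = (0.74, 0.88),
) -> Phantom:
    """Branching vasculature: trunk vessels with branches and capillaries.

    Trunks run across the slab with gentle wobble and alternate artery/vein;
    branches sprout sideways from trunk points; capillaries are short thin
    segments scattered near the trunks.  Deterministic under ``rng_seed``.
    ``n_trunks = 0`` yields an empty phantom.
    """
    rng = np.random.default_rng(rng_seed)
    half = extent / 2.0
    bounds = np.array([[-half, half], [-half, half],
                       [0.0, depth_range[1] + 0.2e-3]])
    segments: list[VesselSegment] = []
    for k in range(n_trunks):
        arterial = k % 2 == 0
        y0 = (-half + (k + 0.5) * extent / max(n_trunks, 1))
        z0 = rng.uniform(*depth_range)
        xs = np.linspace(-half, half, 9)
        ys = y0 + np.cumsum(rng.normal(0.0, 0.04 * extent / 9, 9))
        ys -= ys.mean() - y0
        zs = z0 + rng.normal(0.0, 5e-6, 9)
        trunk_cl = np.column_stack([xs, ys, zs])
        so2 = rng.uniform(*(so2_artery if arterial else so2_vein))
        segments.append(VesselSegment(trunk_cl, trunk_radius, so2,
                                      c_hb=rng.uniform(0.9, 1.1), kind="trunk"))
        for _ in range(branches_per_trunk):
            i = rng.integers(1, 8)
            start = trunk_cl[i]
            ang = rng.uniform(0.35, 0.65) * math.pi * rng.choice([-1.0, 1.0])
            length = rng.uniform(0.15, 0.3) * extent
            direc = np.array([math.cos(ang), math.sin(ang), 0.0])
            npts = 5
            pts = start + np.outer(np.linspace(0, length, npts), direc)
            pts[:, :2] += rng.normal(0.0, 3e-6, (npts, 2)).cumsum(axis=0)
            pts[:, 0] = np.clip(pts[:, 0], -half, half)
            pts[:, 1] = np.clip(pts[:, 1], -half, half)
            so2_b = rng.uniform(*(so2_artery if arterial else so2_vein))
            segments.append(VesselSegment(pts, branch_radius, so2_b,
                                          c_hb=rng.uniform(0.8, 1.0),
                                          kind="branch"))
        for _ in range(capillaries_per_trunk):
            start = np.array([rng.uniform(-half, half),
                              np.clip(y0 + rng.uniform(-0.2, 0.2) * extent,
                                      -half, half),
                              z0 + rng.uniform(-20e-6, 20e-6)])
            ang = rng.uniform(0.0, 2 * math.pi)
            length = rng.uniform(0.08, 0.15) * extent
            end = start + length * np.array([math.cos(ang), math.sin(ang), 0.0])
            end[:2] = np.clip(end[:2], -half, half)
            segments.append(VesselSegment(
                np.stack([start, end]), capillary_radius,
                rng.uniform(*so2_capillary), c_hb=rng.uniform(0.5, 0.8),
                kind="capillary"))
    return Phantom(segments=segments, bounds=bounds)


def add_capillaries(phantom: Phantom, n: int, rng_seed: int,
                    radius: float = 13e-6,
                    so2_range: tuple[float, float] = (0.78, 0.92),
                    c_hb_range: tuple[float, float] = (0.85, 1.1),
                    length_frac: tuple[float, float] = (0.12, 0.25)) -> Phantom:
    """New phantom with ``n`` extra small vessels (hyperemia scenario).

    Models inflammation-driven recruitment: the added segments are
    blood-rich (high relative C_Hb — recruited vessels are perfused), raise
    the vessel density and shift the mean sO2 upward.
    """
    rng = np.random.default_rng(rng_seed)
    (x0, x1), (y0, y1), _ = phantom.bounds
    extent = x1 - x0
    depths = [s.centerline[:, 2].mean() for s in phantom.segments] or [0.2e-3]
    new = list(phantom.segments)
    for _ in range(n):
        start = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1),
                          float(rng.choice(depths)) + rng.uniform(-15e-6, 15e-6)])
        ang = rng.uniform(0.0, 2 * math.pi)
        length = rng.uniform(*length_frac) * extent
        end = start + length * np.array([math.cos(ang), math.sin(ang), 0.0])
        end[0] = np.clip(end[0], x0, x1)
        end[1] = np.clip(end[1], y0, y1)
        new.append(VesselSegment(np.stack([start, end]), radius,
                                 rng.uniform(*so2_range),
                                 c_hb=rng.uniform(*c_hb_range),
                                 kind="capillary"))
    return replace(phantom, segments=new)


def make_blade_edge(position: tuple[float, float] = (0.0, 0.0),
                    orientation_deg: float = 0.0,
                    depth: float = 0.2e-3,
                    thickness: float = 12e-6,
                    extent: float = 1e-3) -> Phantom:
    """Half-plane absorber phantom for edge-spread resolution measurement."""
    half = extent / 2.0
    return Phantom(
        segments=[],
        blade=BladeEdge(position, orientation_deg, depth, thickness),
        bounds=np.array([[-half, half], [-half, half], [0.0, depth + 0.5e-3]]),
    )


# ---------------------------------------------------------------------------
# forward model

def _prune_segments(phantom: Phantom, x: float, y: float,
                    margin: float) -> list[VesselSegment]:
    keep = []
    for seg in phantom.segments:
        (lo, hi) = seg.bbox()
        if (lo[0] - margin <= x <= hi[0] + margin
                and lo[1] - margin <= y <= hi[1] + margin):
            keep.append(seg)
    return keep


def _pulse_kernel(sample_rate: float, pulse_width: float) -> np.ndarray:
    """Odd (bipolar) Gaussian-derivative kernel, peak amplitude 1."""
    tau = pulse_width / _GAUSS_FWHM
    half = int(math.ceil(4.0 * tau * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    g = -t * np.exp(-(t**2) / (2.0 * tau**2))
    peak = np.abs(g).max()
    return g / peak if peak > 0 else g


def forward_aline(
    phantom: Phantom,
    pose: tuple[float, float],
    optical: OpticalModel,
    noise_rms: float = 0.0,
    rng_seed: int | None = None,
    sample_rate: float = 125e6,
    c_sound: float = C_SOUND,
    lateral_samples: int = 7,
    lateral_extent_sigma: float = 2.2,
) -> TimeTrace:
    """Simulate the dual-wavelength pressure record for one beam position.

    The absorbed-energy profile along depth is integrated over a Gaussian
    lateral quadrature grid whose width follows the defocus-dependent beam
    FWHM; each depth sample radiates a bipolar pulse arriving at
    t = depth/c_sound.  The second wavelength's response is placed on the
    same record shifted by ``optical.pulse_delay``.  Additive white pressure
    noise of rms ``noise_rms`` is drawn from ``rng_seed``.

    A pose outside the phantom bounds returns an all-zero trace with a
    warning.
    """
    x, y = pose
    delay_n = int(round(optical.pulse_delay * sample_rate))
    n = 2 * delay_n
    trace = np.zeros(n)

    if not phantom.contains_pose(x, y):
        warnings.warn(f"pose {pose} outside phantom bounds; returning empty trace",
                      RuntimeWarning, stacklevel=2)
        out = TimeTrace(trace, sample_rate, "Pa")
        return out

    z_lo, z_hi = phantom.bounds[2]
    k_lo = max(int(math.floor(z_lo * sample_rate / c_sound)), 0)
    k_hi = min(int(math.ceil(z_hi * sample_rate / c_sound)), delay_n - 1)
    ks = np.arange(k_lo, k_hi + 1)
    zs = ks * c_sound / sample_rate

    fwhm = np.asarray(optical.beam_fwhm(zs))
    sigma = fwhm / _GAUSS_FWHM
    u = np.linspace(-lateral_extent_sigma, lateral_extent_sigma, lateral_samples)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    w = np.exp(-(uu**2 + vv**2) / 2.0).ravel()
    w /= w.sum()

    margin = float(sigma.max()) * lateral_extent_sigma + 1e-9
    segs = _prune_segments(phantom, x, y, margin)

    nz, nl = zs.size, u.size * u.size
    pts = np.empty((nz * nl, 3))
    pts[:, 0] = (x + np.outer(sigma, uu.ravel())).ravel()
    pts[:, 1] = (y + np.outer(sigma, vv.ravel())).ravel()
    pts[:, 2] = np.repeat(zs, nl)

    c_oxy, c_deoxy = phantom.concentrations(pts, segments=segs)
    blade_line = np.zeros(nz)
    if phantom.blade is not None:
        # wavelength-neutral absorber, deposited on the depth sample nearest
        # the sheet center; the Gaussian-beam overlap with a half plane has
        # the closed form Phi(d/sigma) in the beam-center edge distance d —
        # a hard per-point membership test would quantize the edge profile
        blade = phantom.blade
        scale = 0.5 * (optical.eps_hbo2[0] + optical.eps_hb[0])
        z_sheet = blade.depth + blade.thickness / 2.0
        k_blade = int(np.argmin(np.abs(zs - z_sheet)))
        o = math.radians(blade.orientation_deg)
        d = ((x - blade.position[0]) * math.cos(o)
             + (y - blade.position[1]) * math.sin(o))
        alpha = ndtr(d / sigma[k_blade])
        blade_line[k_blade] = blade.absorption * scale * alpha

    kernel = _pulse_kernel(sample_rate, optical.pulse_width)
    energies = (optical.pulse_energy,
                optical.pulse_energy * optical.energy_ratio)
    for wl in (0, 1):
        mu = optical.mu_a(c_oxy, c_deoxy, wl).reshape(nz, nl)
        s = (mu * w).sum(axis=1) + blade_line   # absorbed energy per depth
        s *= optical.pressure_scale * energies[wl] / optical.pulse_energy
        line = np.zeros(delay_n)
        line[ks] = s
        line = np.convolve(line, kernel, mode="same")
        off = wl * delay_n
        trace[off:off + delay_n] += line

    if noise_rms > 0:
        rng = np.random.default_rng(rng_seed)
        trace = trace + rng.normal(0.0, noise_rms, n)
    return TimeTrace(trace, sample_rate, "Pa")


def rasterize_footprint(phantom: Phantom, x_grid: np.ndarray,
                        y_grid: np.ndarray) -> np.ndarray:
    """Ground-truth lateral vessel mask: pixel centers within a vessel's
    radius of its centerline, ignoring depth (maximum-intensity footprint).

    Returns a boolean array of shape (len(y_grid), len(x_grid)) — row-major
    image convention with y as rows.
    """
    xx, yy = np.meshgrid(np.asarray(x_grid), np.asarray(y_grid))
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    mask = np.zeros(pts.shape[0], dtype=bool)
    for seg in phantom.segments:
        cl = seg.centerline.copy()
        cl[:, 2] = 0.0
        flat = VesselSegment(cl, seg.radius, seg.sO2, seg.c_hb, seg.kind)
        mask |= flat.distance(pts) <= seg.radius
    return mask.reshape(xx.shape)
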