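"""Focus characterization and exposure-safety analytics.

Focus finding operates on a :class:`~holobeam.propagation.FieldStack`
(pressure magnitude on a stack of transverse planes): local maxima are
extracted with a minimum physical separation, refined to sub-pixel
positions by per-axis quadratic interpolation, and characterized by
lateral/axial full width at half maximum (FWHM) with linearly interpolated
half-maximum crossings.

Exposure quantities follow the usual plane-wave relations: the
spatial-peak pulse-average intensity Isppa = p^2 / (2 rho c) of the peak
pressure p, the temporal average Ispta = Isppa * duty cycle, and skull
derating pnp * (1 - loss).  The intensity ops default to the conventional
1.5 MRayl water impedance (rho c with c = 1500 m/s) used in exposure
reporting; pass an explicit impedance to use tank conditions instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .propagation import FieldStack

__all__ = [
    "Peak",
    "FocusMetrics",
    "ExposureParams",
    "REPORTING_IMPEDANCE",
    "find_foci",
    "fwhm",
    "characterize_focus",
    "isppa",
    "ispta",
    "derate",
]

#: Conventional water impedance for exposure reporting (rho*c, Rayl).
REPORTING_IMPEDANCE = 1.5e6


@dataclass(frozen=True)
class Peak:
    """One localized pressure maximum (sub-pixel position, SI units)."""

    x: float
    y: float
    z: float
    amplitude: float
    index: tuple  # (iz, iy, ix) of the grid-aligned maximum


@dataclass(frozen=True)
class FocusMetrics:
    """Characterization of one focal spot; lengths in mm, pressure as given."""

    x_mm: float
    y_mm: float
    z_mm: float
    peak_pressure: float
    lateral_fwhm_mm: float
    axial_fwhm_mm: float
    focal_length_mm: float

    def __post_init__(self) -> None:
        if not (self.lateral_fwhm_mm > 0 and self.axial_fwhm_mm > 0):
            raise ValueError("FWHM must be positive")
        if not self.focal_length_mm > 0:
            raise ValueError("focal length must be positive")


@dataclass(frozen=True)
class ExposureParams:
    """Pulsing scheme of a sonication."""

    pnp_mpa: float
    pulse_length: float
    prf: float
    n_pulses: int = 1

    @property
    def duty(self) -> float:
        return self.pulse_length * self.prf

    def __post_init__(self) -> None:
        if not 0 <= self.duty <= 1:
            raise ValueError(f"duty cycle {self.duty} outside [0, 1]")


def _quadratic_offset(fm1: float, f0: float, fp1: float) -> float:
    """Sub-sample offset of a parabola through three equally spaced samples."""
    denom = fm1 - 2 * f0 + fp1
    if denom == 0:
        return 0.0
    off = 0.5 * (fm1 - fp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def find_foci(
    volume: FieldStack,
    n_expected: int,
    min_separation: float,
) -> list[Peak]:
    """Locate the n largest local pressure maxima, sub-pixel refined.

    Maxima closer than ``min_separation`` (Euclidean, metres) to an
    already-accepted stronger maximum are suppressed.  Raises if fewer than
    ``n_expected`` remain, listing what was found.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    from scipy import ndimage

    mag = volume.amplitude
    if mag.shape[0] >= 3:
        footprint = np.ones((3, 3, 3), dtype=bool)
        local_max = (ndimage.maximum_filter(mag, footprint=footprint, mode="nearest") == mag)
    else:
        local_max = ndimage.maximum_filter(mag, size=(1, 3, 3), mode="nearest") == mag
    local_max &= mag > 0.05 * mag.max()  # suppress numerically flat background
    idxs = np.argwhere(local_max)
    order = np.argsort(mag[tuple(idxs.T)])[::-1]
    idxs = idxs[order]

    x = volume.grid.x
    y = volume.grid.y
    z = volume.z
    accepted: list[Peak] = []
    for iz, iy, ix in idxs:
        px, py, pz = x[ix], y[iy], z[iz]
        too_close = any(
            (px - a.x) ** 2 + (py - a.y) ** 2 + (pz - a.z) ** 2 < min_separation**2
            for a in accepted
        )
        if too_close:
            continue
        # quadratic sub-pixel refinement per axis
        fx = px
        if 0 < ix < len(x) - 1:
            fx += _quadratic_offset(mag[iz, iy, ix - 1], mag[iz, iy, ix], mag[iz, iy, ix + 1]) * volume.grid.dx
        fy = py
        if 0 < iy < len(y) - 1:
            fy += _quadratic_offset(mag[iz, iy - 1, ix], mag[iz, iy, ix], mag[iz, iy + 1, ix]) * volume.grid.dx
        fz = pz
        if 0 < iz < len(z) - 1 and len(z) >= 3:
            dz_step = z[min(iz + 1, len(z) - 1)] - z[iz]
            fz += _quadratic_offset(mag[iz - 1, iy, ix], mag[iz, iy, ix], mag[iz + 1, iy, ix]) * dz_step
        accepted.append(
            Peak(x=float(fx), y=float(fy), z=float(fz), amplitude=float(mag[iz, iy, ix]), index=(int(iz), int(iy), int(ix)))
        )
        if len(accepted) == n_expected:
            return accepted
    raise ValueError(
        f"found only {len(accepted)} maxima with separation >= "
        f"{min_separation * 1e3:.1f} mm, expected {n_expected}: {accepted}"
    )


def fwhm(profile, coords) -> float:
    """Full width at half maximum of a sampled magnitude profile.

    Half-maximum crossings adjacent to the global peak are located by
    linear interpolation.  Raises if the profile never drops below half
    maximum on either side (truncated profile).
    """
    p = np.asarray(profile, dtype=float)
    c = np.asarray(coords, dtype=float)
    if p.ndim != 1 or p.shape != c.shape:
        raise ValueError("profile and coords must be matching 1D arrays")
    imax = int(np.argmax(p))
    half = p[imax] / 2.0

    def _cross(indices) -> float:
        prev = imax
        for i in indices:
            if p[i] <= half:
                # linear interpolation between samples i and prev
                f = (half - p[i]) / (p[prev] - p[i])
                return float(c[i] + f * (c[prev] - c[i]))
            prev = i
        raise ValueError("profile never crosses half maximum (truncated)")

    left = _cross(range(imax - 1, -1, -1))
    right = _cross(range(imax + 1, len(p)))
    return abs(right - left)


def characterize_focus(volume: FieldStack, peak: Peak) -> FocusMetrics:
    """FWHM and focal-length characterization of one located focus.

    The lateral FWHM is measured along x through the peak in its axial
    plane; the axial FWHM along z through the peak's lateral position.
    The focal length is the peak's axial distance from the source plane of
    the stack (z = 0 being the transducer surface).
    """
    iz, iy, ix = peak.index
    mag = volume.amplitude
    lateral = fwhm(mag[iz, iy, :], volume.grid.x)
    if len(volume.z) < 3:
        raise ValueError("axial FWHM needs at least 3 planes in the stack")
    axial = fwhm(mag[:, iy, ix], volume.z)
    return FocusMetrics(
        x_mm=peak.x * 1e3,
        y_mm=peak.y * 1e3,
        z_mm=peak.z * 1e3,
        peak_pressure=peak.amplitude,
        lateral_fwhm_mm=lateral * 1e3,
        axial_fwhm_mm=axial * 1e3,
        focal_length_mm=peak.z * 1e3,
    )


def isppa(pnp_pa: float, impedance: float = REPORTING_IMPEDANCE) -> float:
    """Spatial-peak pulse-average intensity, W/cm^2.

    I = p^2 / (2 rho c) for a plane progressive wave of peak pressure p.
    """
    if not impedance > 0:
        raise ValueError("impedance must be positive")
    if pnp_pa < 0:
        raise ValueError("pressure must be nonnegative")
    return (pnp_pa**2) / (2.0 * impedance) / 1e4


def ispta(isppa_w_cm2: float, exposure: ExposureParams) -> float:
    """Spatial-peak temporal-average intensity, mW/cm^2 (Isppa * duty)."""
    duty = exposure.duty
    if duty > 1:
        raise ValueError("duty cycle exceeds 1")
    return isppa_w_cm2 * duty * 1e3


def derate(pnp_mpa: float, loss_fraction: float) -> float:
    """In-situ peak negative pressure after a fractional transmission loss.

    Rounded to two decimals (MPa) for report output, matching the usual
    precision of treatment tables.
    """
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    return round(pnp_mpa * (1.0 - loss_fraction), 2)
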