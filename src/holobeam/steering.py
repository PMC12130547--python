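"""Beam steering by axial translation and rotation of the hologram.

Under plane-wave illumination the field leaving the hologram does not
depend on where along the beam axis the hologram sits, so axial translation
by dz shifts the focus by exactly dz relative to the transducer while the
hologram-referenced focal geometry is unchanged.  Rotation of the
transducer+hologram assembly by an angle about a lateral axis is modeled
spectrally: the exit field is decomposed into plane waves and each
component's direction is rotated rigidly, then the rotated spectrum is
resampled onto the untilted computational plane and propagated.  This is
exact for homogeneous media up to the resampling interpolation and is
guarded to |angle| <= 45 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy.interpolate import RegularGridInterpolator

from .design import HologramPhase
from .grids import ComplexField, Medium, PistonSource, WATER, make_piston_source
from .metrics import FocusMetrics, characterize_focus, find_foci
from .propagation import FieldStack, propagate_volume, _embed, _pad_shape

__all__ = ["SteeringCase", "SteeringResult", "exit_field", "rotate_exit_field",
           "simulate_translated", "simulate_rotated"]

MAX_ROTATION_DEG = 45.0


@dataclass(frozen=True)
class SteeringCase:
    """A hologram placed with an axial offset and/or tilt.

    translation_dz : axial distance of the hologram plane from the
        transducer surface (m, >= 0).
    rotation_deg : tilt of the transducer+hologram assembly about the
        lateral y axis through the hologram centre, in degrees.
    """

    hologram: HologramPhase
    source: PistonSource
    translation_dz: float = 0.0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.translation_dz < 0:
            raise ValueError("translation must be >= 0")
        if abs(self.rotation_deg) > 90:
            raise ValueError("rotation must lie in [-90, 90] degrees")


@dataclass
class SteeringResult:
    """Field stack (hologram-referenced z) plus focus characterization."""

    stack: FieldStack
    metrics: FocusMetrics
    focal_length_hologram_mm: float
    focal_length_transducer_mm: float


def exit_field(case: SteeringCase) -> ComplexField:
    """Complex field immediately after the hologram under plane-wave drive.

    The piston's uniform plane wave acquires the hologram's phase map; the
    (constant) phase accumulated between transducer and hologram is dropped
    as a global factor.
    """
    piston = make_piston_source(case.source, case.hologram.grid)
    values = np.abs(piston.values) * np.exp(1j * case.hologram.phase)
    return ComplexField(
        grid=case.hologram.grid,
        values=values,
        frequency=case.source.frequency,
        z_position=0.0,
    )


def rotate_exit_field(
    field: ComplexField,
    angle_deg: float,
    medium: Medium = WATER,
    pad_factor: float = 2.0,
) -> ComplexField:
    """Rigidly rotate a field's plane-wave spectrum about the y axis.

    Each propagating component (kx, ky, kz) is mapped to its rotated
    direction and the spectrum is linearly resampled onto the untilted
    (kx', ky') grid with the Jacobian |d kx / d kx'| amplitude correction.
    Evanescent components are discarded.
    """
    if abs(angle_deg) > MAX_ROTATION_DEG:
        raise ValueError(
            f"|rotation| > {MAX_ROTATION_DEG} deg is outside the validity "
            "of the spectral rotation model"
        )
    if angle_deg == 0.0:
        return field.copy()
    theta = np.deg2rad(angle_deg)
    k0 = medium.wavenumber(field.frequency)

    shape = (
        _pad_shape(field.grid.ny, pad_factor),
        _pad_shape(field.grid.nx, pad_factor),
    )
    padded, sl = _embed(field.values, shape)
    # shift the field centre to index 0 so the spectrum carries no linear
    # phase ramp (a centre-embedded FFT alternates sign every sample, which
    # would wreck the interpolation below)
    spec = sp_fft.fftshift(sp_fft.fft2(sp_fft.ifftshift(padded)))
    kx = sp_fft.fftshift(2 * np.pi * sp_fft.fftfreq(shape[1], field.grid.dx))
    ky = sp_fft.fftshift(2 * np.pi * sp_fft.fftfreq(shape[0], field.grid.dx))

    KXp, KYp = np.meshgrid(kx, ky)
    kr2 = KXp**2 + KYp**2
    prop_mask = kr2 < k0**2
    kzp = np.sqrt(np.maximum(k0**2 - kr2, 0.0))
    # source-component kx that rotates onto the output component (kx', ky')
    kx_src = KXp * np.cos(theta) - kzp * np.sin(theta)
    valid = prop_mask & (kx_src**2 + KYp**2 < k0**2)

    interp_re = RegularGridInterpolator(
        (ky, kx), spec.real, bounds_error=False, fill_value=0.0
    )
    interp_im = RegularGridInterpolator(
        (ky, kx), spec.imag, bounds_error=False, fill_value=0.0
    )
    pts = np.column_stack([KYp[valid], kx_src[valid]])
    sampled = interp_re(pts) + 1j * interp_im(pts)
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.cos(theta) + np.where(kzp > 0, KXp / kzp, 0.0) * np.sin(theta)
    out = np.zeros_like(spec)
    out[valid] = sampled * np.abs(jac[valid])
    rotated = sp_fft.fftshift(sp_fft.ifft2(sp_fft.ifftshift(out)))[sl]
    return ComplexField(
        grid=field.grid,
        values=rotated,
        frequency=field.frequency,
        z_position=field.z_position,
    )


def _characterize(
    stack: FieldStack, translation_dz: float, min_separation: float = 2e-3
) -> tuple[FocusMetrics, float, float]:
    peak = find_foci(stack, n_expected=1, min_separation=min_separation)[0]
    metrics = characterize_focus(stack, peak)
    fl_holo = metrics.focal_length_mm
    fl_trans = fl_holo + translation_dz * 1e3
    return metrics, fl_holo, fl_trans


def simulate_translated(
    case: SteeringCase,
    z_list: Sequence[float],
    medium: Medium = WATER,
    z_max: Optional[float] = None,
) -> SteeringResult:
    """Simulate the field of an axially translated hologram.

    ``z_list`` gives the hologram-referenced evaluation planes.  Because
    the incident wave is planar the exit field is translation-invariant;
    the transducer-referenced focal length is the hologram-referenced one
    plus the translation.
    """
    if case.rotation_deg != 0.0:
        raise ValueError("use simulate_rotated for tilted holograms")
    z_arr = np.asarray(z_list, dtype=float)
    if z_max is not None and case.translation_dz + z_arr.max() > z_max:
        raise ValueError(
            "translation pushes the evaluated volume beyond the simulated z range"
        )
    stack = propagate_volume(exit_field(case), z_arr, medium)
    metrics, fl_h, fl_t = _characterize(stack, case.translation_dz)
    return SteeringResult(
        stack=stack,
        metrics=metrics,
        focal_length_hologram_mm=fl_h,
        focal_length_transducer_mm=fl_t,
    )


def simulate_rotated(
    case: SteeringCase,
    z_list: Sequence[float],
    medium: Medium = WATER,
) -> SteeringResult:
    """Simulate the field of a rotated transducer+hologram assembly."""
    rotated = rotate_exit_field(exit_field(case), case.rotation_deg, medium)
    stack = propagate_volume(rotated, np.asarray(z_list, dtype=float), medium)
    metrics, fl_h, fl_t = _characterize(stack, case.translation_dz)
    return SteeringResult(
        stack=stack,
        metrics=metrics,
        focal_length_hologram_mm=fl_h,
        focal_length_transducer_mm=fl_t,
    )
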