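"""Angular-spectrum propagation of monochromatic scalar pressure fields.

A field on one transverse plane is decomposed into plane waves by a 2D
FFT; each component (kx, ky) is advanced over an axial step dz by the
transfer factor

    H(kx, ky, dz) = exp(j dz sqrt(k0^2 - kx^2 - ky^2)),   kx^2 + ky^2 <= k0^2

with k0 = 2 pi f / c.  Evanescent components (kx^2 + ky^2 > k0^2) decay as
exp(-|dz| kappa) on forward steps and are zeroed on backward steps so that
back-propagation never amplifies them exponentially.

To suppress wrap-around of the periodic FFT images, fields are embedded in
a zero-padded computational grid (default 2x linear extent) before
propagation and cropped afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .grids import ComplexField, Medium, PlaneGrid

__all__ = [
    "AngularSpectrum",
    "Propagator",
    "FieldStack",
    "to_angular_spectrum",
    "from_angular_spectrum",
    "make_propagator",
    "propagate",
    "backpropagate",
    "propagate_volume",
]

DEFAULT_PAD_FACTOR = 2.0


@dataclass
class AngularSpectrum:
    """2D spatial-frequency representation of a :class:`ComplexField`.

    Axes are FFT-conjugate to the grid: ``kx[i] = 2 pi * fftfreq(nx, dx)``
    in rad/m, in standard (unshifted) FFT order.
    """

    grid: PlaneGrid
    values: np.ndarray
    frequency: float
    z_position: float

    @property
    def kx(self) -> np.ndarray:
        return 2.0 * np.pi * sp_fft.fftfreq(self.grid.nx, self.grid.dx)

    @property
    def ky(self) -> np.ndarray:
        return 2.0 * np.pi * sp_fft.fftfreq(self.grid.ny, self.grid.dx)


@dataclass
class Propagator:
    """Per-component transfer factor H for one signed axial step."""

    H: np.ndarray
    dz: float
    evanescent: np.ndarray  # boolean mask, True where kx^2+ky^2 > k0^2


@dataclass
class FieldStack:
    """Complex pressure sampled on a stack of transverse planes.

    ``values`` is shaped ``(nz, ny, nx)``; ``z`` holds the axial positions
    in metres in input order.
    """

    grid: PlaneGrid
    z: np.ndarray
    values: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.values.shape != (len(self.z), self.grid.ny, self.grid.nx):
            raise ValueError("values shape does not match (nz, ny, nx)")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def plane(self, i: int) -> ComplexField:
        return ComplexField(
            grid=self.grid,
            values=self.values[i],
            frequency=self.frequency,
            z_position=float(self.z[i]),
        )


def to_angular_spectrum(field: ComplexField) -> AngularSpectrum:
    """Discrete 2D Fourier transform of a transverse field (invertible)."""
    return AngularSpectrum(
        grid=field.grid,
        values=sp_fft.fft2(field.values),
        frequency=field.frequency,
        z_position=field.z_position,
    )


def from_angular_spectrum(spec: AngularSpectrum) -> ComplexField:
    """Exact inverse of :func:`to_angular_spectrum`."""
    if spec.values.shape != spec.grid.shape:
        raise ValueError("spectrum shape does not match declared grid")
    return ComplexField(
        grid=spec.grid,
        values=sp_fft.ifft2(spec.values),
        frequency=spec.frequency,
        z_position=spec.z_position,
    )


def make_propagator(
    kx: np.ndarray,
    ky: np.ndarray,
    dz: float,
    medium: Medium,
    frequency: float,
) -> Propagator:
    """Build the angular-spectrum transfer factor for a signed step dz.

    On the propagating band |H| = 1 (lossless medium).  Evanescent
    components decay for dz > 0 and are zeroed for dz < 0.
    """
    k0 = medium.wavenumber(frequency)
    KX, KY = np.meshgrid(np.asarray(kx), np.asarray(ky))
    kr2 = KX**2 + KY**2
    evanescent = kr2 > k0**2
    kz = np.sqrt(np.maximum(k0**2 - kr2, 0.0))
    kappa = np.sqrt(np.maximum(kr2 - k0**2, 0.0))
    H = np.exp(1j * dz * kz)
    if dz > 0:
        H = np.where(evanescent, np.exp(-dz * kappa), H)
    elif dz < 0:
        H = np.where(evanescent, 0.0, H)
    # dz == 0: H identically 1
    return Propagator(H=H, dz=float(dz), evanescent=evanescent)


def _pad_shape(n: int, pad_factor: float) -> int:
    return sp_fft.next_fast_len(int(np.ceil(n * pad_factor)))


def _embed(values: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Centre-embed an array into a larger zero array; return crop slices."""
    ny, nx = values.shape
    py, px = shape
    oy, ox = (py - ny) // 2, (px - nx) // 2
    out = np.zeros(shape, dtype=np.complex128)
    sl = (slice(oy, oy + ny), slice(ox, ox + nx))
    out[sl] = values
    return out, sl


def _attenuation_factor(medium: Medium, dz: float) -> float:
    if medium.attenuation_db_cm == 0.0:
        return 1.0
    return 10.0 ** (-medium.attenuation_db_cm * (abs(dz) * 100.0) / 20.0)


def propagate(
    field: ComplexField,
    dz: float,
    medium: Medium,
    pad_factor: float = DEFAULT_PAD_FACTOR,
) -> ComplexField:
    """Propagate a field by a signed axial step dz.

    Backward steps (dz < 0) zero the evanescent band; the resulting plane
    must not lie behind the transducer surface (z < 0).
    """
    z_new = field.z_position + dz
    if z_new < -1e-12:
        raise ValueError(
            f"propagation to z = {z_new * 1e3:.2f} mm behind the transducer"
        )
    shape = (
        _pad_shape(field.grid.ny, pad_factor),
        _pad_shape(field.grid.nx, pad_factor),
    )
    padded, sl = _embed(field.values, shape)
    kx = 2.0 * np.pi * sp_fft.fftfreq(shape[1], field.grid.dx)
    ky = 2.0 * np.pi * sp_fft.fftfreq(shape[0], field.grid.dx)
    prop = make_propagator(kx, ky, dz, medium, field.frequency)
    out = sp_fft.ifft2(sp_fft.fft2(padded) * prop.H)[sl]
    out *= _attenuation_factor(medium, dz)
    return ComplexField(
        grid=field.grid,
        values=out,
        frequency=field.frequency,
        z_position=max(z_new, 0.0),
    )


def backpropagate(
    field: ComplexField,
    dz: float,
    medium: Medium,
    pad_factor: float = DEFAULT_PAD_FACTOR,
) -> ComplexField:
    """Propagate backward by a positive distance dz (evanescent band zeroed)."""
    if not dz > 0:
        raise ValueError("backpropagate expects a positive distance")
    return propagate(field, -dz, medium, pad_factor=pad_factor)


def propagate_volume(
    field: ComplexField,
    z_list,
    medium: Medium,
    pad_factor: float = DEFAULT_PAD_FACTOR,
) -> FieldStack:
    """Propagate one field to a sorted list of absolute axial positions.

    Equivalent to calling :func:`propagate` once per plane but reuses the
    forward FFT of the source plane.
    """
    z_arr = np.asarray(z_list, dtype=float)
    if z_arr.ndim != 1 or len(z_arr) == 0:
        raise ValueError("z_list must be a non-empty 1D sequence")
    if np.any(np.diff(z_arr) < 0):
        raise ValueError("z_list must be sorted ascending")
    if np.any(z_arr < 0):
        raise ValueError("z_list positions must be >= 0")

    shape = (
        _pad_shape(field.grid.ny, pad_factor),
        _pad_shape(field.grid.nx, pad_factor),
    )
    padded, sl = _embed(field.values, shape)
    spectrum = sp_fft.fft2(padded)
    kx = 2.0 * np.pi * sp_fft.fftfreq(shape[1], field.grid.dx)
    ky = 2.0 * np.pi * sp_fft.fftfreq(shape[0], field.grid.dx)

    out = np.empty((len(z_arr), field.grid.ny, field.grid.nx), dtype=np.complex128)
    for i, z in enumerate(z_arr):
        dz = z - field.z_position
        prop = make_propagator(kx, ky, dz, medium, field.frequency)
        plane = sp_fft.ifft2(spectrum * prop.H)[sl]
        out[i] = plane * _attenuation_factor(medium, dz)
    return FieldStack(grid=field.grid, z=z_arr, values=out, frequency=field.frequency)
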