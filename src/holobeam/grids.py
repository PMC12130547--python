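"""Core lateral grids, media, and source fields.

All quantities are SI internally (metres, Pa, Hz); user-facing fixtures and
the CLI accept mm / MHz / MPa and convert on the way in.

The lateral grid follows the image convention: field arrays are indexed
``[iy, ix]`` with x along the last axis.  The beam (z) axis passes through
the grid centre, with the pixel-centre coordinate of index ``i`` along x
being ``(i - nx/2) * dx``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PlaneGrid",
    "Medium",
    "ComplexField",
    "PistonSource",
    "WATER",
    "make_grid",
    "make_piston_source",
]

#: Minimum sample count per lateral axis.
MIN_SAMPLES = 16


@dataclass(frozen=True)
class PlaneGrid:
    """Uniform lateral sampling grid for one transverse plane.

    Parameters
    ----------
    nx, ny : int
        Sample counts along x (lateral) and y (elevational).
    dx : float
        Isotropic sample spacing in metres (default 100 um, roughly one
        tenth of the wavelength at 1.5 MHz in water).
    """

    nx: int
    ny: int
    dx: float = 100e-6

    def __post_init__(self) -> None:
        if self.nx < MIN_SAMPLES or self.ny < MIN_SAMPLES:
            raise ValueError(
                f"grid needs at least {MIN_SAMPLES} samples per axis, "
                f"got nx={self.nx}, ny={self.ny}"
            )
        if not self.dx > 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def x(self) -> np.ndarray:
        """Pixel-centre x coordinates in metres, beam axis at index nx//2."""
        return (np.arange(self.nx) - self.nx / 2) * self.dx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny / 2) * self.dx

    @property
    def extent_x(self) -> float:
        """Physical side length along x in metres (nx * dx)."""
        return self.nx * self.dx

    @property
    def extent_y(self) -> float:
        return self.ny * self.dx

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays shaped (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass(frozen=True)
class Medium:
    """Homogeneous propagation medium.

    Attributes
    ----------
    sound_speed : float
        Longitudinal sound speed in m/s.
    density : float
        Mass density in kg/m^3.
    attenuation_db_cm : float
        Amplitude attenuation at the working frequency, dB/cm (0 for
        degassed water).
    """

    sound_speed: float
    density: float
    attenuation_db_cm: float = 0.0

    def __post_init__(self) -> None:
        if not self.sound_speed > 0:
            raise ValueError("sound_speed must be positive")
        if not self.density > 0:
            raise ValueError("density must be positive")
        if self.attenuation_db_cm < 0:
            raise ValueError("attenuation must be nonnegative")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho*c in Rayl."""
        return self.sound_speed * self.density

    def wavenumber(self, frequency: float) -> float:
        """Angular wavenumber k0 = 2*pi*f/c in rad/m."""
        if not frequency > 0:
            raise ValueError("frequency must be positive")
        return 2.0 * np.pi * frequency / self.sound_speed

    def wavelength(self, frequency: float) -> float:
        return self.sound_speed / frequency


#: Degassed water at the paper-typical tank conditions.
WATER = Medium(sound_speed=1480.0, density=1000.0, attenuation_db_cm=0.0)


@dataclass
class ComplexField:
    """Complex pressure amplitude p = |p| e^{j phi} on one transverse plane.

    ``values`` is a complex array shaped ``(ny, nx)`` in Pa; ``z_position``
    is the axial distance of the plane from the transducer surface.
    """

    grid: PlaneGrid
    values: np.ndarray
    frequency: float
    z_position: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if self.z_position < 0:
            raise ValueError("z_position must be >= 0")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class PistonSource:
    """Single-element plane-wave (flat piston) transducer.

    The transducer emits a uniform-amplitude, flat-phase disk: in the plane
    z = 0 the pressure is ``surface_pressure`` inside the aperture and 0
    outside.
    """

    diameter: float
    frequency: float = 1.5e6
    surface_pressure: float = 1.0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if not self.surface_pressure > 0:
            raise ValueError("surface_pressure must be positive")


def make_grid(nx: int, ny: int, dx: float = 100e-6) -> PlaneGrid:
    """Create a lateral sampling grid centred on the beam axis.

    Raises
    ------
    ValueError
        If ``dx`` is non-positive or either count is below 16.
    """
    return PlaneGrid(nx=int(nx), ny=int(ny), dx=float(dx))


def make_piston_source(source: PistonSource, grid: PlaneGrid) -> ComplexField:
    """Rasterize a piston source onto a grid as the z = 0 boundary field.

    A pixel belongs to the aperture when its centre lies inside the disk of
    the given diameter.  Phase is identically zero (plane-wave emission).

    Raises
    ------
    ValueError
        If the aperture does not fit inside the grid extent.
    """
    if source.diameter > min(grid.extent_x, grid.extent_y):
        raise ValueError(
            f"aperture diameter {source.diameter * 1e3:.1f} mm exceeds grid "
            f"extent {min(grid.extent_x, grid.extent_y) * 1e3:.1f} mm"
        )
    X, Y = grid.meshgrid()
    disk = (X**2 + Y**2) <= (source.diameter / 2) ** 2
    values = np.where(disk, source.surface_pressure, 0.0).astype(np.complex128)
    return ComplexField(
        grid=grid, values=values, frequency=source.frequency, z_position=0.0
    )
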