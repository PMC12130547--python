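"""Physical realization of a phase map as a 3D-printable acoustic lens.

The designed phase is realized by spatially varying lens thickness.  With
lens sound speed c2 > water sound speed c1, a thicker pixel replaces slow
water by fast lens material and so ADVANCES the transmitted phase; a full
2*pi of design phase corresponds to an extra thickness

    dt_2pi = 2*pi / (k_water - k_lens)

(about 2.79 mm at 1.5 MHz for the default printing material).  The lens is
modeled acoustically as a three-layer stack water / lens / water with the
complex pressure-transmission factor

    T = 4 Z1 Z2 / ((Z1 - Z2)(Z2 - Z3) e^{j phi} + (Z1 + Z2)(Z2 + Z3))

where phi = k_lens * t is the internal phase advance through the layer and
Z1, Z2, Z3 the impedances of the three media.  Bulk absorption in the lens
material is applied on top as 10^(-alpha_dB_cm * t_cm / 20).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import HologramPhase, wrap_phase
from .grids import Medium, PlaneGrid

__all__ = [
    "MaterialProps",
    "ThicknessMap",
    "VISJET_M2R_WT",
    "transmission_coefficient",
    "phase_to_thickness",
    "thickness_to_phase",
    "lens_amplitude_map",
    "export_lens",
    "import_thickness_csv",
    "import_thickness_tiff",
]


@dataclass(frozen=True)
class MaterialProps:
    """Acoustic properties of a printable lens material."""

    sound_speed: float
    density: float
    attenuation_db_cm: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sound_speed > 0 and self.density > 0):
            raise ValueError("material constants must be positive")
        if self.attenuation_db_cm < 0:
            raise ValueError("attenuation must be nonnegative")

    @property
    def impedance(self) -> float:
        return self.sound_speed * self.density

    def wavenumber(self, frequency: float) -> float:
        return 2.0 * np.pi * frequency / self.sound_speed


#: Default MultiJet printing material (values at 1.5 MHz).
VISJET_M2R_WT = MaterialProps(
    sound_speed=2290.0, density=1030.0, attenuation_db_cm=4.6
)


@dataclass
class ThicknessMap:
    """Per-pixel lens thickness in metres on the design grid."""

    grid: PlaneGrid
    thickness: np.ndarray
    base_thickness: float = 0.5e-3

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != self.grid.shape:
            raise ValueError("thickness shape must match grid")
        if not self.base_thickness > 0:
            raise ValueError("base_thickness must be positive")
        if np.any(self.thickness < self.base_thickness - 1e-12):
            raise ValueError("thickness must be >= base_thickness everywhere")


def transmission_coefficient(Z1: float, Z2: float, Z3: float, phi) -> complex:
    """Complex pressure transmission of a layer of impedance Z2.

    ``phi`` is the internal phase advance through the layer (k2 * t).
    For a symmetric stack (Z1 == Z3) the factor is passive, |T| <= 1, with
    equality at phi = 0 (mod full-wave resonance).
    """
    if not (Z1 > 0 and Z2 > 0 and Z3 > 0):
        raise ValueError("impedances must be positive")
    phi = np.asarray(phi, dtype=float)
    denom = (Z1 - Z2) * (Z2 - Z3) * np.exp(1j * phi) + (Z1 + Z2) * (Z2 + Z3)
    if np.any(np.abs(denom) == 0):
        raise ZeroDivisionError("degenerate impedance combination")
    T = 4.0 * Z1 * Z2 / denom
    return complex(T) if T.ndim == 0 else T


def phase_to_thickness(
    phase: HologramPhase,
    lens: MaterialProps,
    water: Medium,
    base_thickness: float = 0.5e-3,
) -> ThicknessMap:
    """Convert a wrapped design phase into a minimal-thickness lens profile.

    t(x, y) = base_thickness + phase / (k_water - k_lens).  Requires the
    lens to be acoustically faster than water (k_water > k_lens) so that
    added thickness advances phase.
    """
    k_w = water.wavenumber(phase.frequency)
    k_l = lens.wavenumber(phase.frequency)
    dk = k_w - k_l
    if abs(dk) < 1e-9:
        raise ValueError("lens and water sound speeds are equal; no phase contrast")
    t = base_thickness + phase.phase / dk
    return ThicknessMap(grid=phase.grid, thickness=t, base_thickness=base_thickness)


def thickness_to_phase(
    t: ThicknessMap,
    lens: MaterialProps,
    water: Medium,
    frequency: float,
) -> HologramPhase:
    """Inverse of :func:`phase_to_thickness` (modulo 2*pi)."""
    k_w = water.wavenumber(frequency)
    k_l = lens.wavenumber(frequency)
    dk = k_w - k_l
    if abs(dk) < 1e-9:
        raise ValueError("lens and water sound speeds are equal; no phase contrast")
    phase = wrap_phase((t.thickness - t.base_thickness) * dk)
    return HologramPhase(grid=t.grid, phase=phase, frequency=frequency)


def lens_amplitude_map(
    t: ThicknessMap,
    lens: MaterialProps,
    water: Medium,
    frequency: float,
) -> np.ndarray:
    """Per-pixel amplitude transmission of the physical lens.

    |T| of the water/lens/water stack at internal phase k_lens * t, times
    the bulk absorption 10^(-alpha * t_cm / 20).  Strictly positive and
    bounded by 1.
    """
    k_l = lens.wavenumber(frequency)
    T = transmission_coefficient(
        water.impedance, lens.impedance, water.impedance, k_l * t.thickness
    )
    absorb = 10.0 ** (-lens.attenuation_db_cm * (t.thickness * 100.0) / 20.0)
    return np.abs(T) * absorb


def _heightmap_mesh(t: ThicknessMap):
    """Build a watertight extruded-heightmap mesh (units: metres)."""
    import trimesh

    ny, nx = t.grid.shape
    X, Y = t.grid.meshgrid()
    top = np.column_stack([X.ravel(), Y.ravel(), t.thickness.ravel()])
    bottom = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    verts = np.vstack([top, bottom])
    nb = nx * ny  # offset of bottom vertices

    def vid(iy, ix, layer):  # layer 0 = top, 1 = bottom
        return layer * nb + iy * nx + ix

    faces = []
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            a, b = vid(iy, ix, 0), vid(iy, ix + 1, 0)
            c, d = vid(iy + 1, ix + 1, 0), vid(iy + 1, ix, 0)
            faces.append([a, b, c])
            faces.append([a, c, d])
            a, b = vid(iy, ix, 1), vid(iy, ix + 1, 1)
            c, d = vid(iy + 1, ix + 1, 1), vid(iy + 1, ix, 1)
            faces.append([a, c, b])
            faces.append([a, d, c])
    for ix in range(nx - 1):  # front/back walls
        faces.append([vid(0, ix, 0), vid(0, ix, 1), vid(0, ix + 1, 1)])
        faces.append([vid(0, ix, 0), vid(0, ix + 1, 1), vid(0, ix + 1, 0)])
        faces.append([vid(ny - 1, ix, 0), vid(ny - 1, ix + 1, 1), vid(ny - 1, ix, 1)])
        faces.append([vid(ny - 1, ix, 0), vid(ny - 1, ix + 1, 0), vid(ny - 1, ix + 1, 1)])
    for iy in range(ny - 1):  # left/right walls
        faces.append([vid(iy, 0, 0), vid(iy + 1, 0, 1), vid(iy, 0, 1)])
        faces.append([vid(iy, 0, 0), vid(iy + 1, 0, 0), vid(iy + 1, 0, 1)])
        faces.append([vid(iy, nx - 1, 0), vid(iy, nx - 1, 1), vid(iy + 1, nx - 1, 1)])
        faces.append([vid(iy, nx - 1, 0), vid(iy + 1, nx - 1, 1), vid(iy + 1, nx - 1, 0)])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def export_lens(
    t: ThicknessMap,
    path,
    format: str,
    quantization: float | None = None,
) -> Path:
    """Write a thickness map as a printable artifact.

    Formats: ``tiff`` (32-bit float heightmap, thickness in micrometres),
    ``csv`` (thickness in metres), ``stl`` (watertight extruded mesh).
    ``quantization`` optionally snaps thickness to a vertical step (e.g.
    25 um, a typical MultiJet layer height) before export.
    """
    path = Path(path)
    thickness = t.thickness
    if quantization is not None:
        if not quantization > 0:
            raise ValueError("quantization step must be positive")
        thickness = np.round(thickness / quantization) * quantization
    fmt = format.lower()
    if fmt == "csv":
        np.savetxt(path, thickness, delimiter=",")
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(
            path,
            (thickness * 1e6).astype(np.float32),
            metadata={
                "units": "um",
                "dx_um": t.grid.dx * 1e6,
                "base_thickness_um": t.base_thickness * 1e6,
                "quantization_um": None if quantization is None else quantization * 1e6,
            },
        )
    elif fmt == "stl":
        mesh = _heightmap_mesh(
            ThicknessMap(grid=t.grid, thickness=thickness, base_thickness=t.base_thickness)
        )
        mesh.export(path, file_type="stl")
    else:
        raise ValueError(f"unknown export format {format!r}; use tiff, csv or stl")
    return path


def import_thickness_csv(path, grid: PlaneGrid, base_thickness: float = 0.5e-3) -> ThicknessMap:
    thickness = np.loadtxt(path, delimiter=",")
    return ThicknessMap(grid=grid, thickness=thickness, base_thickness=base_thickness)


def import_thickness_tiff(path, grid: PlaneGrid, base_thickness: float = 0.5e-3) -> ThicknessMap:
    import tifffile

    thickness = tifffile.imread(path).astype(float) * 1e-6
    return ThicknessMap(grid=grid, thickness=thickness, base_thickness=base_thickness)
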