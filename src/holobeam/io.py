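"""Export helpers for fields, stacks and phase maps (TIFF / CSV / HDF5)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .design import HologramPhase
from .propagation import FieldStack

__all__ = [
    "export_stack_tiff",
    "export_stack_hdf5",
    "export_profile_csv",
    "export_phase_tiff",
    "export_phase_csv",
    "import_phase_csv",
]


def export_stack_tiff(stack: FieldStack, path) -> Path:
    """Per-plane pressure magnitude as a 32-bit multi-page TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        stack.amplitude.astype(np.float32),
        metadata={
            "z_mm": [float(z) * 1e3 for z in stack.z],
            "dx_um": stack.grid.dx * 1e6,
            "frequency_hz": stack.frequency,
        },
    )
    return path


def export_stack_hdf5(stack: FieldStack, path) -> Path:
    """Complex volume with axes, suitable for downstream analysis."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("pressure", data=stack.values, compression="gzip")
        f.create_dataset("z", data=stack.z)
        f.create_dataset("x", data=stack.grid.x)
        f.create_dataset("y", data=stack.grid.y)
        f.attrs["frequency_hz"] = stack.frequency
        f.attrs["dx_m"] = stack.grid.dx
    return path


def export_profile_csv(coords: np.ndarray, values: np.ndarray, path, label: str = "position_m") -> Path:
    """A 1D line profile (axial or lateral) as a two-column CSV."""
    path = Path(path)
    arr = np.column_stack([coords, values])
    np.savetxt(path, arr, delimiter=",", header=f"{label},magnitude", comments="")
    return path


def export_phase_tiff(phase: HologramPhase, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path,
        phase.phase.astype(np.float32),
        metadata={"units": "rad", "dx_um": phase.grid.dx * 1e6,
                  "frequency_hz": phase.frequency},
    )
    return path


def export_phase_csv(phase: HologramPhase, path) -> Path:
    path = Path(path)
    np.savetxt(path, phase.phase, delimiter=",")
    return path


def import_phase_csv(path, grid, frequency: float) -> HologramPhase:
    phase = np.loadtxt(path, delimiter=",")
    return HologramPhase(grid=grid, phase=phase, frequency=frequency)
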