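"""Model/Results interface to the hologram design loop.

:class:`HologramDesign` plays the role of a model object built from data
(the focal targets and the physical source), and :meth:`HologramDesign.fit`
runs the iterative design, returning a :class:`HologramDesignResults`
carrying the estimated phase map, convergence diagnostics, per-focus
achieved amplitudes and a ``summary()`` table.  Simulation, focus
characterization, lens conversion and plotting hang off the results
object.

Example
-------
>>> from holobeam import HologramDesign, FocusTarget, PistonSource
>>> model = HologramDesign(
...     targets=[FocusTarget(0.0, 0.0, 20e-3)],
...     source=PistonSource(diameter=30e-3, frequency=1.5e6),
... )
>>> res = model.fit()
>>> table, stack = res.characterize()
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    DesignConfig,
    DesignDiagnostics,
    FocusTarget,
    HologramPhase,
    TargetPlane,
    rasterize_targets,
    run_iasa,
)
from .grids import ComplexField, Medium, PistonSource, PlaneGrid, WATER, make_grid, make_piston_source
from .metrics import characterize_focus, find_foci
from .propagation import FieldStack, propagate, propagate_volume

__all__ = ["HologramDesign", "HologramDesignResults"]

#: Default lateral margin added around the aperture, metres.
GRID_MARGIN = 4e-3


def _default_grid(source: PistonSource, dx: float = 100e-6) -> PlaneGrid:
    n = int(np.ceil((source.diameter + 2 * GRID_MARGIN) / dx))
    n += n % 2  # keep counts even so the beam axis is a pixel centre offset
    return make_grid(n, n, dx)


class HologramDesign:
    """Acoustic-hologram design problem for a piston source.

    Parameters
    ----------
    targets : sequence of FocusTarget
        Desired foci; any number of planes, any lateral layout.
    source : PistonSource
        The plane-wave transducer (diameter, frequency, surface pressure).
    grid : PlaneGrid, optional
        Design grid; defaults to the aperture plus a 4 mm margin at
        100 um pixels.
    medium : Medium
        Propagation medium between hologram and targets (water).
    config : DesignConfig
        Iteration parameters (cap, uniformity tolerance, weighting).
    """

    def __init__(
        self,
        targets: Sequence[FocusTarget],
        source: PistonSource,
        grid: Optional[PlaneGrid] = None,
        medium: Medium = WATER,
        config: Optional[DesignConfig] = None,
    ) -> None:
        if not targets:
            raise ValueError("need at least one focus target")
        self.targets = list(targets)
        self.source = source
        self.grid = grid if grid is not None else _default_grid(source)
        self.medium = medium
        self.config = config if config is not None else DesignConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        source: PistonSource,
        **kwargs,
    ) -> "HologramDesign":
        """Build from a DataFrame with columns x_mm, y_mm, z_mm[, weight]."""
        weights = df["weight"] if "weight" in df else np.ones(len(df))
        targets = [
            FocusTarget(
                x=row.x_mm * 1e-3,
                y=row.y_mm * 1e-3,
                z=row.z_mm * 1e-3,
                weight=float(w),
            )
            for row, w in zip(df.itertuples(), weights)
        ]
        return cls(targets=targets, source=source, **kwargs)

    @property
    def disk_radius(self) -> float:
        if self.config.focus_disk_radius is not None:
            return self.config.focus_disk_radius
        return self.medium.wavelength(self.source.frequency) / 2.0

    def target_planes(self) -> list[TargetPlane]:
        """Rasterize the targets into per-plane amplitude images."""
        planes = []
        for z in sorted({t.z for t in self.targets}):
            foci = [t for t in self.targets if t.z == z]
            planes.append(rasterize_targets(foci, z, self.grid, self.disk_radius))
        return planes

    def source_field(self) -> ComplexField:
        return make_piston_source(self.source, self.grid)

    def fit(self) -> "HologramDesignResults":
        """Run the weighted iterative design and return the results."""
        phase, diag = run_iasa(
            self.source_field(), self.target_planes(), self.config, self.medium
        )
        return HologramDesignResults(self, phase, diag)


class HologramDesignResults:
    """Fitted hologram: phase map, diagnostics, and evaluation methods."""

    def __init__(
        self,
        model: HologramDesign,
        phase: HologramPhase,
        diagnostics: DesignDiagnostics,
    ) -> None:
        self.model = model
        self.phase = phase
        self.diagnostics = diagnostics

    # -- convergence accessors -------------------------------------------------
    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    @property
    def n_iterations(self) -> int:
        return self.diagnostics.iterations

    @property
    def focus_amplitudes(self) -> np.ndarray:
        """Achieved |p| at each focus at the terminating iteration."""
        return self.diagnostics.final_amplitudes

    @property
    def design_uniformity(self) -> float:
        """In-loop focal-amplitude spread (max-min)/max at termination."""
        return self.diagnostics.final_uniformity

    # -- field evaluation ------------------------------------------------------
    def hologram_field(self) -> ComplexField:
        """Piston-magnitude field at z = 0 carrying the designed phase."""
        src = self.model.source_field()
        return ComplexField(
            grid=self.model.grid,
            values=np.abs(src.values) * np.exp(1j * self.phase.phase),
            frequency=self.model.source.frequency,
            z_position=0.0,
        )

    def propagate(self, z: float) -> ComplexField:
        """Field of the final design at one axial position."""
        return propagate(
            self.hologram_field(),
            z,
            self.model.medium,
            pad_factor=self.model.config.padding_factor,
        )

    def simulate_volume(self, z_list: Sequence[float]) -> FieldStack:
        return propagate_volume(
            self.hologram_field(),
            z_list,
            self.model.medium,
            pad_factor=self.model.config.padding_factor,
        )

    def default_z_list(self, dz_step: float = 0.2e-3) -> np.ndarray:
        """Axial sampling bracketing the target planes (0.2 mm step)."""
        zs = [t.z for t in self.model.targets]
        lo = max(0.5e-3, 0.5 * min(zs))
        hi = 1.75 * max(zs)
        return np.arange(lo, hi + dz_step / 2, dz_step)

    def characterize(
        self,
        z_list: Optional[Sequence[float]] = None,
        min_separation: float = 2e-3,
    ) -> tuple[pd.DataFrame, FieldStack]:
        """Locate and characterize as many foci as the design targets.

        Returns a DataFrame (one row per focus, sorted to match the target
        order by nearest position) and the simulated field stack.
        """
        if z_list is None:
            z_list = self.default_z_list()
        stack = self.simulate_volume(z_list)
        peaks = find_foci(stack, n_expected=len(self.model.targets), min_separation=min_separation)
        # match peaks to targets by nearest 3D position
        rows = []
        remaining = list(peaks)
        for i, t in enumerate(self.model.targets):
            d = [
                (p.x - t.x) ** 2 + (p.y - t.y) ** 2 + (p.z - t.z) ** 2
                for p in remaining
            ]
            p = remaining.pop(int(np.argmin(d)))
            m = characterize_focus(stack, p)
            rows.append(
                {
                    "target": i + 1,
                    "x_mm": m.x_mm,
                    "y_mm": m.y_mm,
                    "z_mm": m.z_mm,
                    "peak_pressure": m.peak_pressure,
                    "lateral_fwhm_mm": m.lateral_fwhm_mm,
                    "axial_fwhm_mm": m.axial_fwhm_mm,
                    "focal_length_mm": m.focal_length_mm,
                }
            )
        return pd.DataFrame(rows), stack

    def focus_uniformity(self, z_list: Optional[Sequence[float]] = None) -> float:
        """Spread (max-min)/max of re-simulated peak pressures across foci."""
        from .design import uniformity

        table, _ = self.characterize(z_list)
        return uniformity(table["peak_pressure"].to_numpy())

    def simulate_through_lens(
        self,
        z_list: Sequence[float],
        lens_material=None,
        base_thickness: float = 0.5e-3,
        slice_step: float = 0.1e-3,
    ) -> FieldStack:
        """Simulate with the lens as a physical layer (split-step slices).

        The printed lens occupying 0 <= z <= t(x, y) is traversed in thin
        slices: in each slice the pixels still inside the material impart
        the relative phase (k_water - k_lens) * dz and the material's bulk
        absorption, and the slice gap is bridged by water propagation.
        Compared to the default apply-phase mode this captures diffraction
        within the lens body, which pushes the focus slightly deeper; the
        returned stack is referenced to the lens base (z = 0).

        ``z_list`` entries must all lie beyond the maximum lens thickness.
        """
        from .lens import VISJET_M2R_WT

        material = lens_material if lens_material is not None else VISJET_M2R_WT
        tmap = self.to_thickness(material, base_thickness)
        t = tmap.thickness
        k_w = self.model.medium.wavenumber(self.model.source.frequency)
        k_l = material.wavenumber(self.model.source.frequency)
        t_max = float(t.max())
        z_arr = np.asarray(z_list, dtype=float)
        if np.any(z_arr < t_max):
            raise ValueError("evaluation planes must lie beyond the lens relief")
        n_slices = max(1, int(np.ceil(t_max / slice_step)))
        dz = t_max / n_slices
        att = 10.0 ** (-material.attenuation_db_cm * (dz * 100.0) / 20.0)
        field = self.model.source_field()
        pad = self.model.config.padding_factor
        for i in range(n_slices):
            z_mid = (i + 0.5) * dz
            inside = t > z_mid
            screen = np.where(inside, np.exp(1j * (k_w - k_l) * dz) * att, 1.0)
            field = ComplexField(
                grid=field.grid,
                values=field.values * screen,
                frequency=field.frequency,
                z_position=field.z_position,
            )
            field = propagate(field, dz, self.model.medium, pad_factor=pad)
        return propagate_volume(field, z_arr, self.model.medium, pad_factor=pad)

    # -- physical realization --------------------------------------------------
    def to_thickness(self, lens_material=None, base_thickness: float = 0.5e-3):
        from .lens import VISJET_M2R_WT, phase_to_thickness

        material = lens_material if lens_material is not None else VISJET_M2R_WT
        return phase_to_thickness(
            self.phase, material, self.model.medium, base_thickness=base_thickness
        )

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fitted design."""
        m = self.model
        lines = []
        w = 66
        lines.append("Acoustic Hologram Design Results".center(w))
        lines.append("=" * w)
        lines.append(f"{'Frequency:':<28}{m.source.frequency / 1e6:.2f} MHz")
        lines.append(f"{'Aperture diameter:':<28}{m.source.diameter * 1e3:.1f} mm")
        lines.append(
            f"{'Grid:':<28}{m.grid.nx} x {m.grid.ny} @ {m.grid.dx * 1e6:.0f} um"
        )
        lines.append(f"{'Medium c, rho:':<28}{m.medium.sound_speed:.0f} m/s, "
                     f"{m.medium.density:.0f} kg/m3")
        lines.append(f"{'Iterations used:':<28}{self.n_iterations} "
                     f"(cap {m.config.max_iterations})")
        lines.append(f"{'Converged:':<28}{self.converged}")
        if len(m.targets) >= 2:
            lines.append(
                f"{'Focal amplitude spread:':<28}{self.design_uniformity * 100:.1f} % "
                f"(tol {m.config.uniformity_tol * 100:.0f} %)"
            )
        lines.append("-" * w)
        lines.append(f"{'focus':>6}{'x (mm)':>10}{'y (mm)':>10}{'z (mm)':>10}"
                     f"{'weight':>10}{'achieved':>12}")
        amps = self.focus_amplitudes
        norm = amps.max() if len(amps) else 1.0
        for i, t in enumerate(m.targets):
            lines.append(
                f"{i + 1:>6}{t.x * 1e3:>10.2f}{t.y * 1e3:>10.2f}"
                f"{t.z * 1e3:>10.2f}{t.weight:>10.2f}{amps[i] / norm:>12.3f}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<HologramDesignResults: {len(self.model.targets)} foci, "
            f"{self.n_iterations} iterations, converged={self.converged}>"
        )

    # -- plotting --------------------------------------------------------------
    def plot_phase(self, ax=None):  # pragma: no cover - requires matplotlib
        """Phase map image (radians); needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.model.grid
        im = ax.imshow(
            self.phase.phase,
            extent=[g.x[0] * 1e3, g.x[-1] * 1e3, g.y[0] * 1e3, g.y[-1] * 1e3],
            origin="lower",
            cmap="twilight",
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.figure.colorbar(im, ax=ax, label="phase (rad)")
        return ax

    def plot_field(self, stack: FieldStack, plane_index: int, ax=None):  # pragma: no cover
        """Normalized |p| image of one plane of a simulated stack."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = stack.grid
        mag = stack.amplitude[plane_index]
        im = ax.imshow(
            mag / mag.max(),
            extent=[g.x[0] * 1e3, g.x[-1] * 1e3, g.y[0] * 1e3, g.y[-1] * 1e3],
            origin="lower",
            cmap="inferno",
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_title(f"z = {stack.z[plane_index] * 1e3:.1f} mm")
        ax.figure.colorbar(im, ax=ax, label="|p| / max")
        return ax
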