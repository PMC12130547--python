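"""Case configuration and built-in study fixtures.

:class:`CaseConfig` bundles everything one design run needs (source, grid,
targets, loop parameters, lens material) and validates it before any heavy
computation.  At this interface lengths are mm, frequencies MHz and
pressures MPa; everything is converted to SI on construction.

Two fixture families regenerate the reference study cases:

* :func:`fixture_single_focus` - an on-axis single focus at 10, 20 or
  30 mm (or any positive focal length) from a 30 mm, 1.5 MHz piston.
* :func:`fixture_biplane` - the three-focus, two-plane brain-targeting
  layout: two foci at (-1.8, 2.6) mm and (1.7, 2.6) mm on the 17.8 mm
  plane and one at (-0.3, -0.5) mm on the 19.8 mm plane, all with unit
  initial weight.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .design import DesignConfig, FocusTarget
from .grids import Medium, PistonSource, PlaneGrid, WATER, make_grid
from .lens import MaterialProps, VISJET_M2R_WT

__all__ = [
    "CaseConfig",
    "fixture_single_focus",
    "fixture_biplane",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger("holobeam")

#: Default transducer aperture (mm).  The vendor sheet of the 1.5 MHz
#: plane-wave element does not print the active diameter; 30 mm matches the
#: element family naming and is exposed per case.
DEFAULT_APERTURE_MM = 30.0
DEFAULT_GRID_N = 384


@dataclass
class CaseConfig:
    """One fully specified design/evaluation case."""

    name: str
    source: PistonSource
    grid: PlaneGrid
    targets: Sequence[FocusTarget]
    design: DesignConfig = dc_field(default_factory=DesignConfig)
    medium: Medium = WATER
    lens_material: MaterialProps = VISJET_M2R_WT

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("case needs at least one target")
        if self.source.diameter > min(self.grid.extent_x, self.grid.extent_y):
            raise ValueError("aperture does not fit inside the grid")
        half_x = self.grid.extent_x / 2
        half_y = self.grid.extent_y / 2
        for t in self.targets:
            if abs(t.x) > half_x or abs(t.y) > half_y:
                raise ValueError("target outside grid extent")

    def to_dict(self) -> dict:
        """mm/MHz/MPa dictionary representation (YAML-serializable).

        Interface values are rounded to 9 decimals so that a save/load
        cycle is exactly idempotent despite the SI unit conversions.
        """
        r = lambda v: round(float(v), 9)
        return {
            "name": self.name,
            "source": {
                "diameter_mm": r(self.source.diameter * 1e3),
                "frequency_mhz": r(self.source.frequency / 1e6),
                "surface_pressure_mpa": r(self.source.surface_pressure / 1e6),
            },
            "grid": {"nx": self.grid.nx, "ny": self.grid.ny,
                     "dx_um": r(self.grid.dx * 1e6)},
            "targets": [
                {"x_mm": r(t.x * 1e3), "y_mm": r(t.y * 1e3), "z_mm": r(t.z * 1e3),
                 "weight": r(t.weight)}
                for t in self.targets
            ],
            "design": {
                "max_iterations": self.design.max_iterations,
                "uniformity_tol": self.design.uniformity_tol,
                "weight_exponent": self.design.weight_exponent,
                "focus_disk_radius_mm": (
                    None if self.design.focus_disk_radius is None
                    else self.design.focus_disk_radius * 1e3
                ),
                "seed": self.design.seed,
                "random_phase_init": self.design.random_phase_init,
                "padding_factor": self.design.padding_factor,
            },
            "medium": {
                "sound_speed": self.medium.sound_speed,
                "density": self.medium.density,
                "attenuation_db_cm": self.medium.attenuation_db_cm,
            },
            "lens_material": {
                "sound_speed": self.lens_material.sound_speed,
                "density": self.lens_material.density,
                "attenuation_db_cm": self.lens_material.attenuation_db_cm,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        src = d["source"]
        grd = d["grid"]
        des = d.get("design", {})
        med = d.get("medium", {})
        lens = d.get("lens_material", {})
        radius = des.get("focus_disk_radius_mm")
        return cls(
            name=d.get("name", "case"),
            source=PistonSource(
                diameter=src["diameter_mm"] * 1e-3,
                frequency=src["frequency_mhz"] * 1e6,
                surface_pressure=src.get("surface_pressure_mpa", 1e-6) * 1e6,
            ),
            grid=make_grid(grd["nx"], grd["ny"], grd["dx_um"] * 1e-6),
            targets=[
                FocusTarget(
                    x=t["x_mm"] * 1e-3, y=t["y_mm"] * 1e-3, z=t["z_mm"] * 1e-3,
                    weight=t.get("weight", 1.0),
                )
                for t in d["targets"]
            ],
            design=DesignConfig(
                max_iterations=des.get("max_iterations", 100),
                uniformity_tol=des.get("uniformity_tol", 0.05),
                weight_exponent=des.get("weight_exponent", 1.0),
                focus_disk_radius=None if radius is None else radius * 1e-3,
                seed=des.get("seed", 0),
                random_phase_init=des.get("random_phase_init", False),
                padding_factor=des.get("padding_factor", 2.0),
            ),
            medium=Medium(
                sound_speed=med.get("sound_speed", WATER.sound_speed),
                density=med.get("density", WATER.density),
                attenuation_db_cm=med.get("attenuation_db_cm", 0.0),
            ),
            lens_material=MaterialProps(
                sound_speed=lens.get("sound_speed", VISJET_M2R_WT.sound_speed),
                density=lens.get("density", VISJET_M2R_WT.density),
                attenuation_db_cm=lens.get(
                    "attenuation_db_cm", VISJET_M2R_WT.attenuation_db_cm
                ),
            ),
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def load_config(path) -> CaseConfig:
    """Read a case from a YAML or JSON file (mm/MHz/MPa units)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return CaseConfig.from_dict(json.loads(text))
    return CaseConfig.from_dict(yaml.safe_load(text))


def _default_source() -> PistonSource:
    return PistonSource(
        diameter=DEFAULT_APERTURE_MM * 1e-3, frequency=1.5e6, surface_pressure=1.0
    )


def fixture_single_focus(
    focal_length_mm: float,
    grid_n: int = DEFAULT_GRID_N,
) -> CaseConfig:
    """On-axis single-focus case at the given focal length (mm)."""
    if not focal_length_mm > 0:
        raise ValueError("focal length must be positive")
    return CaseConfig(
        name=f"single_focus_{focal_length_mm:g}mm",
        source=_default_source(),
        grid=make_grid(grid_n, grid_n, 100e-6),
        targets=[FocusTarget(0.0, 0.0, focal_length_mm * 1e-3)],
    )


def fixture_biplane(grid_n: int = DEFAULT_GRID_N) -> CaseConfig:
    """Three-focus, two-plane brain-targeting case with unit weights."""
    return CaseConfig(
        name="biplane_three_focus",
        source=_default_source(),
        grid=make_grid(grid_n, grid_n, 100e-6),
        targets=[
            FocusTarget(-1.8e-3, 2.6e-3, 17.8e-3),
            FocusTarget(1.7e-3, 2.6e-3, 17.8e-3),
            FocusTarget(-0.3e-3, -0.5e-3, 19.8e-3),
        ],
    )


def run_pipeline(
    config: CaseConfig,
    outdir,
    z_list: Optional[Sequence[float]] = None,
) -> dict:
    """Design -> lens conversion -> simulation -> metrics -> export.

    Writes the phase map (TIFF + CSV), the thickness map (TIFF), a metrics
    CSV with one row per focus, and a run manifest (config, versions,
    timings).  Returns a dict of output paths plus the metrics table.
    """
    from . import __version__
    from .io import export_phase_csv, export_phase_tiff
    from .lens import export_lens
    from .model import HologramDesign

    outdir = Path(outdir)
    if not outdir.exists():
        outdir.mkdir(parents=True)
        logger.info("created output directory %s", outdir)

    timings = {}
    stage = "design"
    try:
        t0 = time.perf_counter()
        model = HologramDesign(
            targets=config.targets,
            source=config.source,
            grid=config.grid,
            medium=config.medium,
            config=config.design,
        )
        result = model.fit()
        timings["design_s"] = round(time.perf_counter() - t0, 3)
        logger.info(
            "design: %d iterations, converged=%s",
            result.n_iterations, result.converged,
        )

        stage = "lens"
        t0 = time.perf_counter()
        thickness = result.to_thickness(config.lens_material)
        timings["lens_s"] = round(time.perf_counter() - t0, 3)

        stage = "simulate"
        t0 = time.perf_counter()
        table, stack = result.characterize(z_list)
        timings["simulate_s"] = round(time.perf_counter() - t0, 3)
        logger.info("simulate: %d planes, %d foci", len(stack.z), len(table))

        stage = "export"
        paths = {
            "phase_tiff": export_phase_tiff(result.phase, outdir / "phase.tiff"),
            "phase_csv": export_phase_csv(result.phase, outdir / "phase.csv"),
            "thickness_tiff": export_lens(thickness, outdir / "thickness.tiff", "tiff"),
            "metrics_csv": outdir / "metrics.csv",
            "manifest": outdir / "manifest.json",
        }
        table = table.assign(case=config.name)
        table.to_csv(paths["metrics_csv"], index=False)
        cfg = config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "holobeam_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.design.seed,
            "iterations": result.n_iterations,
            "converged": bool(result.converged),
            "timings": timings,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"paths": paths, "metrics": table, "result": result}
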