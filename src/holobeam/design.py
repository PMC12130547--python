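"""Weighted iterative angular spectrum hologram design (Gerchberg-Saxton style).

The design loop alternates between the hologram plane (z = 0) and one or
more target planes.  Each iteration forward-propagates the current
hologram-plane field to every target plane, replaces the magnitude there by
the weighted target image while keeping the phase, back-propagates each
plane to z = 0, sums the back-propagated complex fields, and re-imposes the
source (piston aperture) magnitude while keeping the phase.  Per-focus
amplitude weights are adjusted proportionally until the relative spread of
achieved focal amplitudes drops below the uniformity tolerance (default 5%),
with a hard cap of 100 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from .grids import ComplexField, Medium, PlaneGrid, WATER
from .propagation import backpropagate, propagate

__all__ = [
    "FocusTarget",
    "TargetPlane",
    "DesignConfig",
    "HologramPhase",
    "DesignDiagnostics",
    "rasterize_targets",
    "run_iasa",
    "update_weights",
    "uniformity",
    "wrap_phase",
]


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap angles to [0, 2*pi)."""
    return np.mod(phase, 2.0 * np.pi)


@dataclass(frozen=True)
class FocusTarget:
    """One desired focal spot.

    x, y are lateral positions and z the target-plane distance from the
    transducer surface, all in metres.  ``weight`` is the desired relative
    focal amplitude (dimensionless, initial value 1).
    """

    x: float
    y: float
    z: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.z > 0:
            raise ValueError("focus plane distance z must be positive")
        if not self.weight > 0:
            raise ValueError("focus weight must be positive")


@dataclass
class TargetPlane:
    """Target amplitude image on one plane at distance z.

    ``amplitude_image`` is the nonnegative desired magnitude per pixel; the
    background (outside the focal disks) is zero, which the loop imposes as
    part of the amplitude constraint.  When built by
    :func:`rasterize_targets` the contributing foci and disk radius are kept
    so the loop can re-rasterize with updated weights and measure achieved
    amplitudes inside each disk.
    """

    z: float
    amplitude_image: np.ndarray
    grid: PlaneGrid
    foci: Sequence[FocusTarget] = ()
    disk_radius: float = 0.0

    def __post_init__(self) -> None:
        self.amplitude_image = np.asarray(self.amplitude_image, dtype=float)
        if not self.z > 0:
            raise ValueError("plane distance must be positive")
        if self.amplitude_image.shape != self.grid.shape:
            raise ValueError("amplitude image shape must match grid")
        if np.any(self.amplitude_image < 0):
            raise ValueError("target amplitudes must be nonnegative")
        if not np.any(self.amplitude_image > 0):
            raise ValueError("target image needs at least one nonzero pixel")


@dataclass
class DesignConfig:
    """Tunable parameters of the iterative design loop.

    max_iterations : hard cap on forward/backward sweeps (default 100).
    uniformity_tol : stop once (max-min)/max of achieved focal amplitudes,
        relative to their desired weights, falls below this (default 0.05).
    weight_exponent : exponent of the proportional weight correction
        (1.0 = direct proportional; 0 disables adaptation).
    focus_disk_radius : radius of the rasterized focal disks; ``None``
        means half the water wavelength at the working frequency.
    random_phase_init : start from a seeded random phase instead of the
        deterministic zero phase (rarely needed; helps escape symmetric
        stagnation).
    padding_factor : linear zero-padding factor of the computational grid.
    lens_material : when set, the hologram-plane amplitude is recalibrated
        each iteration by the transmission/absorption of the physical lens
        realizing the current phase map.
    """

    max_iterations: int = 100
    uniformity_tol: float = 0.05
    weight_exponent: float = 1.0
    focus_disk_radius: Optional[float] = None
    seed: int = 0
    random_phase_init: bool = False
    padding_factor: float = 2.0
    lens_material: Optional["object"] = None  # MaterialProps, lazy import
    lens_base_thickness: float = 0.5e-3

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.uniformity_tol < 1:
            raise ValueError("uniformity_tol must be in (0, 1)")


@dataclass
class HologramPhase:
    """Designed phase profile, wrapped to [0, 2*pi), on the design grid."""

    grid: PlaneGrid
    phase: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != self.grid.shape:
            raise ValueError("phase shape must match grid")
        if np.any(self.phase < 0) or np.any(self.phase >= 2 * np.pi):
            raise ValueError("phase must be wrapped to [0, 2*pi)")


@dataclass
class DesignDiagnostics:
    """Per-iteration record of the design loop.

    ``focus_amplitudes[k]`` holds the achieved |p| at every focus at
    iteration k (order: planes in input order, foci within plane in input
    order).  ``uniformity_history`` is the weighted focal-amplitude spread
    per iteration; it is recorded as observed and need not be monotone.
    """

    focus_amplitudes: list = dc_field(default_factory=list)
    uniformity_history: list = dc_field(default_factory=list)
    weight_history: list = dc_field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def final_amplitudes(self) -> np.ndarray:
        return np.asarray(self.focus_amplitudes[-1])

    @property
    def final_uniformity(self) -> float:
        return float(self.uniformity_history[-1])


def rasterize_targets(
    foci: Sequence[FocusTarget],
    z: float,
    grid: PlaneGrid,
    disk_radius: float,
) -> TargetPlane:
    """Rasterize foci sharing one plane into a target amplitude image.

    Each focus becomes a filled disk of the given radius with magnitude
    equal to its weight.  Disks must lie inside the grid and must not
    overlap (overlap would make per-focus amplitudes ambiguous).
    """
    if not foci:
        raise ValueError("need at least one focus")
    if not disk_radius > 0:
        raise ValueError("disk_radius must be positive")
    for f in foci:
        if abs(f.z - z) > 1e-12:
            raise ValueError("all foci must share the plane distance z")
    X, Y = grid.meshgrid()
    half_x, half_y = grid.extent_x / 2, grid.extent_y / 2
    image = np.zeros(grid.shape)
    covered = np.zeros(grid.shape, dtype=bool)
    for f in foci:
        if abs(f.x) + disk_radius > half_x or abs(f.y) + disk_radius > half_y:
            raise ValueError(
                f"focus at ({f.x * 1e3:.1f}, {f.y * 1e3:.1f}) mm falls outside the grid"
            )
        disk = (X - f.x) ** 2 + (Y - f.y) ** 2 <= disk_radius**2
        if np.any(disk & covered):
            raise ValueError("focal disks overlap; reduce disk_radius or separate foci")
        image[disk] = f.weight
        covered |= disk
    return TargetPlane(
        z=z, amplitude_image=image, grid=grid, foci=tuple(foci), disk_radius=disk_radius
    )


def update_weights(
    achieved: np.ndarray,
    desired: np.ndarray,
    weights: np.ndarray,
    exponent: float = 1.0,
) -> np.ndarray:
    """Proportional per-focus weight correction, renormalized to mean 1.

    w_i <- w_i * (desired_i / achieved_i)^exponent.  A focus with zero
    achieved amplitude has been lost by the optimization and is an error.
    """
    achieved = np.asarray(achieved, dtype=float)
    desired = np.asarray(desired, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(achieved <= 0):
        raise ValueError("achieved amplitude is zero at a focus (focus lost)")
    new = weights * (desired / achieved) ** exponent
    return new / new.mean()


def uniformity(amplitudes) -> float:
    """Relative spread (max - min) / max of focal amplitudes."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("uniformity needs at least two focal amplitudes")
    if np.any(amps < 0) or amps.max() <= 0:
        raise ValueError("amplitudes must be nonnegative with a positive max")
    return float((amps.max() - amps.min()) / amps.max())


def _achieved_amplitude(
    field_values: np.ndarray, plane: TargetPlane
) -> list[float]:
    """Peak |p| inside each rasterized focal disk (robust to sub-pixel drift)."""
    X, Y = plane.grid.meshgrid()
    mag = np.abs(field_values)
    out = []
    for f in plane.foci:
        disk = (X - f.x) ** 2 + (Y - f.y) ** 2 <= plane.disk_radius**2
        out.append(float(mag[disk].max()))
    return out


def run_iasa(
    source: ComplexField,
    planes: Sequence[TargetPlane],
    config: DesignConfig | None = None,
    medium: Medium = WATER,
) -> tuple[HologramPhase, DesignDiagnostics]:
    """Run the weighted iterative angular spectrum design loop.

    Parameters
    ----------
    source : ComplexField
        Piston boundary field at z = 0; its magnitude is the source
        amplitude constraint, its aperture the emitting region.
    planes : sequence of TargetPlane
        Target amplitude images at distinct plane distances.
    config : DesignConfig
        Loop parameters; defaults follow the class docstring.

    Returns
    -------
    (HologramPhase, DesignDiagnostics)
        Final wrapped phase on the design grid and the per-iteration
        convergence record.  The diagnostics' final focus amplitudes are
        measured from the returned field itself, so re-propagating the
        final design reproduces them exactly.
    """
    if config is None:
        config = DesignConfig()
    if not planes:
        raise ValueError("need at least one target plane")
    zs = [p.z for p in planes]
    if len(set(zs)) != len(zs):
        raise ValueError("target planes must be at distinct distances")

    source_amp = np.abs(source.values)
    if config.random_phase_init:
        rng = np.random.default_rng(config.seed)
        init_phase = rng.uniform(0, 2 * np.pi, size=source_amp.shape)
    else:
        init_phase = np.zeros_like(source_amp)
    current = ComplexField(
        grid=source.grid,
        values=source_amp * np.exp(1j * init_phase),
        frequency=source.frequency,
        z_position=0.0,
    )

    all_foci = [f for p in planes for f in p.foci]
    n_foci = len(all_foci)
    desired = np.array([f.weight for f in all_foci]) if n_foci else np.array([])
    weights = desired.copy()

    lens_factor = None
    diag = DesignDiagnostics()
    pad = config.padding_factor

    for it in range(1, config.max_iterations + 1):
        # (a) forward propagate to every target plane
        try:
            forwards = [
                propagate(current, p.z, medium, pad_factor=pad) for p in planes
            ]
        except ValueError as exc:  # overflow to non-finite values mid-loop
            raise FloatingPointError(
                f"non-finite field at iteration {it}; aborting design: {exc}"
            ) from exc

        # (b) record achieved amplitude at each focus
        achieved = []
        for p, fw in zip(planes, forwards):
            achieved.extend(_achieved_amplitude(fw.values, p))
        achieved = np.asarray(achieved)
        diag.focus_amplitudes.append(achieved.tolist())
        diag.weight_history.append(weights.tolist())
        diag.iterations = it
        if n_foci >= 2:
            u = uniformity(achieved / desired)
            diag.uniformity_history.append(u)
            if u < config.uniformity_tol:
                diag.converged = True
                break
        else:
            diag.uniformity_history.append(0.0)
            if it == config.max_iterations:
                diag.converged = True

        if it == config.max_iterations:
            break

        # (h, applied before the next sweep) proportional weight adjustment
        if n_foci >= 2 and config.weight_exponent != 0.0:
            weights = update_weights(
                achieved, desired, weights, config.weight_exponent
            )

        # (c) amplitude constraint at each target plane, phase kept
        constrained = []
        for p, fw in zip(planes, forwards):
            if p.foci:
                img = rasterize_targets(
                    [
                        FocusTarget(f.x, f.y, f.z, w)
                        for f, w in zip(
                            p.foci,
                            weights[_plane_slice(planes, p)],
                        )
                    ],
                    p.z,
                    p.grid,
                    p.disk_radius,
                ).amplitude_image
            else:
                img = p.amplitude_image
            constrained.append(
                ComplexField(
                    grid=p.grid,
                    values=img * np.exp(1j * np.angle(fw.values)),
                    frequency=source.frequency,
                    z_position=p.z,
                )
            )

        # (d, e) back-propagate each plane to z = 0 and sum
        summed = np.zeros_like(current.values)
        for cf in constrained:
            summed += backpropagate(cf, cf.z_position, medium, pad_factor=pad).values

        # (f) source constraint: piston magnitude, phase kept
        new_phase = np.angle(summed)
        magnitude = source_amp
        # (g) optional lens amplitude recalibration
        if config.lens_material is not None:
            from .lens import lens_amplitude_map, phase_to_thickness

            holo = HologramPhase(
                grid=source.grid, phase=wrap_phase(new_phase), frequency=source.frequency
            )
            tmap = phase_to_thickness(
                holo,
                config.lens_material,
                medium,
                base_thickness=config.lens_base_thickness,
            )
            lens_factor = lens_amplitude_map(
                tmap, config.lens_material, medium, source.frequency
            )
            magnitude = source_amp * lens_factor
        current = ComplexField(
            grid=source.grid,
            values=magnitude * np.exp(1j * new_phase),
            frequency=source.frequency,
            z_position=0.0,
        )

    phase = HologramPhase(
        grid=source.grid,
        phase=wrap_phase(np.angle(current.values)),
        frequency=source.frequency,
    )
    return phase, diag


def _plane_slice(planes: Sequence[TargetPlane], plane: TargetPlane) -> slice:
    """Index range of a plane's foci within the flattened focus list."""
    start = 0
    for p in planes:
        if p is plane:
            return slice(start, start + len(p.foci))
        start += len(p.foci)
    raise ValueError("plane not in list")
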