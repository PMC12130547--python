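"""Independent numerical oracles used by the test suite.

The Rayleigh-Sommerfeld double sum evaluates the first Rayleigh-Sommerfeld
diffraction integral directly,

    p(x, y, z) = sum over source pixels of
                 p0 * z * exp(j k R) * (1 - j k R) / (2 pi R^3) * dx^2,

with R the source-to-field-point distance.  It is an O(N^4) brute-force
reference for the FFT-based angular-spectrum propagator; the kernel's sign
convention was fixed against the plane-wave closed form exp(+j k z).
"""

from __future__ import annotations

import numpy as np

from holobeam import ComplexField, Medium


def rayleigh_sommerfeld(field: ComplexField, z: float, medium: Medium) -> np.ndarray:
    """Brute-force propagation of a sampled field to the plane at +z."""
    k = medium.wavenumber(field.frequency)
    g = field.grid
    X, Y = g.meshgrid()
    src = field.values
    out = np.zeros_like(src)
    dx2 = g.dx**2
    for iy in range(g.ny):
        for ix in range(g.nx):
            R = np.sqrt((X - g.x[ix]) ** 2 + (Y - g.y[iy]) ** 2 + z**2)
            K = z * np.exp(1j * k * R) * (1 - 1j * k * R) / (2 * np.pi * R**3)
            out[iy, ix] = np.sum(src * K) * dx2
    return out


def fresnel_lens_phase(grid, focal_length: float, k0: float) -> np.ndarray:
    """Analytic converging-lens phase k0 (F - sqrt(r^2 + F^2)), unwrapped."""
    X, Y = grid.meshgrid()
    return -k0 * (np.sqrt(X**2 + Y**2 + focal_length**2) - focal_length)
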