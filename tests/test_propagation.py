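"""Angular-spectrum propagation: transforms, transfer factor, oracles."""

import numpy as np
import pytest

from holobeam import (
    ComplexField,
    PistonSource,
    WATER,
    backpropagate,
    from_angular_spectrum,
    make_grid,
    make_piston_source,
    make_propagator,
    propagate,
    propagate_volume,
    to_angular_spectrum,
)
from oracles import fresnel_lens_phase, rayleigh_sommerfeld

F0 = 1.5e6


def _field(grid, values):
    return ComplexField(grid=grid, values=values, frequency=F0)


class TestTransforms:
    def test_constant_field_is_dc_only(self):
        g = make_grid(32, 32, 1e-4)
        spec = to_angular_spectrum(_field(g, np.full((32, 32), 2.0 + 0j)))
        mag = np.abs(spec.values)
        assert mag[0, 0] == pytest.approx(2.0 * 32 * 32)
        assert np.all(mag.ravel()[1:] < 1e-9)

    def test_impulse_has_flat_spectrum(self):
        g = make_grid(32, 32, 1e-4)
        v = np.zeros((32, 32), dtype=complex)
        v[5, 7] = 1.0
        spec = to_angular_spectrum(_field(g, v))
        assert np.allclose(np.abs(spec.values), 1.0)

    def test_parseval(self):
        rng = np.random.default_rng(42)
        g = make_grid(48, 48, 1e-4)
        v = rng.standard_normal((48, 48)) + 1j * rng.standard_normal((48, 48))
        spec = to_angular_spectrum(_field(g, v))
        direct = np.sum(np.abs(v) ** 2)
        via_spec = np.sum(np.abs(spec.values) ** 2) / (48 * 48)
        assert via_spec == pytest.approx(direct, rel=1e-12)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(7)
        g = make_grid(32, 32, 1e-4)
        v = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        back = from_angular_spectrum(to_angular_spectrum(_field(g, v)))
        assert np.abs(back.values - v).max() < 1e-10 * np.abs(v).max()


class TestPropagator:
    def test_zero_step_is_identity(self):
        kx = 2 * np.pi * np.fft.fftfreq(32, 1e-4)
        prop = make_propagator(kx, kx, 0.0, WATER, F0)
        assert np.allclose(prop.H, 1.0)

    def test_on_axis_phase_one_wavelength(self):
        lam = WATER.sound_speed / F0
        kx = 2 * np.pi * np.fft.fftfreq(32, 1e-4)
        prop = make_propagator(kx, kx, lam, WATER, F0)
        # DC bin advances by exactly 2*pi over one wavelength
        assert np.angle(prop.H[0, 0]) == pytest.approx(0.0, abs=1e-9)
        assert prop.H[0, 0].real == pytest.approx(1.0)

    def test_unit_magnitude_on_propagating_band(self):
        kx = 2 * np.pi * np.fft.fftfreq(64, 1e-4)
        prop = make_propagator(kx, kx, 7e-3, WATER, F0)
        assert np.allclose(np.abs(prop.H[~prop.evanescent]), 1.0)
        assert np.all(np.abs(prop.H[prop.evanescent]) <= 1.0)

    def test_backward_zeroes_evanescent(self):
        kx = 2 * np.pi * np.fft.fftfreq(64, 1e-4)
        prop = make_propagator(kx, kx, -7e-3, WATER, F0)
        assert np.all(prop.H[prop.evanescent] == 0)


class TestPropagate:
    def test_plane_wave_global_phase_advance(self):
        # without padding the FFT is periodic, so a uniform field is a true
        # infinite plane wave: amplitude unchanged, global phase k0*dz
        g = make_grid(32, 32, 1e-4)
        f = _field(g, np.ones((32, 32), dtype=complex))
        dz = 3.3e-3
        out = propagate(f, dz, WATER, pad_factor=1)
        k0 = WATER.wavenumber(F0)
        expected = np.exp(1j * k0 * dz)
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_cannot_cross_transducer_plane(self):
        g = make_grid(32, 32, 1e-4)
        f = _field(g, np.ones((32, 32), dtype=complex))
        with pytest.raises(ValueError):
            propagate(f, -1e-3, WATER)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        g = make_grid(32, 32, 1e-4)
        va = rng.standard_normal((32, 32)) + 0j
        vb = rng.standard_normal((32, 32)) + 0j
        a, b = 2.0 - 1j, 0.5 + 3j
        lhs = propagate(_field(g, a * va + b * vb), 5e-3, WATER).values
        rhs = a * propagate(_field(g, va), 5e-3, WATER).values + b * propagate(
            _field(g, vb), 5e-3, WATER
        ).values
        assert np.abs(lhs - rhs).max() < 1e-10 * np.abs(lhs).max()

    def test_confined_beam_energy_conserved(self):
        # a gentle Gaussian beam stays inside the grid, so lossless
        # propagation conserves its energy to numerical precision
        g = make_grid(64, 64, 2e-4)
        X, Y = g.meshgrid()
        v = np.exp(-(X**2 + Y**2) / (2 * (1.5e-3) ** 2)).astype(complex)
        f = _field(g, v)
        out = propagate(f, 2e-3, WATER, pad_factor=4)
        e_in = np.sum(np.abs(f.values) ** 2)
        e_out = np.sum(np.abs(out.values) ** 2)
        assert abs(e_out - e_in) / e_in < 1e-6

    def test_forward_backward_round_trip(self):
        # grid wide enough that the diffracting Gaussian's tails never
        # reach the crop boundary at either plane
        g = make_grid(96, 96, 2e-4)
        X, Y = g.meshgrid()
        v = np.exp(-(X**2 + Y**2) / (2 * (1.5e-3) ** 2)).astype(complex)
        f = _field(g, v)
        fwd = propagate(f, 4e-3, WATER, pad_factor=4)
        back = backpropagate(fwd, 4e-3, WATER, pad_factor=4)
        assert np.abs(back.values - f.values).max() < 1e-6 * np.abs(f.values).max()


class TestRayleighSommerfeldAgreement:
    """Cross-check the FFT propagator against the brute-force double sum."""

    @pytest.mark.parametrize("z", [5e-3, 10e-3, 15e-3, 20e-3])
    def test_focused_disk(self, z):
        g = make_grid(64, 64, 1.5e-4)  # 9.6 mm grid
        src = make_piston_source(PistonSource(diameter=8e-3, frequency=F0), g)
        k0 = WATER.wavenumber(F0)
        lens = fresnel_lens_phase(g, 15e-3, k0)
        f = ComplexField(grid=g, values=src.values * np.exp(1j * lens), frequency=F0)
        ours = propagate(f, z, WATER, pad_factor=4).values
        ref = rayleigh_sommerfeld(f, z, WATER)
        rel_rms = np.sqrt(np.mean(np.abs(ours - ref) ** 2)) / np.abs(ref).max()
        assert rel_rms < 0.02

    def test_backpropagated_focus_spreads_to_aperture(self):
        # the focal spot back-propagated to the source plane spreads over a
        # disk roughly the aperture size
        g = make_grid(64, 64, 1.5e-4)
        src = make_piston_source(PistonSource(diameter=8e-3, frequency=F0), g)
        k0 = WATER.wavenumber(F0)
        lens = fresnel_lens_phase(g, 15e-3, k0)
        f = ComplexField(grid=g, values=src.values * np.exp(1j * lens), frequency=F0)
        focal = propagate(f, 15e-3, WATER, pad_factor=4)
        back = backpropagate(focal, 15e-3, WATER, pad_factor=4)
        mag = np.abs(back.values)
        X, Y = g.meshgrid()
        r = np.sqrt(X**2 + Y**2)
        inside = mag[r < 3.5e-3].mean()
        outside = mag[r > 4.5e-3].mean()
        assert inside > 3 * outside


class TestPropagateVolume:
    def test_single_entry_equals_propagate(self):
        g = make_grid(32, 32, 1e-4)
        rng = np.random.default_rng(1)
        f = _field(g, rng.standard_normal((32, 32)) + 0j)
        stack = propagate_volume(f, [4e-3], WATER)
        single = propagate(f, 4e-3, WATER)
        assert np.allclose(stack.values[0], single.values)
        assert len(stack.z) == 1

    def test_plane_count_and_order(self):
        g = make_grid(32, 32, 1e-4)
        f = _field(g, np.ones((32, 32), dtype=complex))
        zs = [1e-3, 2e-3, 5e-3]
        stack = propagate_volume(f, zs, WATER)
        assert stack.values.shape[0] == 3
        assert np.allclose(stack.z, zs)

    @pytest.mark.parametrize("bad", [[3e-3, 1e-3], [-1e-3, 2e-3], []])
    def test_rejects_bad_z_lists(self, bad):
        g = make_grid(32, 32, 1e-4)
        f = _field(g, np.ones((32, 32), dtype=complex))
        with pytest.raises(ValueError):
            propagate_volume(f, bad, WATER)

    def test_focused_field_axial_peak_near_design(self):
        # at this aperture the Fresnel number is low, so the axial peak
        # sits a little proximal to the geometric focus, never beyond it
        g = make_grid(128, 128, 1.5e-4)
        src = make_piston_source(PistonSource(diameter=12e-3, frequency=F0), g)
        k0 = WATER.wavenumber(F0)
        F = 15e-3
        lens = fresnel_lens_phase(g, F, k0)
        f = ComplexField(grid=g, values=src.values * np.exp(1j * lens), frequency=F0)
        zs = np.arange(4e-3, 25e-3, 0.5e-3)
        stack = propagate_volume(f, zs, WATER)
        on_axis = np.abs(stack.values[:, 64, 64])
        z_peak = zs[np.argmax(on_axis)]
        assert 0.75 * F < z_peak <= 1.05 * F
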