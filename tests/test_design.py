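"""Iterative design loop: weights, uniformity, rasterization, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holobeam import (
    DesignConfig,
    FocusTarget,
    PistonSource,
    WATER,
    make_grid,
    make_piston_source,
    rasterize_targets,
    run_iasa,
    uniformity,
    update_weights,
)
from oracles import fresnel_lens_phase


class TestUpdateWeights:
    def test_fixed_point_when_achieved_equals_desired(self):
        w = update_weights([1.0, 2.0], [1.0, 2.0], [1.0, 1.0])
        assert np.allclose(w, [1.0, 1.0])

    def test_underperforming_focus_weight_doubles(self):
        # one focus at half the desired amplitude: its raw correction is x2
        w = update_weights([0.5, 1.0], [1.0, 1.0], [1.0, 1.0], exponent=1.0)
        assert w[0] / w[1] == pytest.approx(2.0)

    def test_exponent_zero_freezes_weights(self):
        w = update_weights([0.3, 1.7], [1.0, 1.0], [1.0, 1.0], exponent=0.0)
        assert np.allclose(w, [1.0, 1.0])

    def test_lost_focus_is_an_error(self):
        with pytest.raises(ValueError):
            update_weights([0.0, 1.0], [1.0, 1.0], [1.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.1, 10.0), min_size=2, max_size=6),
        st.floats(0.1, 2.0),
    )
    def test_mean_one_normalization(self, achieved, exponent):
        desired = np.ones(len(achieved))
        w = update_weights(achieved, desired, desired, exponent)
        assert np.mean(w) == pytest.approx(1.0)


class TestUniformity:
    @pytest.mark.parametrize(
        "amps, expected",
        [
            ((1, 1, 1), 0.0),
            ((0.926, 0.997, 1.0), 0.074),
            ((0.87, 0.89, 1.0), 0.13),
        ],
    )
    def test_relative_spread(self, amps, expected):
        assert uniformity(amps) == pytest.approx(expected)

    def test_needs_two_amplitudes(self):
        with pytest.raises(ValueError):
            uniformity([1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8))
    def test_scale_invariant_and_bounded(self, amps):
        u = uniformity(amps)
        assert 0 <= u < 1
        assert uniformity([3.7 * a for a in amps]) == pytest.approx(u)


class TestRasterizeTargets:
    def test_single_focus_disk(self, small_grid):
        plane = rasterize_targets(
            [FocusTarget(0, 0, 20e-3)], 20e-3, small_grid, 0.5e-3
        )
        assert plane.amplitude_image.max() == 1.0
        n_on = np.count_nonzero(plane.amplitude_image)
        assert abs(n_on - np.pi * 5**2) < 2 * np.pi * 5  # 0.5 mm / 0.1 mm = 5 px

    def test_paper_layout_disks_are_disjoint(self, small_grid):
        # hippocampal foci 3.5 mm apart with 0.5 mm disks: disjoint
        foci = [
            FocusTarget(-1.8e-3, 2.6e-3, 17.8e-3),
            FocusTarget(1.7e-3, 2.6e-3, 17.8e-3),
        ]
        plane = rasterize_targets(foci, 17.8e-3, small_grid, 0.5e-3)
        n_single = np.count_nonzero(
            rasterize_targets(foci[:1], 17.8e-3, small_grid, 0.5e-3).amplitude_image
        )
        assert np.count_nonzero(plane.amplitude_image) == pytest.approx(
            2 * n_single, abs=3
        )

    def test_overlap_rejected(self, small_grid):
        foci = [FocusTarget(0, 0, 10e-3), FocusTarget(0.4e-3, 0, 10e-3)]
        with pytest.raises(ValueError):
            rasterize_targets(foci, 10e-3, small_grid, 0.5e-3)

    def test_out_of_grid_rejected(self, small_grid):
        with pytest.raises(ValueError):
            rasterize_targets(
                [FocusTarget(20e-3, 0, 10e-3)], 10e-3, small_grid, 0.5e-3
            )


class TestRunIasa:
    def test_zero_planes_rejected(self, small_grid, small_source):
        src = make_piston_source(small_source, small_grid)
        with pytest.raises(ValueError):
            run_iasa(src, [], DesignConfig())

    def test_phase_only_design(self, small_design_result):
        """The emitted field keeps the piston magnitude; only phase varies."""
        res = small_design_result
        field = res.hologram_field()
        src = res.model.source_field()
        assert np.allclose(np.abs(field.values), np.abs(src.values))
        assert np.all(res.phase.phase >= 0)
        assert np.all(res.phase.phase < 2 * np.pi)

    def test_single_focus_matches_fresnel_lens(self, small_design_result):
        """A single on-axis design converges to a Fresnel-zone phase map."""
        res = small_design_result
        g = res.model.grid
        k0 = WATER.wavenumber(res.model.source.frequency)
        analytic = fresnel_lens_phase(g, 15e-3, k0)
        X, Y = g.meshgrid()
        aperture = np.sqrt(X**2 + Y**2) <= res.model.source.diameter / 2
        diff = res.phase.phase[aperture] - analytic[aperture]
        # circular correlation: mean resultant of the phase differences
        plv = np.abs(np.mean(np.exp(1j * diff)))
        assert plv > 0.9

    def test_self_consistency_of_final_amplitudes(self):
        """Re-propagating the final design reproduces the recorded focal
        amplitudes exactly: the diagnostics are measured from the returned
        field itself."""
        from holobeam import HologramDesign
        from holobeam.design import _achieved_amplitude
        from holobeam.propagation import propagate

        model = HologramDesign(
            targets=[
                FocusTarget(-1.5e-3, 0, 12e-3),
                FocusTarget(1.5e-3, 0, 12e-3),
            ],
            source=PistonSource(diameter=10e-3, frequency=1.5e6),
            grid=make_grid(128, 128, 100e-6),
            config=DesignConfig(max_iterations=15),
        )
        res = model.fit()
        plane = model.target_planes()[0]
        fwd = propagate(res.hologram_field(), plane.z, WATER,
                        pad_factor=model.config.padding_factor)
        achieved = _achieved_amplitude(fwd.values, plane)
        assert np.allclose(achieved, res.focus_amplitudes, rtol=1e-12)

    def test_diagnostics_record_every_iteration(self, small_design_result):
        d = small_design_result.diagnostics
        assert d.iterations == len(d.focus_amplitudes)
        assert d.iterations == len(d.uniformity_history)

    def test_non_finite_field_aborts(self, small_grid, small_source):
        from holobeam import ComplexField

        src = make_piston_source(small_source, small_grid)
        plane = rasterize_targets(
            [FocusTarget(0, 0, 10e-3)], 10e-3, small_grid, 0.5e-3
        )
        bad = ComplexField(
            grid=small_grid,
            values=np.full(small_grid.shape, 1e308, dtype=complex),
            frequency=1.5e6,
        )
        with pytest.raises(FloatingPointError):
            run_iasa(bad, [plane], DesignConfig(max_iterations=3))

    def test_deterministic_zero_phase_init(self, small_grid, small_source):
        src = make_piston_source(small_source, small_grid)
        plane = rasterize_targets(
            [FocusTarget(0, 0, 10e-3)], 10e-3, small_grid, 0.5e-3
        )
        cfg = DesignConfig(max_iterations=5)
        p1, _ = run_iasa(src, [plane], cfg)
        p2, _ = run_iasa(src, [plane], cfg)
        assert np.array_equal(p1.phase, p2.phase)
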