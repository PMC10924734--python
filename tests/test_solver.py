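"""Solver tests: boundary conditions, single-step behaviour, kernel/numpy
consistency, conservation, a heat-equation oracle, refinement and stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spinecable as sc
from spinecable.physics import (
    DEFAULT_CONSTANTS,
    IonSpecies,
    SpineGeometry,
    mm_to_density,
    rest_state,
)
from spinecable.protocols import MorphologySpec, Phase, Protocol, fixture_generator
from spinecable.solver import (
    SolverSettings,
    apply_dendritic_boundary,
    apply_synaptic_boundary,
    interface_conductivity,
    run,
    stability_scan,
    step,
)

C = DEFAULT_CONSTANTS


class TestInterfaceConductivity:
    def test_equal_segments_pass_through(self):
        assert interface_conductivity(3.7, 3.7) == pytest.approx(3.7, rel=1e-15)

    def test_blocked_interface(self):
        assert interface_conductivity(1.0, 0.0) == 0.0

    def test_series_combination(self):
        assert interface_conductivity(1.0, 3.0) == pytest.approx(1.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            interface_conductivity(-1.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.floats(min_value=1e-6, max_value=1e6))
    def test_bounded_by_min_and_mean(self, s1, s2):
        # the series combination lies between min(s1,s2) and the arithmetic mean
        sif = interface_conductivity(s1, s2)
        assert min(s1, s2) - 1e-9 <= sif <= 0.5 * (s1 + s2) + 1e-9


class TestBoundaries:
    def test_zero_current_ghosts_equal_first_segment(self, ref_geom, species):
        st_ = rest_state(ref_geom, species, -0.070)
        ghost = apply_synaptic_boundary(st_.n, ref_geom, species, 0.0)
        np.testing.assert_array_equal(ghost, st_.n[:, 0])

    def test_sodium_ghost_excess(self, species):
        geom = SpineGeometry.from_region_radii(79.8e-9, 35e-9, 0.25e-6)
        st_ = rest_state(geom, species, -0.070)
        ghost = apply_synaptic_boundary(st_.n, geom, species, 25e-12)
        excess = ghost[0] - st_.n[0, 0]
        assert excess == pytest.approx(1.20e24, rel=2e-3)
        assert excess / mm_to_density(1.0) == pytest.approx(1.99, rel=5e-3)
        np.testing.assert_array_equal(ghost[1:], st_.n[1:, 0])

    def test_ghost_excess_scales_inverse_radius_squared(self, species):
        g1 = SpineGeometry.from_region_radii(79.8e-9, 35e-9, 0.25e-6)
        g2 = SpineGeometry.from_region_radii(2 * 79.8e-9, 35e-9, 0.25e-6)
        st1, st2 = rest_state(g1, species, -0.07), rest_state(g2, species, -0.07)
        e1 = apply_synaptic_boundary(st1.n, g1, species, 25e-12)[0] - st1.n[0, 0]
        e2 = apply_synaptic_boundary(st2.n, g2, species, 25e-12)[0] - st2.n[0, 0]
        assert e1 == pytest.approx(4 * e2, rel=1e-12)

    def test_dendritic_ghost_rest_and_clamp(self, species):
        n_ghost, phi = apply_dendritic_boundary(species, -0.070, None)
        np.testing.assert_allclose(
            n_ghost, [mm_to_density(10.0), mm_to_density(140.0), mm_to_density(10.0)]
        )
        assert phi == -0.070
        _, phi_d = apply_dendritic_boundary(species, -0.070, 6e-3)
        assert phi_d == pytest.approx(-0.064)


class TestStep:
    def test_rest_is_fixed_point(self, tiny, species):
        geom, _, _ = tiny
        st0 = rest_state(geom, species, -0.070)
        st1 = step(st0, geom, 0.5e-9)
        np.testing.assert_array_equal(st1.n, st0.n)

    def test_first_step_only_first_sodium_segment_changes(self, ref_geom, species):
        st0 = rest_state(ref_geom, species, -0.070)
        dt = 0.1e-9
        st1 = step(st0, ref_geom, dt, i_in=25e-12)
        a = ref_geom.a[0]
        expect = dt * 25e-12 / (C.e * np.pi * a**2 * ref_geom.h)
        assert st1.n[0, 0] - st0.n[0, 0] == pytest.approx(expect, rel=1e-6)
        # with zero interior gradients nothing else moves on the first step
        # (up to float rounding of the uniform rest potential)
        np.testing.assert_allclose(st1.n[1:], st0.n[1:], rtol=1e-9)
        np.testing.assert_allclose(st1.n[0, 1:], st0.n[0, 1:], rtol=1e-9)

    def test_kernel_matches_numpy_step(self, species):
        """The compiled kernel and the numpy step integrate identically."""
        morph, _, _ = fixture_generator("tiny")
        geom = morph.to_geometry()
        n_steps, dt = 200, 0.5e-9
        proto = Protocol((Phase(n_steps * dt, 25e-12, clamp_offset=2e-3),))
        traj = run(geom, species, proto, SolverSettings(dt=dt, record_stride=n_steps))
        st_ = rest_state(geom, species, -0.070)
        for _ in range(n_steps):
            st_ = step(st_, geom, dt, i_in=25e-12, clamp_offset=2e-3)
        np.testing.assert_allclose(traj.conc[-1], st_.n, rtol=1e-12)

    def test_closed_box_conserves_each_species(self, species):
        """With all boundaries closed, per-species particle totals are exact."""
        morph, _, _ = fixture_generator("tiny")
        geom = morph.to_geometry()
        st_ = rest_state(geom, species, -0.070)
        # perturb sodium to create gradients (and hence drift + diffusion)
        st_.n[0] *= 1.0 + 0.05 * np.sin(np.arange(geom.n_segments))
        totals0 = (st_.n * geom.volume).sum(axis=1)
        for _ in range(500):
            st_ = step(st_, geom, 0.25e-9, closed=True)
        totals1 = (st_.n * geom.volume).sum(axis=1)
        np.testing.assert_allclose(totals1, totals0, rtol=1e-13)


class TestNeutralDiffusionOracle:
    """A z = 0 tracer reduces the scheme to the explicit heat equation, whose
    discrete cosine modes decay at a known closed-form rate."""

    def _uniform_tracer_geometry(self, n=8):
        return SpineGeometry.from_region_radii(
            50e-9, 50e-9, 50e-9, n_head=3, n_neck=3, n_dend=2, h=0.1e-6
        )

    def test_cosine_mode_decay_rate(self):
        D = 1.0e-9
        tracer = (IonSpecies("X", 0, D, 100.0),)
        geom = self._uniform_tracer_geometry()
        N, h = geom.n_segments, geom.h
        st_ = rest_state(geom, tracer, 0.0)
        m = 1
        x = (np.arange(N) + 0.5) * h
        mode = np.cos(m * np.pi * x / (N * h))
        amp0 = mm_to_density(5.0)
        st_.n[0] += amp0 * mode
        dt, n_steps = 1e-9, 4000
        for _ in range(n_steps):
            st_ = step(st_, geom, dt, closed=True)
        # discrete eigenvalue of the zero-flux Laplacian on segment centers
        lam = 4.0 * D / h**2 * np.sin(m * np.pi / (2 * N)) ** 2
        decay_exact = (1.0 - dt * lam) ** n_steps
        amp1 = (st_.n[0] - mm_to_density(100.0)) @ mode / (mode @ mode)
        assert amp1 / amp0 == pytest.approx(decay_exact, rel=1e-10)
        # and the continuum rate to truncation accuracy
        assert amp1 / amp0 == pytest.approx(
            np.exp(-D * (m * np.pi / (N * h)) ** 2 * dt * n_steps), rel=5e-3
        )

    def test_diffusion_cfl_bound(self):
        """Explicit-Euler stability flips near dt = h^2/(2D) = 5 us."""
        D = 1.0e-9
        tracer = (IonSpecies("X", 0, D, 100.0),)
        geom = self._uniform_tracer_geometry()
        N, h = geom.n_segments, geom.h
        x = (np.arange(N) + 0.5) * h
        mode = np.cos((N - 1) * np.pi * x / (N * h))  # highest mode: worst case

        def amplifies(dt):
            st_ = rest_state(geom, tracer, 0.0)
            st_.n[0] += mm_to_density(1.0) * mode
            a0 = np.abs(st_.n[0] - mm_to_density(100.0)).max()
            for _ in range(200):
                st_ = step(st_, geom, dt, closed=True)
            return np.abs(st_.n[0] - mm_to_density(100.0)).max() > a0

        assert amplifies(8e-6)
        assert not amplifies(4e-6)


class TestRun:
    def test_zero_current_protocol_constant(self, tiny, species):
        geom, protocol, settings = tiny
        traj = sc.run(geom, species, protocol, settings)
        assert traj.status == "ok"
        np.testing.assert_array_equal(traj.conc[-1], traj.conc[0])
        np.testing.assert_allclose(traj.phi, -0.070, rtol=1e-12)

    def test_deterministic_rerun(self, tiny, species):
        geom, _, settings = tiny
        proto = sc.step_protocol(25e-12, 1e-6)
        t1 = sc.run(geom, species, proto, settings)
        t2 = sc.run(geom, species, proto, settings)
        np.testing.assert_array_equal(t1.conc, t2.conc)
        np.testing.assert_array_equal(t1.phi, t2.phi)

    def test_clamp_equal_to_rest_is_identity(self, tiny, species):
        geom, _, settings = tiny
        p_clamped = Protocol((Phase(2e-6, 25e-12, clamp_offset=0.0),))
        p_plain = Protocol((Phase(2e-6, 25e-12),))
        t1 = sc.run(geom, species, p_clamped, settings)
        t2 = sc.run(geom, species, p_plain, settings)
        np.testing.assert_array_equal(t1.conc, t2.conc)

    def test_instability_reported_with_time(self, ref_geom):
        from spinecable.protocols import variant_symmetric_electrolyte

        v = variant_symmetric_electrolyte()
        traj = sc.run(
            ref_geom, v.species, sc.step_protocol(25e-12, 50e-6),
            SolverSettings(dt=0.5e-9, record_stride=2000), phi_rest=v.phi_rest,
        )
        assert traj.status == "unstable"
        assert traj.fail_time is not None and 0 < traj.fail_time <= 50e-6

    def test_cable_mode_matches_series_resistance(self, ref_geom, species):
        """Clamping concentrations reduces the model to the cable equation:
        the steady head depolarization is I times the series resistance."""
        i_in = 25e-12
        traj = sc.run(
            ref_geom, species, sc.step_protocol(i_in, 100e-6),
            SolverSettings(dt=0.5e-9, record_stride=2000), cable_mode=True,
        )
        # independent oracle: sum of interface resistances from the first
        # segment's center to the clamped dendritic ghost
        from spinecable.physics import drift_resistivity

        n_rest = np.array([s.n_rest for s in species])
        r_e = drift_resistivity(n_rest, species)
        a = np.concatenate([ref_geom.a, [ref_geom.a[-1]]])
        sig = a**2 / r_e
        sig_if = 2 * sig[:-1] * sig[1:] / (sig[:-1] + sig[1:])
        R_series = np.sum(ref_geom.h / (np.pi * sig_if[1:]))
        depol = traj.phi[-1, 0] - traj.phi_rest
        assert depol == pytest.approx(i_in * R_series, rel=1e-2)

    def test_dendrite_radius_sensitivity_is_small(self, species):
        """Doubling the dendrite radius barely moves the head voltage."""
        trajs = []
        for dr in (0.25e-6, 0.5e-6):
            geom = MorphologySpec(
                neck_radius=35e-9, head_radius=250e-9, dend_radius=dr
            ).to_geometry()
            trajs.append(
                sc.run(geom, species, sc.step_protocol(25e-12, 100e-6),
                       SolverSettings(dt=0.2e-9, record_stride=5000))
            )
        d0 = trajs[0].phi[-1, 0] - trajs[0].phi_rest
        d1 = trajs[1].phi[-1, 0] - trajs[1].phi_rest
        assert d1 == pytest.approx(d0, rel=3e-2)


class TestStabilityScan:
    def test_scan_returns_largest_stable(self, ref_geom, species):
        best, statuses = stability_scan(
            ref_geom, species, sc.step_protocol(25e-12, 10e-3),
            [1e-9, 0.5e-9], max_duration=50e-6,
        )
        assert best == pytest.approx(0.5e-9)
        assert statuses[1e-9] == "unstable"

    def test_all_unstable_returns_none(self, ref_geom, species):
        best, statuses = stability_scan(
            ref_geom, species, sc.step_protocol(25e-12, 10e-3),
            [4e-9, 2e-9], max_duration=20e-6,
        )
        assert best is None
        assert set(statuses.values()) == {"unstable"}
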