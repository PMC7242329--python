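"""D2Q9 BGK solver: lattice mapping, forcing scheme, steady balances."""

import numpy as np
import pytest

from ciliaflow import (
    LatticeState,
    compute_body_force,
    element_forces,
    lbm_step,
    make_fixture,
    map_to_lattice,
    solve_frozen_orientations,
)
from ciliaflow._kernels import HAVE_NUMBA, step
from ciliaflow.lbm import TAU_MAX, TAU_MIN


class TestLatticeMapping:
    def test_defining_relations_round_trip(self):
        """kappa, U0 and Re definitions hold simultaneously in lattice units."""
        p = map_to_lattice(0.4, 2.0, Re=0.1, resolution=5, target_mach=0.02)
        lat = p.lattice
        D = lat.D
        assert np.sqrt(lat.nu * lat.rho0 / lat.kappa) / D == pytest.approx(2.0, abs=1e-12)
        assert lat.rho0 * D * lat.U0 / (lat.rho0 * lat.nu) == pytest.approx(0.1, abs=1e-12)
        assert lat.fc / lat.kappa == pytest.approx(lat.U0, abs=1e-15)

    def test_unit_lambda_screening_identity(self):
        p = map_to_lattice(0.4, 1.0, Re=0.1)
        lat = p.lattice
        assert np.sqrt(lat.nu * lat.rho0 / lat.kappa) / lat.D == pytest.approx(1.0, abs=1e-12)

    def test_kappa_quarters_when_lambda_doubles(self):
        k1 = map_to_lattice(0.4, 2.0, Re=0.1).lattice.kappa
        k2 = map_to_lattice(0.4, 4.0, Re=0.1).lattice.kappa
        assert k1 / k2 == pytest.approx(4.0, rel=1e-12)

    def test_tau_window_enforced(self):
        with pytest.raises(ValueError, match="stability window"):
            map_to_lattice(0.4, 2.0, Re=0.01, resolution=5, target_mach=0.05)
        p = map_to_lattice(0.4, 2.0, Re=0.1)
        assert TAU_MIN < p.lattice.tau < TAU_MAX

    @pytest.mark.parametrize("bad", [{"phi": 1.2}, {"lambda_": -1}, {"Re": 0}, {"target_mach": 0.5}])
    def test_invalid_inputs_rejected(self, bad):
        kw = {"phi": 0.4, "lambda_": 2.0, "Re": 0.1}
        kw.update(bad)
        with pytest.raises(ValueError):
            map_to_lattice(kw["phi"], kw["lambda_"], kw["Re"], target_mach=kw.get("target_mach", 0.02))


class TestBodyForce:
    def test_zero_flow_no_cilia_gives_zero_force(self, small_tiling, default_params):
        from ciliaflow import assign_ciliated

        emap = assign_ciliated(small_tiling, 0.0, seed=0)
        state = LatticeState.rest(small_tiling.grid_shape)
        fx, fy = compute_body_force(state, emap, default_params)
        assert not fx.any() and not fy.any()

    def test_single_element_force_footprint(self, default_params):
        emap, info = make_fixture("single_element", nx_elements=8, ny_elements=8, angle=0.0)
        state = LatticeState.rest(emap.node_owner.shape)
        fx, fy = compute_body_force(state, emap, default_params)
        on = emap.node_owner == info["element_index"]
        fc = default_params.lattice.fc
        assert np.all(fx[on] == fc) and np.all(fy[on] == 0.0)
        assert not fx[~on].any() and not fy.any()

    def test_uniform_u0_flow_cancels_uniform_forcing(self, default_params):
        """At U = U0 everywhere, friction exactly balances the ciliary force."""
        emap, _ = make_fixture("uniform_forcing", angle=0.0)
        state = LatticeState.rest(emap.node_owner.shape)
        state.ux[:] = default_params.lattice.U0
        fx, fy = compute_body_force(state, emap, default_params)
        assert np.abs(fx).max() < 1e-18 and np.abs(fy).max() < 1e-18


class TestStepping:
    def test_rest_state_is_fixed_point(self, default_params, small_tiling):
        from ciliaflow import assign_ciliated

        emap = assign_ciliated(small_tiling, 0.0, seed=0)
        state = LatticeState.rest(small_tiling.grid_shape)
        f0 = state.f.copy()
        for _ in range(5):
            lbm_step(state, emap, default_params)
        np.testing.assert_allclose(state.f, f0, atol=1e-15)

    def test_uniform_force_accelerates_at_g_over_rho(self):
        """With friction off, a uniform force increases bulk velocity by g/rho per step."""
        p = map_to_lattice(1.0, 2.0, Re=0.1)
        emap, _ = make_fixture("uniform_forcing", angle=0.0, nx_elements=4, ny_elements=4)
        state = LatticeState.rest(emap.node_owner.shape)
        g = 1e-6
        fccx = np.full(emap.tiling.n_elements, g)
        fccy = np.zeros_like(fccx)
        scratch = np.empty_like(state.f)

        def advance(n):
            nonlocal scratch
            for _ in range(n):
                step(state.f, scratch, state.ux, state.uy, state.rho,
                     fccx, fccy, emap.node_owner, 0.0, 1.0 / p.lattice.tau)
                state.f, scratch = scratch, state.f

        advance(50)
        u50 = state.ux.mean()
        advance(50)
        u100 = state.ux.mean()
        assert u100 - u50 == pytest.approx(50 * g / p.lattice.rho0, rel=1e-9)
        assert np.abs(state.uy).max() < 1e-15

    def test_global_momentum_bookkeeping(self, random_map):
        """Per-step global momentum change equals the summed applied body force."""
        p = map_to_lattice(0.5, 2.0, Re=0.1)
        state = LatticeState.rest(random_map.node_owner.shape)
        for _ in range(20):
            lbm_step(state, random_map, p)
        m0 = state.momentum()
        lbm_step(state, random_map, p)
        m1 = state.momentum()
        # the force applied during the step is -kappa*u_new + f_c, i.e. the
        # body force evaluated on the post-step state (implicit friction)
        fx, fy = compute_body_force(state, random_map, p)
        applied = np.array([fx.sum(), fy.sum()])
        np.testing.assert_allclose(m1 - m0, applied, rtol=1e-9, atol=1e-15)

    def test_numba_and_numpy_kernels_agree(self, random_map):
        if not HAVE_NUMBA:
            pytest.skip("numba unavailable; single backend only")
        p = map_to_lattice(0.5, 2.0, Re=0.1)
        fccx, fccy = element_forces(random_map, p)
        shape = random_map.node_owner.shape
        states = []
        sums = []
        n = random_map.tiling.n_elements
        for backend in ("numba", "numpy"):
            st = LatticeState.rest(shape)
            scratch = np.empty_like(st.f)
            es = (np.empty(n), np.empty(n))
            for _ in range(10):
                step(st.f, scratch, st.ux, st.uy, st.rho, fccx, fccy,
                     random_map.node_owner, p.lattice.kappa, 1.0 / p.lattice.tau,
                     backend=backend, elem_sums=es)
                st.f, scratch = scratch, st.f
            states.append(st)
            sums.append(es)
        np.testing.assert_allclose(states[0].f, states[1].f, atol=1e-14)
        np.testing.assert_allclose(sums[0][0], sums[1][0], atol=1e-16)
        np.testing.assert_allclose(sums[0][1], sums[1][1], atol=1e-16)


class TestSteadyStates:
    def test_uniform_forcing_reaches_u0_everywhere(self):
        """All-ciliated uniform forcing balances friction at |U| = U0 exactly."""
        p = map_to_lattice(1.0, 4.0, Re=0.1)
        emap, _ = make_fixture("uniform_forcing", angle=0.3)
        state = solve_frozen_orientations(emap, p, tolerance=1e-10)
        speed = np.hypot(state.ux, state.uy)
        assert np.abs(speed / p.lattice.U0 - 1.0).max() < 1e-3
        angle = np.arctan2(state.uy, state.ux)
        assert np.abs(angle - 0.3).max() < 1e-3

    def test_steady_momentum_balance(self):
        """Integral of f_c balances the integral of -kappa*U to < 1e-3."""
        emap, _ = make_fixture("two_element")
        p = map_to_lattice(2.0 / emap.tiling.n_elements, 2.0, Re=0.1)
        state = solve_frozen_orientations(emap, p, tolerance=1e-11)
        fx, fy = compute_body_force(state, emap, p)
        fcx = fx + p.lattice.kappa * state.ux
        fcy = fy + p.lattice.kappa * state.uy
        res = np.hypot(fx.sum(), fy.sum()) / np.hypot(fcx.sum(), fcy.sum())
        assert res < 1e-3

    def test_density_fluctuations_bounded_by_mach_squared(self):
        p = map_to_lattice(1.0, 2.0, Re=0.1)
        emap, _ = make_fixture("uniform_forcing", angle=0.0)
        state = solve_frozen_orientations(emap, p, tolerance=1e-10)
        mach = np.hypot(state.ux, state.uy).max() / p.lattice.cs
        assert np.abs(state.rho - 1.0).max() < 3.0 * mach**2

    def test_grid_convergence_uniform_forcing(self):
        from ciliaflow import DEFAULT_MACH

        speeds = []
        for res in (5, 10):
            # keep tau inside the stability window as the grid refines
            p = map_to_lattice(1.0, 2.0, Re=0.1, resolution=res,
                               target_mach=DEFAULT_MACH * 5 / res)
            emap, _ = make_fixture("uniform_forcing", angle=0.0, resolution=res)
            st = solve_frozen_orientations(emap, p, tolerance=1e-10)
            speeds.append(np.hypot(st.ux, st.uy).mean() / p.lattice.U0)
        assert abs(speeds[1] - speeds[0]) < 0.01


class TestScreening:
    @pytest.fixture(scope="class")
    def decay_distances(self):
        """Distance at which |U| falls to 10% of the on-element value."""
        out = {}
        for lam in (1.0, 2.0, 4.0):
            # 20x20 elements: large enough that even lambda=4 decays below
            # 10% before periodic images overlap
            emap, info = make_fixture("single_element", nx_elements=20, ny_elements=20)
            p = map_to_lattice(1.0 / emap.tiling.n_elements, lam, Re=0.1)
            st = solve_frozen_orientations(emap, p, tolerance=1e-10)
            speed = np.hypot(st.ux, st.uy)
            cx, cy = info["center"]
            nx, ny = speed.shape
            X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
            dx = (X - cx + nx / 2) % nx - nx / 2
            dy = (Y - cy + ny / 2) % ny - ny / 2
            r = np.hypot(dx, dy)
            u_on = speed[emap.node_owner == info["element_index"]].mean()
            # radial shell profile
            shells = np.arange(0, min(nx, ny) // 2, 2)
            prof = np.array(
                [speed[(r >= a) & (r < a + 2)].mean() for a in shells]
            )
            below = np.flatnonzero(prof < 0.1 * u_on)
            out[lam] = shells[below[0]]
        return out

    def test_screening_length_monotone_in_lambda(self, decay_distances):
        d = [decay_distances[lam] for lam in (1.0, 2.0, 4.0)]
        assert d[0] < d[1] < d[2]

    def test_far_field_efolding_matches_lambda_D(self):
        """Vorticity decays as the screened (Brinkman) kernel exp(-r/l)/sqrt(r).

        The rotational part of the flow is screened on l = lambda*D; the
        speed itself keeps an algebraic pressure-dipole tail and is not a
        clean probe.  A log-linear fit of |omega|*sqrt(r) between 2l and 5l
        must recover the e-folding length within 15%.
        """
        from ciliaflow import vorticity_field

        emap, info = make_fixture("single_element", nx_elements=20, ny_elements=20)
        p = map_to_lattice(1.0 / emap.tiling.n_elements, 2.0, Re=0.1)
        st = solve_frozen_orientations(emap, p, tolerance=1e-10)
        om = np.abs(vorticity_field(st.ux, st.uy, p.lattice.D, p.lattice.U0))
        cx, cy = info["center"]
        nx, ny = om.shape
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        r = np.hypot((X - cx + nx / 2) % nx - nx / 2, (Y - cy + ny / 2) % ny - ny / 2)
        shells = np.arange(0, min(nx, ny) // 2, 2)
        prof = np.array([om[(r >= a) & (r < a + 2)].mean() for a in shells])
        ell = 2.0 * p.lattice.D
        sel = (shells >= 2 * ell) & (shells <= 5 * ell) & (prof > 0)
        slope = np.polyfit(shells[sel], np.log(prof[sel] * np.sqrt(shells[sel])), 1)[0]
        assert -1.0 / slope == pytest.approx(ell, rel=0.15)


class TestFrozenTwoElements:
    """Screening controls whether neighboring elements feel each other."""

    @pytest.fixture(scope="class")
    def delta_thetas(self):
        from ciliaflow import summarize_element_flow

        out = {}
        for lam in (1.0, 5.0):
            emap, info = make_fixture("two_element")
            p = map_to_lattice(2.0 / emap.tiling.n_elements, lam, Re=0.1)
            st = solve_frozen_orientations(emap, p, tolerance=1e-11)
            summ = summarize_element_flow(st, emap, eps_speed=0.0)
            out[lam] = np.abs(summ.delta_theta)
        return out

    def test_weak_screening_keeps_flow_along_forces(self, delta_thetas):
        assert np.all(delta_thetas[1.0] < np.deg2rad(5.0))

    def test_long_range_interaction_misaligns_flow(self, delta_thetas):
        assert np.all(delta_thetas[5.0] > delta_thetas[1.0])
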