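import numpy as np
import pytest
from scipy.integrate import solve_ivp

import notchemt as ne
from notchemt.circuit import IDX, N_SPECIES, SPECIES, rhs
from notchemt.lattice import (LatticeConfig, LatticeState, basal_scales,
                              neighbour_environment, self_coupled_steady_states)


def small_cfg(**kw):
    base = dict(rows=4, cols=4, g_J=80.0, g_D=20.0, duration=12.0, seed=5)
    base.update(kw)
    return LatticeConfig(**base)


class TestNeighbourEnvironment:
    def test_homogeneous_lattice_sees_own_levels(self, params_on):
        cfg = small_cfg()
        x = np.linspace(10, 2000, N_SPECIES)
        grid = np.tile(x[:, None, None], (1, 4, 4))
        env = neighbour_environment(LatticeState(0.0, grid), 1, 2, cfg)
        assert env.D_ext == pytest.approx(x[IDX["D"]])
        assert env.J_ext == pytest.approx(x[IDX["J"]])
        assert env.N_ext == pytest.approx(x[IDX["N"]])

    def test_point_source_spreads_to_four_neighbours(self, params_on):
        cfg = small_cfg(rows=5, cols=5)
        grid = np.zeros((N_SPECIES, 5, 5))
        grid[IDX["D"], 2, 2] = 100.0
        state = LatticeState(0.0, grid)
        for r, c in ((1, 2), (3, 2), (2, 1), (2, 3)):
            assert neighbour_environment(state, r, c, cfg).D_ext == 25.0
        assert neighbour_environment(state, 2, 2, cfg).D_ext == 0.0
        assert neighbour_environment(state, 0, 0, cfg).D_ext == 0.0

    def test_sum_aggregation_scales_by_four(self, params_on):
        grid = np.full((N_SPECIES, 3, 3), 7.0)
        state = LatticeState(0.0, grid)
        env = neighbour_environment(state, 1, 1, small_cfg(rows=3, cols=3,
                                                           aggregation="sum"))
        assert env.D_ext == pytest.approx(28.0)

    def test_out_of_range_index(self, params_on):
        grid = np.zeros((N_SPECIES, 4, 4))
        with pytest.raises(IndexError):
            neighbour_environment(LatticeState(0.0, grid), 4, 0, small_cfg())

    def test_uniform_fields_passed_through(self):
        cfg = small_cfg(sJ_ext=111.0, I_ext=222.0)
        grid = np.zeros((N_SPECIES, 4, 4))
        env = neighbour_environment(LatticeState(0.0, grid), 0, 0, cfg)
        assert env.sJ_ext == 111.0 and env.I_ext == 222.0


class TestRandomInitialLattice:
    def test_deterministic_and_replicate_dependent(self, params_on):
        cfg = small_cfg()
        a = ne.random_initial_lattice(cfg, params_on, replicate=0)
        b = ne.random_initial_lattice(cfg, params_on, replicate=0)
        c = ne.random_initial_lattice(cfg, params_on, replicate=1)
        np.testing.assert_array_equal(a.grid, b.grid)
        assert not np.array_equal(a.grid, c.grid)

    def test_sample_mean_matches_half_scale(self, params_on):
        cfg = small_cfg(rows=50, cols=50)
        lat = ne.random_initial_lattice(cfg, params_on, replicate=0)
        scales = basal_scales(params_on, cfg)
        means = lat.grid.reshape(N_SPECIES, -1).mean(axis=1)
        np.testing.assert_allclose(means, scales / 2, rtol=0.05)


class TestIntegrateLattice:
    def test_homogeneous_periodic_lattice_stays_homogeneous(self, params_on):
        cfg = small_cfg(duration=24.0)
        x = np.linspace(50, 5000, N_SPECIES)
        init = LatticeState(0.0, np.tile(x[:, None, None], (1, 4, 4)))
        snaps = ne.integrate_lattice(init, cfg, params_on)
        for s in snaps:
            spread = np.ptp(s.grid.reshape(N_SPECIES, -1), axis=1)
            assert np.all(spread == 0.0)

    def test_zero_production_matches_exponential_decay(self, decay_params):
        p = decay_params.replace(**{f: 0.0 for f in
                                    ("g_N", "g_D", "g_J", "g_P", "g_u34",
                                     "g_mS", "g_S", "g_u200", "g_mZ", "g_Z")})
        cfg = small_cfg(duration=20.0, g_J=None, g_D=None)
        x0 = np.full((N_SPECIES, 4, 4), 300.0)
        snaps = ne.integrate_lattice(LatticeState(0.0, x0), cfg, p,
                                     rtol=1e-8, atol=1e-8)
        gam = np.array([getattr(p, "gamma_" + s) for s in SPECIES])
        expected = 300.0 * np.exp(-gam * 20.0)
        np.testing.assert_allclose(snaps[-1].grid[:, 0, 0], expected,
                                   rtol=1e-6)

    def test_one_by_one_periodic_equals_self_coupled_cell(self, params_on):
        cfg = LatticeConfig(rows=1, cols=1, g_J=45.0, g_D=20.0,
                            duration=36.0, seed=1)
        x0 = np.linspace(100, 20000, N_SPECIES)
        init = LatticeState(0.0, x0[:, None, None].copy())
        snaps = ne.integrate_lattice(init, cfg, params_on,
                                     rtol=1e-8, atol=1e-6)
        p = cfg.apply_overrides(params_on)

        def f(t, y):   # independent oracle: the cell is its own neighbourhood
            yc = np.maximum(y, 0.0)
            env = ne.Environment(N_ext=yc[IDX["N"]], D_ext=yc[IDX["D"]],
                                 J_ext=yc[IDX["J"]])
            return rhs(y, env, p)

        ref = solve_ivp(f, (0, 36.0), x0, t_eval=[36.0], rtol=1e-8, atol=1e-6)
        np.testing.assert_allclose(snaps[-1].grid[:, 0, 0], ref.y[:, -1],
                                   rtol=1e-4, atol=1e-2)

    def test_frozen_environment_cell_matches_single_cell_model(self,
                                                               params_on):
        # at a homogeneous fixed point the lattice is stationary, and a
        # single cell whose environment is frozen to that state's levels is
        # stationary at the same point
        cfg = LatticeConfig(rows=3, cols=3, g_J=45.0, g_D=20.0, duration=24.0,
                            seed=1)
        states = self_coupled_steady_states(cfg, params_on, n_starts=20,
                                            seed=2)
        stable = [s for s in states if s.stable]
        assert stable
        x = stable[0].state
        init = LatticeState(0.0, np.tile(x[:, None, None], (1, 3, 3)))
        snaps = ne.integrate_lattice(init, cfg, params_on)
        np.testing.assert_allclose(snaps[-1].grid[:, 1, 1], x,
                                   rtol=1e-4, atol=1e-2)
        env = ne.Environment(N_ext=x[IDX["N"]], D_ext=x[IDX["D"]],
                             J_ext=x[IDX["J"]])
        sol = ne.simulate_cell(x, env, cfg.apply_overrides(params_on),
                               (0.0, 24.0))
        np.testing.assert_allclose(sol.y[:, -1], x, rtol=1e-4, atol=1e-2)

    def test_translation_invariance_with_periodic_boundaries(self, params_on):
        cfg = small_cfg(rows=5, cols=5, duration=12.0)
        init = ne.random_initial_lattice(cfg, params_on, replicate=0)
        rolled = LatticeState(0.0, np.roll(init.grid, (1, 2), axis=(1, 2)))
        s1 = ne.integrate_lattice(init, cfg, params_on)[-1]
        s2 = ne.integrate_lattice(rolled, cfg, params_on)[-1]
        np.testing.assert_allclose(np.roll(s1.grid, (1, 2), axis=(1, 2)),
                                   s2.grid, rtol=1e-6, atol=1e-3)

    def test_bit_identical_snapshots_for_same_seed(self, params_on):
        cfg = small_cfg(duration=10.0, snapshot_times=(5.0,))
        a = ne.integrate_lattice(ne.random_initial_lattice(cfg, params_on),
                                 cfg, params_on)
        b = ne.integrate_lattice(ne.random_initial_lattice(cfg, params_on),
                                 cfg, params_on)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.grid, s2.grid)

    def test_snapshot_times_include_duration(self, params_on):
        cfg = small_cfg(duration=10.0, snapshot_times=(2.0, 7.0))
        snaps = ne.integrate_lattice(ne.random_initial_lattice(cfg, params_on),
                                     cfg, params_on)
        assert [s.time for s in snaps] == [2.0, 7.0, 10.0]

    def test_nonfinite_initial_state_rejected(self, params_on):
        cfg = small_cfg()
        grid = np.zeros((N_SPECIES, 4, 4))
        grid[0, 0, 0] = np.inf
        with pytest.raises(FloatingPointError):
            ne.integrate_lattice(LatticeState(0.0, grid), cfg, params_on)

    def test_tolerance_refinement_changes_fractions_little(self, params_off,
                                                           thresholds):
        cfg = LatticeConfig(rows=10, cols=10, g_J=80.0, g_D=20.0,
                            duration=48.0, seed=3)
        init = ne.random_initial_lattice(cfg, params_off)
        coarse = ne.integrate_lattice(init, cfg, params_off,
                                      rtol=1e-5, atol=1e-2)[-1]
        fine = ne.integrate_lattice(init, cfg, params_off,
                                    rtol=1e-7, atol=1e-4)[-1]
        fc = ne.classify_lattice(coarse.grid, thresholds).fractions()
        ff = ne.classify_lattice(fine.grid, thresholds).fractions()
        for lab in ("E", "E/M", "M"):
            assert abs(fc[lab] - ff[lab]) <= 0.005 + 1e-12


class TestHybridInitialLattice:
    def test_zero_jitter_is_homogeneous_and_all_hybrid(self, params_off,
                                                       thresholds):
        cfg = LatticeConfig(rows=6, cols=6, g_J=45.0, g_D=20.0, duration=12.0,
                            seed=2)
        init = ne.hybrid_initial_lattice(cfg, params_off, thresholds,
                                         jitter=0.0)
        assert np.all(np.ptp(init.grid.reshape(N_SPECIES, -1), axis=1) == 0.0)
        pmap = ne.classify_lattice(init.grid, thresholds)
        assert np.all(pmap.emt == "E/M")

    def test_missing_hybrid_state_raises(self, decay_params, thresholds):
        cfg = LatticeConfig(rows=4, cols=4, duration=12.0, seed=2)
        with pytest.raises(ValueError, match="bifurcation scan"):
            ne.hybrid_initial_lattice(cfg, decay_params, thresholds)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [dict(rows=0), dict(duration=0.0),
                                    dict(boundary="torus"),
                                    dict(aggregation="max"),
                                    dict(snapshot_times=(999.0,))])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)

    def test_config_hash_stable_and_sensitive(self):
        assert small_cfg().hash() == small_cfg().hash()
        assert small_cfg().hash() != small_cfg(g_J=81.0).hash()
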