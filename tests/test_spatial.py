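import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mdolsim.spatial import (DETOXIFIER, EMBEZZLER, IB_KINETICS, IBParams,
                             ColonyState, diffuse_fields, grow_divide_shove,
                             initialize_colony, mixing_index,
                             partition_and_compose, run_colony, update_cells)


def small_params(**kw):
    defaults = dict(kinetics=IB_KINETICS.replace(s0=100.0, theta=0.0),
                    L=60, max_steps=150, max_cells=500, n_inoculum=20,
                    r0=3.0, seed=0)
    defaults.update(kw)
    return IBParams(**defaults)


class TestInitializeColony:
    def test_even_inoculum_is_exactly_balanced(self):
        state = initialize_colony(small_params(n_inoculum=100, r0=7.0))
        assert int((state.ctype == DETOXIFIER).sum()) == 50
        assert int((state.ctype == EMBEZZLER).sum()) == 50

    def test_cells_inside_inoculum_disc(self):
        p = small_params()
        state = initialize_colony(p)
        dist = np.linalg.norm(state.pos - state.center, axis=1)
        assert dist.max() <= p.r0

    def test_seed_determinism(self):
        s1 = initialize_colony(small_params(seed=5))
        s2 = initialize_colony(small_params(seed=5))
        np.testing.assert_array_equal(s1.pos, s2.pos)

    def test_overdense_inoculum_rejected(self):
        with pytest.raises(ValueError, match="close packing"):
            small_params(n_inoculum=200, r0=2.0)


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        state = initialize_colony(small_params())
        before = state.S.copy()
        diffuse_fields(state)
        np.testing.assert_allclose(state.S, before, atol=1e-12)

    def test_zero_diffusivity_freezes_field(self):
        state = initialize_colony(small_params(Ds=0.0, Di=0.0, Dp=0.0))
        state.I[10, 10] = 5.0
        before = state.I.copy()
        diffuse_fields(state)
        np.testing.assert_array_equal(state.I, before)

    def test_point_mass_conservation_per_step(self):
        state = initialize_colony(small_params())
        state.I[30, 30] = 100.0
        for _ in range(200):
            before = state.I.sum()
            diffuse_fields(state)
            assert abs(state.I.sum() - before) <= 1e-9 * before

    def test_point_spread_matches_heat_kernel(self):
        """Free-space spreading of a point mass follows the 2-D Gaussian
        kernel at matched variance (checked away from boundaries)."""
        p = small_params(L=120, Di=1.0, dt=0.1)
        state = initialize_colony(p)
        state.I[:] = 0.0
        c = 60
        state.I[c, c] = 1.0
        n_steps = 150
        for _ in range(n_steps):
            diffuse_fields(state)
        t = n_steps * p.dt
        yy, xx = np.mgrid[0:p.L, 0:p.L]
        r2 = ((xx - c) ** 2 + (yy - c) ** 2) * p.h ** 2
        kernel = np.exp(-r2 / (4 * p.Di * t)) / (4 * np.pi * p.Di * t)
        mask = r2 <= (4 * np.sqrt(2 * p.Di * t)) ** 2
        np.testing.assert_allclose(state.I[mask], kernel[mask],
                                   atol=0.01 * kernel.max())


class TestUpdateCells:
    def test_detoxifier_only_colony_never_grows(self):
        p = small_params()
        state = initialize_colony(p)
        state.ctype[:] = DETOXIFIER
        mass0 = state.mass.copy()
        for _ in range(50):
            update_cells(state)
        np.testing.assert_array_equal(state.mass, mass0)
        assert state.P.sum() == 0.0

    def test_detoxifier_keeps_internal_substrate_low(self):
        p = small_params(kinetics=IB_KINETICS.replace(s0=200.0, theta=0.05))
        state = initialize_colony(p)
        for _ in range(30):
            update_cells(state)
        s_d = state.s_in[state.ctype == DETOXIFIER].mean()
        s_e = state.s_in[state.ctype == EMBEZZLER].mean()
        assert s_d < s_e

    def test_halving_dt_halves_mass_change_to_first_order(self):
        p = small_params()
        base = initialize_colony(p)
        for _ in range(20):  # move past the empty-pool transient
            update_cells(base)
            grow_divide_shove(base)
        one = base.copy()
        update_cells(one, dt=p.dt)
        two = base.copy()
        update_cells(two, dt=p.dt / 2)
        update_cells(two, dt=p.dt / 2)
        d1 = one.mass.sum() - base.mass.sum()
        d2 = two.mass.sum() - base.mass.sum()
        assert d1 == pytest.approx(d2, rel=0.05)

    def test_pools_never_negative(self):
        state = initialize_colony(small_params())
        for _ in range(50):
            update_cells(state)
        assert state.s_in.min() >= 0 and state.i_in.min() >= 0
        assert state.p_in.min() >= 0
        assert state.S.min() >= 0 and state.I.min() >= 0


class TestGrowDivideShove:
    def test_no_division_below_threshold(self):
        state = initialize_colony(small_params())
        n0 = state.n_cells
        pos0 = state.pos.copy()
        grow_divide_shove(state)
        assert state.n_cells == n0
        # inoculum was sampled without overlap control; cells may shift,
        # but none should teleport
        assert np.abs(state.pos - pos0).max() < 2.0

    def test_single_division_produces_equal_daughters(self):
        p = small_params(n_inoculum=1)
        state = initialize_colony(p)
        state.mass[0] = 2.5
        grow_divide_shove(state)
        assert state.n_cells == 2
        np.testing.assert_allclose(state.mass, [1.25, 1.25])
        gap = np.linalg.norm(state.pos[1] - state.pos[0])
        assert gap >= p.cell_radius

    def test_shoving_reduces_worst_overlap(self):
        p = small_params(n_inoculum=40, r0=3.5)
        state = initialize_colony(p)
        d_min = 2 * p.cell_radius

        def worst():
            tree = cKDTree(state.pos)
            pairs = tree.query_pairs(d_min, output_type="ndarray")
            if pairs.size == 0:
                return 0.0
            d = np.linalg.norm(state.pos[pairs[:, 1]] - state.pos[pairs[:, 0]],
                               axis=1)
            return float((d_min - d).max())

        before = worst()
        assert before > 0  # random inoculum has overlaps
        grow_divide_shove(state)
        assert worst() < before


class TestRegionsAndMixing:
    def _state(self, pos, ctype):
        p = small_params()
        n = len(pos)
        return ColonyState(params=p, S=np.zeros((p.L, p.L)),
                           I=np.zeros((p.L, p.L)), P=np.zeros((p.L, p.L)),
                           pos=np.asarray(pos, float),
                           ctype=np.asarray(ctype),
                           s_in=np.zeros(n), i_in=np.zeros(n),
                           p_in=np.zeros(n), mass=np.ones(n),
                           lineage=np.arange(n),
                           rng=np.random.default_rng(0))

    def test_expanding_fraction_arithmetic(self):
        c = 30.0
        pos = [[c, c]] * 2 + [[c + 10, c], [c, c + 10], [c - 10, c],
                              [c + 10, c + 10]]
        ctype = [0, 1, 0, 0, 0, 1]
        inoc, expa, prof = partition_and_compose(self._state(pos, ctype),
                                                 r0=3.0)
        assert expa.fraction == pytest.approx(0.75)
        assert inoc.fraction == pytest.approx(0.5)

    def test_empty_expanding_region_flagged(self):
        pos = [[30.0, 30.0], [30.5, 30.0]]
        inoc, expa, _ = partition_and_compose(self._state(pos, [0, 1]),
                                              r0=5.0)
        assert expa.flagged_empty
        assert np.isnan(expa.fraction)

    def test_initial_state_is_half_detoxifier(self):
        state = initialize_colony(small_params(n_inoculum=30))
        inoc, _, _ = partition_and_compose(state)
        assert inoc.fraction == pytest.approx(0.5)

    def test_mixing_index_segregated_half_planes(self):
        xs, ys = np.mgrid[0:10, 0:10]
        pos = np.column_stack([xs.ravel() * 1.0, ys.ravel() * 1.0]) + 20.0
        ctype = (pos[:, 0] - 20 >= 5).astype(int)
        val = mixing_index(self._state(pos, ctype), k=6)
        assert val < 0.2

    def test_mixing_index_checkerboard(self):
        xs, ys = np.mgrid[0:10, 0:10]
        pos = np.column_stack([xs.ravel() * 1.0, ys.ravel() * 1.0]) + 20.0
        ctype = ((xs + ys) % 2).ravel()
        val = mixing_index(self._state(pos, ctype), k=4)
        # interior 4-neighborhoods are fully opposite-type; boundary cells
        # see same-type diagonals, diluting the grid mean below 1
        assert val > 0.85

    def test_mixing_index_random_labels_matches_expectation(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(10, 50, size=(200, 2))
        vals = []
        for _ in range(100):
            ctype = rng.permutation(np.repeat([0, 1], 100))
            vals.append(mixing_index(self._state(pos, ctype), k=6))
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        # opposite-type frequency for balanced labels without replacement
        expect = 100 / 199
        assert abs(mean - expect) <= 2 * se + 1e-3

    def test_mixing_index_needs_enough_cells(self):
        with pytest.raises(ValueError):
            mixing_index(self._state([[1.0, 1.0], [2.0, 2.0]], [0, 1]), k=6)


class TestRunColony:
    def test_reproducible_composition_series(self):
        p = small_params(max_steps=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, s1, m1 = run_colony(p)
            _, s2, m2 = run_colony(p)
        assert s1.equals(s2)
        assert m1["stop_reason"] == m2["stop_reason"]

    def test_manifest_records_stop_reason_and_seed(self):
        p = small_params(max_steps=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, manifest = run_colony(p)
        assert manifest["seed"] == p.seed
        assert manifest["stop_reason"] in {"max_steps", "max_cells",
                                           "substrate_depleted",
                                           "boundary_contact"}

    def test_carbon_bookkeeping_identities(self):
        p = small_params(max_steps=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, _, _ = run_colony(p)
        led = state.ledger
        assert led["s_consumed"] == pytest.approx(led["i_produced"],
                                                  rel=1e-12)
        assert led["i_consumed"] == pytest.approx(led["p_produced"],
                                                  rel=1e-12)
        # biomass gained = y * (P consumed), toxicity disabled here
        assert led["biomass_gained"] == pytest.approx(
            p.kinetics.y * led["p_consumed"], rel=1e-3)

    def test_boundary_contact_flagged(self):
        p = small_params(L=24, max_steps=400, max_cells=5000,
                         kinetics=IB_KINETICS.replace(s0=300.0))
        with pytest.warns(UserWarning, match="boundary"):
            state, _, manifest = run_colony(p)
        assert manifest["stop_reason"] == "boundary_contact"
        assert state.boundary_contact
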