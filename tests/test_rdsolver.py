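"""Method-of-lines solver: oracles, conservation, boundaries, meshes."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

import myocolor as mc
from myocolor.rdsolver import InitialProfile, initial_state
from myocolor.scheme import Species

from conftest import day_series


def test_frozen_system_stays_at_init(frozen_scheme, small_grid, cold_20):
    sch = dataclasses.replace(frozen_scheme, D_O2=0.0)
    init = initial_state(small_grid, sch)
    traj = mc.simulate(sch, small_grid, cold_20, init=init,
                       times_s=day_series(2.0, 4))
    for st in traj.states:
        assert st.C == pytest.approx(init.C, abs=1e-12)


def test_pure_diffusion_matches_erfc_solution(frozen_scheme):
    """k = 0, D > 0, zero initial O2: semi-infinite erfc profile at early t."""
    grid = mc.SpatialGrid(0.02, 400)
    cond = mc.StorageConditions(T_C=2.0, pO2_pct=20.0)
    init = initial_state(grid, frozen_scheme)  # O2 zero everywhere
    times = np.array([5e3, 1e4, 2e4])
    traj = mc.simulate(frozen_scheme, grid, cond, init=init, times_s=times,
                       rtol=1e-9, atol=1e-12)
    D = frozen_scheme.D_O2
    Cs = frozen_scheme.o2_solubility * cond.pO2_pct
    x = grid.x
    for st in traj.states:
        analytic = Cs * erfc(x / (2.0 * np.sqrt(D * st.time_s)))
        mask = analytic >= 0.05 * Cs
        got = st.species_profile(frozen_scheme, "O2")[mask]
        assert got == pytest.approx(analytic[mask], rel=0.01)


def test_zero_diffusivity_matches_well_mixed_ode(nodiff_scheme, cold_20):
    """D = 0, uniform init: every node follows the 0-D mass-action ODEs."""
    sch = nodiff_scheme
    grid = mc.SpatialGrid(0.02, 12)
    C0 = np.array([0.30, 0.50, 0.20, 0.27])
    init = mc.SpatialState(0.0, np.tile(C0[:, None], (1, grid.n_nodes)))
    times = day_series(5.0, 8)
    traj = mc.simulate(sch, grid, cold_20, init=init, times_s=times,
                       rtol=1e-9, atol=1e-12)

    k = mc.arrhenius_scale(sch, cold_20.T_K)

    def oracle_rhs(t, y):  # independent naive triple loop
        dy = np.zeros_like(y)
        for i in range(sch.n_species):
            for j in range(sch.n_reactions):
                term = sch.stoich[i, j] * k[j]
                for m in range(sch.n_species):
                    if sch.stoich[m, j] < 0:
                        term *= y[m] ** (-sch.stoich[m, j])
                dy[i] += term
        return dy

    sol = solve_ivp(oracle_rhs, (0, times[-1]), C0, method="Radau",
                    t_eval=times, rtol=1e-11, atol=1e-13)
    for ti in range(len(times)):
        ref = sol.y[:, ti]
        for node in range(grid.n_nodes):
            got = traj.states[ti].C[:, node]
            assert np.allclose(got, ref, rtol=1e-6, atol=1e-9)


# -- initial state ---------------------------------------------------------


def test_default_initial_profile(scheme, small_grid):
    st = initial_state(small_grid, scheme)
    assert st.C[:3, 0] == pytest.approx([0.05, 0.90, 0.05])
    assert st.C[:3, -1] == pytest.approx([0.95, 0.0, 0.05])
    sums = st.C[:3].sum(axis=0)
    assert sums == pytest.approx(np.ones(small_grid.n_nodes), abs=1e-12)


def test_uniform_initial_profile(scheme, small_grid):
    prof = InitialProfile(surface={"Mb": 0.2, "MbO2": 0.5, "MMb": 0.3}, deep=None)
    st = initial_state(small_grid, scheme, prof)
    assert np.all(st.C[:3] == st.C[:3, :1])


def test_initial_profile_rejects_bad_sum(scheme, small_grid):
    with pytest.raises(ValueError, match="sum to 1"):
        initial_state(
            small_grid, scheme,
            InitialProfile(surface={"Mb": 0.5, "MbO2": 0.6, "MMb": 0.0}),
        )


def test_initial_o2_is_boundary_value_at_surface_only(scheme, small_grid, cold_20):
    st = initial_state(small_grid, scheme, conditions=cold_20)
    o2 = st.species_profile(scheme, "O2")
    assert o2[0] == pytest.approx(scheme.o2_solubility * 20.0)
    assert np.all(o2[1:] == 0.0)


# -- invariants ------------------------------------------------------------


def test_myoglobin_conservation_along_trajectory(scheme, cold_20):
    traj = mc.simulate(scheme, mc.SpatialGrid(0.02, 60), cold_20,
                       times_s=day_series(15.0, 4))
    for st in traj.states:
        sums = st.C[scheme.myoglobin_indices].sum(axis=0)
        assert np.max(np.abs(sums - 1.0)) <= 1e-6


def test_o2_bounded_without_o2_production(cold_20):
    # oxygenation consumes O2 and nothing produces it
    sch = mc.ReactionScheme(
        species=(
            Species("Mb", "myoglobin-form"),
            Species("MbO2", "myoglobin-form"),
            Species("O2", "dissolved-gas", diffusive=True),
        ),
        stoich=np.array([[-1], [1], [-1]]),
        k_ref=[2.7e-3],
        T_ref_K=293.15,
        D_O2=1e-9,
        Ea_J_mol=32.5e3,
    )
    grid = mc.SpatialGrid(0.02, 60)
    init = mc.SpatialState(
        0.0, np.vstack([np.full(60, 0.9), np.full(60, 0.1), np.zeros(60)])
    )
    traj = mc.simulate(sch, grid, cold_20, init=init, times_s=day_series(10.0, 4))
    cs = sch.o2_solubility * cold_20.pO2_pct
    for st in traj.states:
        o2 = st.species_profile(sch, "O2")
        assert np.all(o2 >= 0.0)
        assert np.all(o2 <= cs + 1e-9)


def test_browning_is_faster_when_warmer(scheme):
    """Time for the surface ratio to cross any threshold shrinks with T."""
    times = day_series(15.0, 6)
    cross = []
    for T in (2.0, 6.0, 10.0):
        traj = mc.simulate(scheme, mc.SpatialGrid(0.02, 60),
                           mc.StorageConditions(T_C=T, pO2_pct=20.0),
                           times_s=times)
        ck = mc.predict_color(traj, mc.ColorMapParams(S=2.0))
        for level in (0.999999, 0.8):
            idx = np.flatnonzero(ck.values < level)
            cross.append((level, T, times[idx[0]] if len(idx) else np.inf))
    for level in (0.999999, 0.8):
        ts = [t for lv, T, t in cross if lv == level]
        assert ts == sorted(ts, reverse=True)


def test_tolerance_controls_integration(scheme, cold_20):
    """Tightening tolerances changes the surface ratio by < 1e-4 sup-norm."""
    times = day_series(15.0, 4)
    grid = mc.SpatialGrid(0.02, 60)
    series = []
    for rtol, atol in ((1e-6, 1e-9), (1e-8, 1e-11)):
        traj = mc.simulate(scheme, grid, cold_20, times_s=times,
                           rtol=rtol, atol=atol)
        mbo2 = mc.surface_timeseries(traj, "MbO2")
        series.append(mbo2 / (1.0 - mbo2))
    assert np.max(np.abs(series[0] - series[1])) < 1e-4


# -- surface series & meshes ----------------------------------------------


def test_surface_timeseries_reads_surface_node(scheme, small_grid, cold_20, frozen_scheme):
    sch = dataclasses.replace(frozen_scheme, D_O2=0.0)
    traj = mc.simulate(sch, small_grid, cold_20, times_s=day_series(1.0, 4))
    s = mc.surface_timeseries(traj, "MbO2")
    assert s == pytest.approx(np.full(len(traj.states), 0.90))
    with pytest.raises(KeyError, match="unknown species"):
        mc.surface_timeseries(traj, "Xyz")


def test_mesh_convergence_differences_shrink(scheme, cold_20):
    out = mc.mesh_convergence(scheme, cold_20, (100, 200, 400),
                              times_s=day_series(15.0, 2))
    d = out["differences"]
    assert len(d) == 2
    assert d[1] <= d[0] + 1e-9  # non-increasing up to solver noise


def test_mesh_convergence_identical_counts(scheme, cold_20):
    out = mc.mesh_convergence(scheme, cold_20, (60, 60),
                              times_s=day_series(5.0, 2))
    assert out["differences"][0] == 0.0


def test_mesh_convergence_linear_scheme(cold_20):
    sch = mc.ReactionScheme(
        species=(
            Species("Mb", "myoglobin-form"),
            Species("MbO2", "myoglobin-form"),
            Species("MMb", "myoglobin-form"),
            Species("O2", "dissolved-gas", diffusive=True),
        ),
        stoich=np.array([[0], [-1], [1], [0]]),
        k_ref=[2e-6],
        T_ref_K=293.15,
        D_O2=1e-9,
        Ea_J_mol=32.5e3,
    )
    out = mc.mesh_convergence(sch, cold_20, (200, 400),
                              times_s=day_series(10.0, 2))
    assert out["differences"][0] < 1e-3


def test_mesh_convergence_needs_two_meshes(scheme, cold_20):
    with pytest.raises(ValueError):
        mc.mesh_convergence(scheme, cold_20, (100,))


# -- input validation ------------------------------------------------------


def test_simulate_rejects_bad_times(scheme, small_grid, cold_20):
    with pytest.raises(ValueError, match="increasing"):
        mc.simulate(scheme, small_grid, cold_20, times_s=[0.0, 2.0, 1.0])
    with pytest.raises(ValueError, match="30 days"):
        mc.simulate(scheme, small_grid, cold_20, times_s=[0.0, 31 * 86400.0])


def test_simulate_rejects_inconsistent_init(scheme, small_grid, cold_20):
    bad = mc.SpatialState(0.0, np.zeros((2, 5)))
    with pytest.raises(ValueError, match="inconsistent"):
        mc.simulate(scheme, small_grid, cold_20, init=bad, times_s=[0.0, 10.0])


def test_conditions_validation():
    with pytest.raises(ValueError):
        mc.StorageConditions(pO2_pct=120.0)
    with pytest.warns(UserWarning, match="cold-storage"):
        mc.StorageConditions(T_C=40.0)


def test_grid_validation():
    with pytest.raises(ValueError):
        mc.SpatialGrid(0.02, 5)
    with pytest.raises(ValueError):
        mc.SpatialGrid(-1.0, 100)
    g = mc.SpatialGrid(0.02, 101)
    assert g.dx == pytest.approx(0.02 / 100)
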