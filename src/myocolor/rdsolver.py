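"""1-D reaction–diffusion integration of myoglobin chemistry in a meat slab.

Method of lines: the slab depth is discretized on a uniform grid (x = 0 at
the exposed surface), dissolved oxygen gets a second-order central-difference
diffusion term, every species reacts at every node, and the resulting stiff
ODE system is integrated with a banded-Jacobian implicit solver (LSODA).

Boundary conditions (when the scheme has a positive O₂ diffusivity):
Dirichlet at the surface — dissolved O₂ held at solubility × headspace %
— and zero flux at the bottom (tray contact). With D_O₂ = 0 there is no
diffusion operator and no boundary condition is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .scheme import ReactionScheme, arrhenius_scale

__all__ = [
    "SpatialGrid",
    "StorageConditions",
    "InitialProfile",
    "SpatialState",
    "TrajectoryResult",
    "IntegrationError",
    "initial_state",
    "simulate",
    "surface_timeseries",
    "mesh_convergence",
    "trajectory_to_csv",
]

NEG_TOL = 1e-9
MAX_TIME_S = 30 * 86400.0


class IntegrationError(RuntimeError):
    """Stiff integrator failed; carries the last successful time."""

    def __init__(self, message: str, last_time_s: float):
        super().__init__(message)
        self.last_time_s = last_time_s


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D depth grid, x = 0 at the exposed surface."""

    depth_m: float = 0.02
    n_nodes: int = 400

    def __post_init__(self) -> None:
        if self.depth_m <= 0:
            raise ValueError("depth_m must be positive")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be at least 10")

    @property
    def dx(self) -> float:
        return self.depth_m / (self.n_nodes - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.depth_m, self.n_nodes)


@dataclass(frozen=True)
class StorageConditions:
    """Storage-experiment factors for one run."""

    T_C: float = 2.0
    pO2_pct: float = 20.0
    aging_d: float = 14.0
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pO2_pct <= 100.0:
            raise ValueError("pO2_pct must lie in [0, 100]")
        if not -2.0 <= self.T_C <= 25.0:
            warnings.warn(
                f"storage temperature {self.T_C} °C is outside the usual "
                "cold-storage range (−2 to 25 °C)",
                stacklevel=2,
            )

    @property
    def T_K(self) -> float:
        return self.T_C + 273.15


@dataclass(frozen=True)
class InitialProfile:
    """Initial composition: surface values relaxing linearly to deep values.

    The default mimics a just-bloomed surface (oxymyoglobin-rich skin over a
    deep anoxic core): surface fractions blend linearly into the deep
    fractions over ``bloom_depth_m``; ``deep=None`` gives a uniform profile.
    """

    surface: Mapping[str, float] = field(
        default_factory=lambda: {"Mb": 0.05, "MbO2": 0.90, "MMb": 0.05}
    )
    deep: Mapping[str, float] | None = field(
        default_factory=lambda: {"Mb": 0.95, "MbO2": 0.0, "MMb": 0.05}
    )
    bloom_depth_m: float = 0.002


DEFAULT_PROFILE = InitialProfile()


@dataclass(frozen=True)
class SpatialState:
    """Concentration/fraction of every species on the grid at one time."""

    time_s: float
    C: np.ndarray  # (M, n_nodes)

    def species_profile(self, scheme: ReactionScheme, name: str) -> np.ndarray:
        return self.C[scheme.index(name)]


@dataclass(frozen=True)
class TrajectoryResult:
    grid: SpatialGrid
    conditions: StorageConditions
    scheme: ReactionScheme
    times_s: np.ndarray
    states: tuple[SpatialState, ...]

    @property
    def surface_o2(self) -> float:
        """Dirichlet surface O₂ concentration, mol·m⁻³."""
        return self.scheme.o2_solubility * self.conditions.pO2_pct


def _check_fractions(fr: Mapping[str, float], what: str) -> None:
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} myoglobin fractions must sum to 1, got {total}")
    if any(v < 0 for v in fr.values()):
        raise ValueError(f"{what} fractions must be non-negative")


def initial_state(
    grid: SpatialGrid,
    scheme: ReactionScheme,
    profile: InitialProfile = DEFAULT_PROFILE,
    conditions: StorageConditions | None = None,
) -> SpatialState:
    """Post-blooming initial condition on the grid.

    Myoglobin fractions blend linearly from ``profile.surface`` at x = 0 to
    ``profile.deep`` at the bloom depth (constant beyond); dissolved O₂ is
    set to the surface boundary value at x = 0 and 0 elsewhere (boundary
    value requires ``conditions``; otherwise O₂ starts at 0 everywhere).
    """
    mb_names = [scheme.species[i].name for i in scheme.myoglobin_indices]
    surf = {nm: float(profile.surface.get(nm, 0.0)) for nm in mb_names}
    _check_fractions(surf, "surface")
    if profile.deep is None:
        deep = surf
    else:
        deep = {nm: float(profile.deep.get(nm, 0.0)) for nm in mb_names}
        _check_fractions(deep, "deep")

    x = grid.x
    w = np.clip(1.0 - x / profile.bloom_depth_m, 0.0, 1.0)  # 1 at surface
    C = np.zeros((scheme.n_species, grid.n_nodes))
    for nm in mb_names:
        C[scheme.index(nm)] = surf[nm] * w + deep[nm] * (1.0 - w)
    if conditions is not None and scheme.D_O2 > 0:
        for i in scheme.diffusive_indices:
            C[i, 0] = scheme.o2_solubility * conditions.pO2_pct
    return SpatialState(time_s=0.0, C=C)


def _make_rhs(
    scheme: ReactionScheme,
    grid: SpatialGrid,
    k: np.ndarray,
    surface_value: float,
):
    """Right-hand side of the method-of-lines ODE system.

    State layout is node-major (all species at node 0, then node 1, ...) so
    that the Jacobian is banded with half-bandwidth M (in-node reaction
    coupling plus nearest-neighbour diffusion coupling).
    """
    M = scheme.n_species
    n = grid.n_nodes
    dx2 = grid.dx**2
    stoich = scheme.stoich.astype(float)
    orders = scheme.orders
    diff_idx = scheme.diffusive_indices if scheme.D_O2 > 0 else np.array([], int)
    D = scheme.D_O2
    N = scheme.n_reactions
    reactants = [
        [(i, int(orders[i, j])) for i in np.flatnonzero(orders[:, j])]
        for j in range(N)
    ]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        C = y.reshape(n, M).T  # (M, n)
        rates = np.empty((N, n))
        for j in range(N):
            r = np.full(n, k[j])
            for i, o in reactants[j]:
                r *= C[i] if o == 1 else C[i] ** o
            rates[j] = r
        dC = stoich @ rates
        for i in diff_idx:
            u = C[i]
            lap = np.empty(n)
            lap[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
            lap[-1] = 2.0 * (u[-2] - u[-1])  # zero-flux bottom (mirror)
            lap[0] = 0.0
            dC[i] += D * lap / dx2
            dC[i, 0] = 0.0  # Dirichlet surface node held fixed
        return dC.T.ravel()

    return rhs


def simulate(
    scheme: ReactionScheme,
    grid: SpatialGrid,
    conditions: StorageConditions,
    init: SpatialState | None = None,
    times_s: Sequence[float] | np.ndarray = None,
    *,
    profile: InitialProfile = DEFAULT_PROFILE,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TrajectoryResult:
    """Integrate the reaction–diffusion system over storage time.

    Rate constants are rescaled to the storage temperature with the single
    activation energy of the scheme. ``init=None`` builds the default
    post-blooming initial state. Output states are clipped to non-negative
    values; concentrations below −1e−9 abort the run.
    """
    if times_s is None:
        raise ValueError("times_s is required")
    times = np.asarray(times_s, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times_s must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times_s must be strictly increasing")
    if times[0] < 0 or times[-1] > MAX_TIME_S:
        raise ValueError("times_s must lie within [0, 30 days]")
    if init is None:
        init = initial_state(grid, scheme, profile, conditions)
    if init.C.shape != (scheme.n_species, grid.n_nodes):
        raise ValueError(
            f"init shape {init.C.shape} inconsistent with scheme/grid "
            f"({scheme.n_species}, {grid.n_nodes})"
        )

    k = arrhenius_scale(scheme, conditions.T_K)
    surface_value = scheme.o2_solubility * conditions.pO2_pct
    y0 = init.C.copy()
    if scheme.D_O2 > 0:
        for i in scheme.diffusive_indices:
            y0[i, 0] = surface_value
    rhs = _make_rhs(scheme, grid, k, surface_value)

    t0 = times[0]
    t_eval = times
    prepend = t0 > 0
    if prepend:
        t_eval = np.concatenate([[0.0], times])
    M = scheme.n_species
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])) if times[-1] > 0 else (0.0, 1.0),
        y0.T.ravel(),
        method="LSODA",
        t_eval=t_eval if times[-1] > 0 else None,
        rtol=rtol,
        atol=atol,
        lband=M,
        uband=M,
    )
    if times[-1] == 0:  # degenerate single-time request
        states = (SpatialState(0.0, np.clip(y0, 0.0, None)),)
        return TrajectoryResult(grid, conditions, scheme, times, states)
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else 0.0
        raise IntegrationError(
            f"stiff integration failed at t = {last:.3g} s: {sol.message}", last
        )
    states = []
    for idx, t in enumerate(sol.t):
        if prepend and idx == 0:
            continue
        C = sol.y[:, idx].reshape(grid.n_nodes, M).T
        if C.min() < -NEG_TOL:
            raise IntegrationError(
                f"concentration {C.min():.3e} below −1e−9 at t = {t:.3g} s", t
            )
        states.append(SpatialState(time_s=float(t), C=np.clip(C, 0.0, None)))
    return TrajectoryResult(grid, conditions, scheme, times, tuple(states))


def surface_timeseries(traj: TrajectoryResult, species: str) -> np.ndarray:
    """Value of one species at the exposed surface (x = 0) per output time."""
    i = traj.scheme.index(species)
    return np.array([st.C[i, 0] for st in traj.states])


def _surface_ratio_series(traj: TrajectoryResult) -> np.ndarray:
    mbo2 = surface_timeseries(traj, "MbO2")
    denom = 1.0 - mbo2
    return np.where(denom > 1e-12, mbo2 / np.maximum(denom, 1e-12), np.inf)


def mesh_convergence(
    scheme: ReactionScheme,
    conditions: StorageConditions,
    node_counts: Sequence[int],
    *,
    depth_m: float = 0.02,
    times_s: np.ndarray | None = None,
    **sim_kw,
) -> dict:
    """Surface MbO₂/(MMb+Mb) series per mesh and sup-norm refinement gaps.

    Returns ``{"node_counts": ..., "series": {n: ratio array},
    "differences": [sup-norm gap between consecutive refinements]}``.
    """
    if len(node_counts) < 2:
        raise ValueError("need at least two node counts")
    if times_s is None:
        times_s = np.linspace(0.0, 15 * 86400.0, 181)
    series: dict[int, np.ndarray] = {}
    for n in node_counts:
        traj = simulate(
            scheme, SpatialGrid(depth_m, n), conditions, times_s=times_s, **sim_kw
        )
        series[n] = _surface_ratio_series(traj)
    diffs = [
        float(np.max(np.abs(series[b] - series[a])))
        for a, b in zip(node_counts[:-1], node_counts[1:])
    ]
    return {"node_counts": list(node_counts), "series": series, "differences": diffs}


def trajectory_to_csv(traj: TrajectoryResult, path: str | Path) -> None:
    """Export a trajectory as tidy CSV (time_s, x_m, species, value)."""
    rows = []
    x = traj.grid.x
    for st in traj.states:
        for i, nm in enumerate(traj.scheme.species_names):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": st.time_s,
                        "x_m": x,
                        "species": nm,
                        "value": st.C[i],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
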