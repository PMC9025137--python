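"""Synthetic storage-experiment datasets.

Generates a*/a*₀ kinetics with the structure of the real storage
experiments: a 4-factor, 3-level design (storage temperature, headspace O₂,
aging time, cutting angle), redness sampled every 15 minutes over 15 days,
three-phase Gompertz kinetics, and additive Gaussian measurement noise.
Either the phenomenological truth (factor regressions + Gompertz) or the
reaction–diffusion model itself can act as the generator, so every fitting
and calibration stage of the package can be exercised with no external data.

The default truth coefficients are fabricated (clearly labelled synthetic in
all output metadata); see docs/methods.md for how they were chosen and which
qualitative effect directions they encode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .colormap import ColorKinetics, ColorMapParams, kinetics_from_csv, kinetics_to_csv, predict_color
from .phenom import FactorRegression, gompertz_a, GompertzParams, lag_from_factors, mumax_from_factors
from .rdsolver import SpatialGrid, StorageConditions, simulate
from .scheme import ReactionScheme

__all__ = [
    "LEVELS",
    "DesignTable",
    "NoiseModel",
    "make_design",
    "default_truth",
    "DEFAULT_A0",
    "DEFAULT_AF",
    "synth_kinetics",
    "synth_from_rd",
    "write_dataset",
    "read_dataset",
]

LEVELS = {
    "T_C": (2.0, 6.0, 10.0),
    "pO2_pct": (0.0, 20.0, 100.0),
    "aging_d": (0.0, 7.0, 14.0),
    "angle_deg": (0.0, 45.0, 90.0),
}

DEFAULT_A0 = 20.0  # typical bloomed beef a*
DEFAULT_AF = 4.0  # browned plateau a*

# Conference matrix of order 6 (Paley construction over GF(5)); the
# definitive screening design rows are ±(its rows) plus a center run. With
# four factors we use its first four columns, the standard way to run a
# 13-run definitive screening design for m = 4.
_C6 = np.array(
    [
        [0, 1, 1, 1, 1, 1],
        [1, 0, 1, -1, -1, 1],
        [1, 1, 0, 1, -1, -1],
        [1, -1, 1, 0, 1, -1],
        [1, -1, -1, 1, 0, 1],
        [1, 1, -1, -1, 1, 0],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class DesignTable:
    """Ordered list of storage-condition runs drawn from the 3-level sets."""

    runs: tuple[StorageConditions, ...]
    replicates_allowed: bool = False

    def __post_init__(self) -> None:
        for run in self.runs:
            for attr, levels in LEVELS.items():
                v = getattr(run, attr)
                if not any(abs(v - lv) < 1e-9 for lv in levels):
                    raise ValueError(
                        f"{attr} = {v} is not one of the design levels {levels}"
                    )
        if not self.replicates_allowed:
            seen = set()
            for run in self.runs:
                key = (run.T_C, run.pO2_pct, run.aging_d, run.angle_deg)
                if key in seen:
                    raise ValueError(f"duplicate run {key} (replicates not requested)")
                seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "T_C": r.T_C,
                    "pO2_pct": r.pO2_pct,
                    "aging_d": r.aging_d,
                    "angle_deg": r.angle_deg,
                }
                for r in self.runs
            ]
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on a*/a*₀ with a reproducible seed."""

    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def _map_levels(coded: np.ndarray) -> list[StorageConditions]:
    factors = ("T_C", "pO2_pct", "aging_d", "angle_deg")
    runs = []
    for row in coded:
        kw = {f: LEVELS[f][int(c) + 1] for f, c in zip(factors, row)}
        runs.append(StorageConditions(**kw))
    return runs


def make_design(
    kind: str, runs: Sequence[StorageConditions] | None = None
) -> DesignTable:
    """Build a design table.

    ``kind`` is one of ``definitive-screening`` (the 13-run, 4-factor,
    3-level definitive screening design: fold-over pairs of conference-matrix
    rows plus a center run), ``full-factorial`` (all 81 level combinations)
    or ``custom`` (echoes back a validated explicit run list).
    """
    if kind == "definitive-screening":
        rows = []
        for r in _C6[:, :4]:
            rows.append(r)
            rows.append(-r)
        rows.append(np.zeros(4, dtype=int))
        return DesignTable(runs=tuple(_map_levels(np.array(rows))))
    if kind == "full-factorial":
        grids = np.meshgrid(*[(-1, 0, 1)] * 4, indexing="ij")
        coded = np.stack([g.ravel() for g in grids], axis=1)
        return DesignTable(runs=tuple(_map_levels(coded)))
    if kind == "custom":
        if runs is None:
            raise ValueError("custom design requires an explicit run list")
        return DesignTable(runs=tuple(runs))
    raise ValueError(f"unknown design kind {kind!r}")


def default_truth() -> FactorRegression:
    """Fabricated truth coefficients for the synthetic generator.

    Chosen so that, over the design levels: lag is largest in the cold
    high-oxygen corner (~13 d at 2 °C / 100% O₂), decreases with storage
    temperature at both O₂ levels, increases from 20% to 100% O₂ at every
    design temperature (strongly at 2 °C, marginally at 10 °C — the T·pO2
    cross term makes these two effects compete), and stays within [1, 14]
    days for every design run. See docs/methods.md.
    """
    b = np.array([0.30103, -2.76051e-4, -2.0e-6, -3.0e-4, 5.0e-6, 3.62264e-2])
    c = np.array([0.7776, -4.0e-3, 2.0e-5, -1.0e-4, 5.0e-5, -1.0e-5])
    return FactorRegression(b=b, c=c)


def _sampling_times_h(days: float, dt_min: float) -> np.ndarray:
    n = int(round(days * 24 * 60 / dt_min)) + 1
    return np.arange(n) * (dt_min / 60.0)


def synth_kinetics(
    design: DesignTable,
    truth: FactorRegression | None = None,
    a0: float = DEFAULT_A0,
    af: float = DEFAULT_AF,
    *,
    days: float = 15.0,
    dt_min: float = 15.0,
    noise: NoiseModel = NoiseModel(),
) -> list[ColorKinetics]:
    """Gompertz-generated a*/a*₀ kinetics for every run of a design.

    Lag must fall in [1, 14] days for every run (validated); values are
    clipped to [0, 1.05]. Deterministic given the noise seed.
    """
    reg = truth if truth is not None else default_truth()
    times_h = _sampling_times_h(days, dt_min)
    rng = np.random.default_rng(noise.seed)
    out = []
    for cond in design.runs:
        lag = lag_from_factors(reg, cond)
        mumax = mumax_from_factors(reg, cond)
        if not 1.0 <= lag <= 14.0:
            raise ValueError(
                f"truth coefficients give lag = {lag:.3g} d outside [1, 14] "
                f"at {cond}"
            )
        p = GompertzParams(a0=a0, af=af, mumax=mumax, lag=lag)
        values = gompertz_a(times_h / 24.0, p) / a0
        if noise.sigma > 0:
            values = values + rng.normal(0.0, noise.sigma, size=values.shape)
        values = np.clip(values, 0.0, 1.05)
        out.append(
            ColorKinetics(
                times_h=times_h, values=values, condition=cond, source="synthetic"
            )
        )
    return out


def synth_from_rd(
    scheme: ReactionScheme,
    design: DesignTable,
    S: float,
    Ea_kJ_mol: float,
    noise: NoiseModel = NoiseModel(sigma=0.0),
    *,
    n_nodes: int = 400,
    depth_m: float = 0.02,
    days: float = 15.0,
    dt_min: float = 15.0,
    rtol: float = 1e-6,
) -> list[ColorKinetics]:
    """Self-consistency data: the reaction–diffusion model as generator.

    Runs the solver and the threshold color map for every design run at the
    given (S, Ea) and adds Gaussian noise; used by the calibration recovery
    studies.
    """
    times_h = _sampling_times_h(days, dt_min)
    rng = np.random.default_rng(noise.seed)
    grid = SpatialGrid(depth_m, n_nodes)
    sch = scheme.with_ea(Ea_kJ_mol * 1e3)
    out = []
    for cond in design.runs:
        traj = simulate(sch, grid, cond, times_s=times_h * 3600.0, rtol=rtol)
        ck = predict_color(traj, ColorMapParams(S=S))
        values = ck.values
        if noise.sigma > 0:
            values = np.clip(
                values + rng.normal(0.0, noise.sigma, size=values.shape), 0.0, 1.05
            )
        out.append(
            ColorKinetics(
                times_h=times_h, values=values, condition=cond, source="synthetic"
            )
        )
    return out


def write_dataset(
    directory: str | Path, dataset: Sequence[ColorKinetics], seed: int | None = None
) -> pd.DataFrame:
    """One CSV per run plus a manifest CSV of the conditions (and seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ck in enumerate(dataset):
        fname = f"run_{i:02d}.csv"
        kinetics_to_csv(ck, directory / fname)
        rows.append(
            {
                "run": i,
                "file": fname,
                "T_C": ck.condition.T_C,
                "pO2_pct": ck.condition.pO2_pct,
                "aging_d": ck.condition.aging_d,
                "angle_deg": ck.condition.angle_deg,
                "source": ck.source,
                "seed": seed if seed is not None else "",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_dataset(directory: str | Path) -> list[ColorKinetics]:
    """Read back a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [kinetics_from_csv(directory / f) for f in manifest["file"]]
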