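"""Map surface myoglobin composition to normalized CIELAB redness a*/a*₀.

The bright-red appearance of bloomed beef persists while the surface ratio
r = MbO₂/(MMb + Mb) stays above a threshold S; once the ratio drops below S
the redness falls with it. Because the three myoglobin forms sum to 1, the
ratio equals MbO₂/(1 − MbO₂) and depends on the oxymyoglobin fraction only.

The default mapping is the continuous normalized form a*/a*₀ = min(r/S, 1)
(the predicted ratio normalized by its value at the threshold). The
discontinuous literal variant (a*/a*₀ = r below S) and an opt-in smooth
logistic variant are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rdsolver import StorageConditions, TrajectoryResult, surface_timeseries

__all__ = [
    "ColorKinetics",
    "ColorMapParams",
    "myoglobin_ratio",
    "color_from_ratio",
    "predict_color",
    "kinetics_to_csv",
    "kinetics_from_csv",
]

RATIO_SENTINEL = np.inf
_SOURCES = ("observed", "rd-model", "gompertz-model", "synthetic")


@dataclass(frozen=True)
class ColorKinetics:
    """Time series of normalized redness a*/a*₀ under one storage condition."""

    times_h: np.ndarray
    values: np.ndarray
    condition: StorageConditions
    source: str = "observed"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times_h and values must be 1-D arrays of equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")
        hi = 1.05 if self.source in ("observed", "synthetic") else 1.0 + 1e-9
        if np.any(v < -1e-9) or np.any(v > hi + 1e-9):
            raise ValueError(
                f"a*/a*₀ values out of range [0, {hi}] for source {self.source!r}"
            )

    @property
    def times_d(self) -> np.ndarray:
        return self.times_h / 24.0


@dataclass(frozen=True)
class ColorMapParams:
    """Threshold S on the MbO₂/(MMb+Mb) ratio, plus variant switches."""

    S: float = 2.0
    literal: bool = False  # discontinuous published form (a*/a*₀ = r below S)
    logistic_width: float | None = None  # opt-in smooth threshold, ratio units

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("S must be positive")
        if self.logistic_width is not None and self.logistic_width <= 0:
            raise ValueError("logistic_width must be positive")


def myoglobin_ratio(mbO2, mmb, mb):
    """MbO₂/(MMb + Mb) = MbO₂/(1 − MbO₂) for fractions summing to 1.

    Accepts scalars or arrays; returns +inf where MbO₂ = 1.
    """
    mbO2 = np.asarray(mbO2, dtype=float)
    mmb = np.asarray(mmb, dtype=float)
    mb = np.asarray(mb, dtype=float)
    if np.any(mbO2 < -1e-12) or np.any(mmb < -1e-12) or np.any(mb < -1e-12):
        raise ValueError("myoglobin fractions must be non-negative")
    total = mbO2 + mmb + mb
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("myoglobin fractions must sum to 1 (tol 1e-6)")
    denom = mmb + mb
    with np.errstate(divide="ignore"):
        r = np.where(denom > 0, mbO2 / np.where(denom > 0, denom, 1.0), RATIO_SENTINEL)
    return float(r) if r.ndim == 0 else r


def color_from_ratio(r, params: ColorMapParams = ColorMapParams()):
    """Normalized redness a*/a*₀ from the surface ratio r.

    Default: min(r/S, 1) — continuous at the threshold, bounded in [0, 1].
    ``params.literal`` selects the discontinuous variant (1 for r ≥ S, r
    below). ``params.logistic_width`` selects a smooth logistic threshold.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("ratio must be non-negative")
    S = params.S
    if params.logistic_width is not None:
        w = params.logistic_width
        lo = 1.0 / (1.0 + np.exp(S / w))
        out = (1.0 / (1.0 + np.exp(-(r - S) / w)) - lo) / (1.0 - lo)
        out = np.clip(out, 0.0, 1.0)
    elif params.literal:
        out = np.where(r >= S, 1.0, np.minimum(r, 1.0))
    else:
        out = np.minimum(r / S, 1.0)
    return float(out) if out.ndim == 0 else out


def predict_color(
    traj: TrajectoryResult, params: ColorMapParams = ColorMapParams()
) -> ColorKinetics:
    """Predicted a*/a*₀ series at the meat surface from a trajectory."""
    for nm in ("Mb", "MbO2", "MMb"):
        if nm not in traj.scheme.species_names:
            raise KeyError(f"scheme lacks required myoglobin form {nm!r}")
    mbo2 = surface_timeseries(traj, "MbO2")
    mmb = surface_timeseries(traj, "MMb")
    mb = surface_timeseries(traj, "Mb")
    r = myoglobin_ratio(mbo2, mmb, mb)
    values = color_from_ratio(r, params)
    return ColorKinetics(
        times_h=np.asarray(traj.times_s) / 3600.0,
        values=np.clip(values, 0.0, 1.0),
        condition=traj.conditions,
        source="rd-model",
    )


# -- CSV round trip --------------------------------------------------------


def kinetics_to_csv(ck: ColorKinetics, path: str | Path) -> None:
    """Write a kinetics series with '#'-prefixed condition metadata lines."""
    c = ck.condition
    with open(path, "w") as fh:
        fh.write(f"# source: {ck.source}\n")
        fh.write(f"# T_C: {c.T_C}\n")
        fh.write(f"# pO2_pct: {c.pO2_pct}\n")
        fh.write(f"# aging_d: {c.aging_d}\n")
        fh.write(f"# angle_deg: {c.angle_deg}\n")
        fh.write("time_h,a_ratio\n")
        for t, v in zip(ck.times_h, ck.values):
            fh.write(f"{t:.10g},{v:.10g}\n")


def kinetics_from_csv(path: str | Path) -> ColorKinetics:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    cond = StorageConditions(
        T_C=float(meta.get("T_C", 2.0)),
        pO2_pct=float(meta.get("pO2_pct", 20.0)),
        aging_d=float(meta.get("aging_d", 14.0)),
        angle_deg=float(meta.get("angle_deg", 0.0)),
    )
    return ColorKinetics(
        times_h=df["time_h"].to_numpy(),
        values=df["a_ratio"].to_numpy(),
        condition=cond,
        source=meta.get("source", "observed"),
    )
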