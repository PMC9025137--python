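import dataclasses

import numpy as np
import pytest

import myocolor as mc


@pytest.fixture(scope="session")
def scheme():
    """The bundled 4-reaction stand-in scheme."""
    return mc.default_scheme()


@pytest.fixture(scope="session")
def frozen_scheme(scheme):
    """Same species, every rate constant zero."""
    return dataclasses.replace(scheme, k_ref=np.zeros_like(scheme.k_ref))


@pytest.fixture(scope="session")
def nodiff_scheme(scheme):
    """Default chemistry with oxygen diffusion switched off."""
    return dataclasses.replace(scheme, D_O2=0.0)


@pytest.fixture
def small_grid():
    return mc.SpatialGrid(depth_m=0.02, n_nodes=40)


@pytest.fixture
def cold_20(recwarn):
    return mc.StorageConditions(T_C=2.0, pO2_pct=20.0)


def day_series(days=15.0, per_day=24):
    return np.linspace(0.0, days * 86400.0, int(days * per_day) + 1)


def crossing_day(ck, level):
    """First time (days) a kinetics series falls below `level` (inf if never)."""
    v, t = ck.values, ck.times_h / 24.0
    idx = np.flatnonzero(v < level)
    if len(idx) == 0:
        return np.inf
    i = idx[0]
    if i == 0:
        return 0.0
    return float(np.interp(level, [v[i], v[i - 1]], [t[i], t[i - 1]]))
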