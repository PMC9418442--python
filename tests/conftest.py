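import datetime as dt

import numpy as np
import pandas as pd
import pytest

from beelife import SimConfig, analyze_days, analyze_lives, run_colony
from beelife.core_model import SUBSTRATES, CombMap, CombMapSeries, NestGeometry

_CODE = {name: i for i, name in enumerate(SUBSTRATES)}

D0 = dt.date(2021, 6, 1)


def make_detections(sec, x, y, date=None, side=0, confidence=1.0, bee_id="b1"):
    """Build a detection table from seconds-of-day and positions."""
    sec = np.asarray(sec, dtype=float)
    n = len(sec)
    date = date or (D0 + dt.timedelta(days=1))
    return pd.DataFrame({
        "bee_id": [bee_id] * n,
        "timestamp": pd.Timestamp(date) + pd.to_timedelta(sec, unit="s"),
        "x_cm": np.broadcast_to(np.asarray(x, float), n).copy(),
        "y_cm": np.broadcast_to(np.asarray(y, float), n).copy(),
        "side": np.broadcast_to(np.asarray(side), n).astype(np.int8),
        "confidence": np.broadcast_to(np.asarray(confidence, float), n).copy(),
    })


def toy_map(date, geometry, honey_rows=2):
    """10x10-cell test map: honey band on top, brood mid, dance floor at exit."""
    ny, nx = geometry.n_cells_y, geometry.n_cells_x
    codes = np.full((ny, nx), _CODE["empty"], dtype=np.int8)
    codes[:honey_rows, :] = _CODE["honey"]
    codes[5, :] = _CODE["brood_young"]
    codes[6, :] = _CODE["brood_capped"]
    cx = (np.arange(nx) + 0.5) * geometry.grid_cell
    cy = (np.arange(ny) + 0.5) * geometry.grid_cell
    xx, yy = np.meshgrid(cx, cy)
    ex, ey = geometry.exit_point
    codes[np.hypot(xx - ex, yy - ey) <= 6.0] = _CODE["dancefloor"]
    return CombMap(date, codes, geometry)


@pytest.fixture
def toy_geometry():
    return NestGeometry(20.0, 20.0, 2.0)


@pytest.fixture
def toy_maps(toy_geometry):
    return CombMapSeries([
        toy_map(D0, toy_geometry, honey_rows=2),
        toy_map(D0 + dt.timedelta(days=4), toy_geometry, honey_rows=4),
    ])


# ---------------------------------------------------------------------------
# Shared simulation runs (session-scoped: these carry most of the suite cost)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_run():
    """~70-bee colony over 30 days at a 20-s time step."""
    cfg = SimConfig(seed=1, n_days=30, cohort_interval_days=5, bees_per_cohort=12,
                    frame_rate=0.05, detection_prob=0.85)
    return run_colony(cfg, seed=1)


@pytest.fixture(scope="session")
def small_day(small_run):
    return analyze_days(small_run.behavioral_days, small_run.registry,
                        small_run.maps, embed=False, seed=1)


@pytest.fixture(scope="session")
def big_run():
    """~450-bee colony over the full 50-day period at a 20-s time step.

    Scale chosen so the lifetime analysis retains well over 300 bees after
    the 10-day minimum, matching the planted-factor recovery conditions.
    """
    cfg = SimConfig(seed=1, n_days=50, cohort_interval_days=5, bees_per_cohort=45,
                    frame_rate=0.05, detection_prob=0.85)
    return run_colony(cfg, seed=1)


@pytest.fixture(scope="session")
def big_day(big_run):
    return analyze_days(big_run.behavioral_days, big_run.registry,
                        big_run.maps, embed=False, seed=1)


@pytest.fixture(scope="session")
def big_life(big_run, big_day):
    return analyze_lives(big_day, big_run.registry)
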