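"""Synthetic observation-hive colony generator.

Produces detection tables, comb-map series and bee registries with known
per-bee ground truth, emulating the data properties of a barcode-tracked
honey bee colony: ~3 Hz detections with dropout and a confidence score,
age-matched cohorts introduced every few days, age polyethism (brood care
-> nest interior -> dance floor / foraging trips), individual variation in
movement activity and in transition age, lifespans negatively coupled to
transition age, and comb maps re-measured every few days.

The movement model is an Ornstein-Uhlenbeck (mean-reverting) walk toward a
substrate-dependent anchor.  Only occupancy, speed and dispersion statistics
matter downstream, so path realism beyond that is not attempted.  Step scale
is proportional to a per-bee activity factor and modulated by a circadian
factor ``1 + kappa * cos(2*pi*(h - 13.5)/24)`` so the circadian coefficient
has a planted positive sign.
"""

from __future__ import annotations

import datetime as _dt
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core_model import (
    SUBSTRATES,
    CombMap,
    CombMapSeries,
    DomainError,
    NestGeometry,
)

_CODE = {name: i for i, name in enumerate(SUBSTRATES)}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    Defaults mirror the study conditions: a 50-day observation period with a
    cohort introduced and the comb re-measured every ~5 days, 3 Hz imaging of
    a 49 x 74.2 cm observation-hive plane with the exit at the lower-right
    corner.  ``frame_rate`` is a free parameter; every downstream metric
    takes it as input, so reduced-rate runs remain consistent.
    """

    seed: int = 0
    n_days: int = 50
    cohort_interval_days: int = 5
    bees_per_cohort: int = 300
    frame_rate: float = 3.0  # detections / second
    detection_prob: float = 0.85  # per-frame probability a present bee is detected
    nest_width_cm: float = 49.0
    nest_height_cm: float = 74.2
    map_interval_days: int = 5
    grid_cell_cm: float = 2.0
    start_date: _dt.date = _dt.date(2021, 6, 1)
    conf_below_frac: float = 0.1  # fraction of detections below the 0.8 threshold
    # Archetype distributions
    activity_sigma: float = 0.35  # lognormal sigma of the activity factor
    mean_transition_age: float = 12.0
    sd_transition_age: float = 4.0
    lifespan_base: float = 4.0
    lifespan_slope: float = 1.8  # days of life per day of transition age
    lifespan_sd: float = 4.0
    trip_rate: float = 3.0  # foraging trips / day once transitioned
    # Movement model
    ou_tau_s: float = 600.0  # mean-reversion timescale
    sigma_base_cm: float = 7.0  # stationary positional SD at activity = 1

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if not (0 < self.detection_prob <= 1):
            raise ConfigurationError("detection_prob must be in (0, 1]")
        if self.nest_width_cm <= 0 or self.nest_height_cm <= 0:
            raise ConfigurationError("nest dimensions must be positive")
        if self.n_days < 1 or self.cohort_interval_days < 1 or self.map_interval_days < 1:
            raise ConfigurationError("day counts must be >= 1")

    @property
    def geometry(self) -> NestGeometry:
        return NestGeometry(self.nest_width_cm, self.nest_height_cm, self.grid_cell_cm)

    def date_of_day(self, day: int) -> _dt.date:
        return self.start_date + _dt.timedelta(days=int(day))


@dataclass(frozen=True)
class BeeArchetype:
    """Planted ground-truth parameters of one simulated bee.

    ``activity`` scales step speed and roaming range (the planted analogue of
    an overall movement-activity axis); ``transition_age`` is the age at which
    substrate preference shifts to the dance floor and foraging trips begin
    (the planted analogue of an early-vs-late transition axis).  In the
    default generator lifespan increases with transition age, so
    early-transitioning bees live shorter lives.
    """

    bee_id: str
    cohort_id: str
    birth_day: int
    lifespan_days: int
    activity: float
    transition_age: float
    forager_trip_rate: float
    kappa: float  # circadian modulation amplitude

    def __post_init__(self):
        if self.lifespan_days < 1 or self.activity <= 0 or self.transition_age < 1:
            raise ConfigurationError("invalid archetype parameters")


@dataclass
class GroundTruth:
    """Per-bee planted parameters plus per-day occupancy and trip logs."""

    archetypes: pd.DataFrame
    occupancy: pd.DataFrame  # bee_id, date, f_honey, f_brood, f_dancefloor, time_inside_s, time_outside_s
    trips: pd.DataFrame  # bee_id, date, exit_s, entry_s (seconds of day)


def _cohort_label(i: int) -> str:
    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


# ---------------------------------------------------------------------------
# Nest layout
# ---------------------------------------------------------------------------

def generate_nest_layout(config: SimConfig, seed: int | None = None) -> CombMapSeries:
    """Generate the comb-map series for the observation period.

    One map per ``map_interval_days`` from day 0 through ``n_days``
    (inclusive).  The dance floor is a fixed disc of cells adjacent to the
    exit corner, identical in every map; honey is stored in the top band far
    from the exit; brood occupies a central ellipse whose extent varies
    between measurement days; the outer cell ring is wood with a small
    gallery notch.
    """
    geometry = config.geometry
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nx, ny = geometry.n_cells_x, geometry.n_cells_y
    cx = (np.arange(nx) + 0.5) * geometry.grid_cell
    cy = (np.arange(ny) + 0.5) * geometry.grid_cell
    xx, yy = np.meshgrid(cx, cy)

    # Fixed dance-floor disc at the exit corner (lower right).
    ex, ey = geometry.exit_point
    df_mask = np.hypot(xx - ex, yy - ey) <= 0.33 * geometry.width

    maps = []
    for day in range(0, config.n_days + 1, config.map_interval_days):
        codes = np.full((ny, nx), _CODE["empty"], dtype=np.int8)
        # honey band at the top, depth varying between measurements
        depth = geometry.height * (0.20 + 0.08 * rng.random())
        codes[yy < depth] = _CODE["honey"]
        # thin pollen band under the honey
        codes[(yy >= depth) & (yy < depth + geometry.grid_cell)] = _CODE["pollen"]
        # central brood ellipse, extent varying between measurements
        bx, by = geometry.width * 0.5, geometry.height * 0.55
        rx = geometry.width * 0.30 * (0.85 + 0.3 * rng.random())
        ry = geometry.height * 0.20 * (0.85 + 0.3 * rng.random())
        r2 = ((xx - bx) / rx) ** 2 + ((yy - by) / ry) ** 2
        codes[r2 <= 1.0] = _CODE["brood_capped"]
        codes[r2 <= 0.45] = _CODE["brood_young"]
        # wooden frame border and a gallery notch at the top-left
        border = np.zeros((ny, nx), dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        codes[border] = _CODE["wood"]
        codes[:2, :2] = _CODE["gallery"]
        # dance floor last: fixed over the whole period
        codes[df_mask] = _CODE["dancefloor"]
        maps.append(CombMap(config.date_of_day(day), codes, geometry))
    return CombMapSeries(maps)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def generate_population(config: SimConfig, seed: int | None = None) -> list[BeeArchetype]:
    """Draw per-bee archetypes for cohorts introduced every few days.

    Cohorts are labelled alphabetically in order of birth date.  Activity is
    lognormal (median 1), transition age is normal (clipped to [3, 24] days),
    and lifespan increases with transition age plus noise, planting the
    early-transition => short-life coupling.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    birth_days = list(range(0, config.n_days, config.cohort_interval_days))
    if not birth_days or config.bees_per_cohort < 1:
        raise ConfigurationError("cohort schedule is empty")
    bees = []
    idx = 0
    for c, birth in enumerate(birth_days):
        for _ in range(config.bees_per_cohort):
            activity = float(rng.lognormal(0.0, config.activity_sigma))
            ta = float(np.clip(
                rng.normal(config.mean_transition_age, config.sd_transition_age), 3.0, 24.0))
            lifespan = int(np.clip(round(
                config.lifespan_base + config.lifespan_slope * ta
                + rng.normal(0.0, config.lifespan_sd)), 6, 60))
            bees.append(BeeArchetype(
                bee_id=f"b{idx:05d}",
                cohort_id=_cohort_label(c),
                birth_day=birth,
                lifespan_days=lifespan,
                activity=activity,
                transition_age=ta,
                forager_trip_rate=float(config.trip_rate * rng.lognormal(0.0, 0.25)),
                kappa=float(rng.uniform(0.15, 0.5)),
            ))
            idx += 1
    return bees


def archetypes_frame(archetypes: Sequence[BeeArchetype], config: SimConfig) -> pd.DataFrame:
    rows = [{
        "bee_id": a.bee_id,
        "cohort": a.cohort_id,
        "birth_day": a.birth_day,
        "birth_date": config.date_of_day(a.birth_day),
        "death_date": config.date_of_day(a.birth_day + a.lifespan_days),
        "lifespan_days": a.lifespan_days,
        "activity": a.activity,
        "transition_age": a.transition_age,
        "forager_trip_rate": a.forager_trip_rate,
        "kappa": a.kappa,
    } for a in archetypes]
    return pd.DataFrame(rows)


def registry_from_archetypes(archetypes: Sequence[BeeArchetype], config: SimConfig) -> pd.DataFrame:
    """Bee registry (bee_id, cohort, birth_date, death_date)."""
    df = archetypes_frame(archetypes, config)
    return df[["bee_id", "cohort", "birth_date", "death_date"]].copy()


# ---------------------------------------------------------------------------
# Detection simulation
# ---------------------------------------------------------------------------

def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def _anchor_for(age: np.ndarray, transition_age: np.ndarray, geometry: NestGeometry):
    """Substrate-dependent attractor by life phase (brood -> interior -> dance floor)."""
    w, h = geometry.width, geometry.height
    ax = np.where(age >= transition_age, 0.82 * w,
                  np.where(age >= 0.5 * transition_age, 0.30 * w, 0.50 * w))
    ay = np.where(age >= transition_age, 0.88 * h,
                  np.where(age >= 0.5 * transition_age, 0.32 * h, 0.55 * h))
    return ax, ay


def simulate_day(day: int, archetypes: Sequence[BeeArchetype], maps: CombMapSeries,
                 config: SimConfig, seed: int):
    """Simulate one calendar day for all bees alive on that day.

    Returns ``(detections, occupancy, trips)``: the detection table for the
    day and the day's ground-truth occupancy fractions and trip log.  Uses an
    rng keyed on ``(seed, day)`` so streaming day-by-day and simulating the
    whole period at once produce identical output.
    """
    geometry = config.geometry
    rng = np.random.default_rng([int(seed), int(day)])
    alive = [a for a in archetypes
             if a.birth_day <= day < min(a.birth_day + a.lifespan_days, config.n_days)]
    empty_det = pd.DataFrame(columns=["bee_id", "timestamp", "x_cm", "y_cm", "side", "confidence"])
    empty_occ = pd.DataFrame(columns=["bee_id", "date", "f_honey", "f_brood", "f_dancefloor",
                                      "time_inside_s", "time_outside_s"])
    empty_trips = pd.DataFrame(columns=["bee_id", "date", "exit_s", "entry_s"])
    if not alive:
        return empty_det, empty_occ, empty_trips

    n = len(alive)
    n_frames = int(round(86400 * config.frame_rate))
    dt = 86400.0 / n_frames
    ages = np.array([day - a.birth_day for a in alive], dtype=float)
    activity = np.array([a.activity for a in alive])
    ta = np.array([a.transition_age for a in alive])
    kappa = np.array([a.kappa for a in alive])

    # circadian step-scale modulation, peaking at 13:30 local time
    hour = (np.arange(n_frames) + 0.5) * dt / 3600.0
    circ = 1.0 + kappa[:, None] * np.cos(2.0 * np.pi * (hour[None, :] - 13.5) / 24.0)
    np.clip(circ, 0.05, None, out=circ)

    # OU walk toward the phase anchor
    a_coef = math.exp(-dt / config.ou_tau_s)
    sd_stat = config.sigma_base_cm * activity
    innov_sd = sd_stat[:, None] * math.sqrt(1.0 - a_coef * a_coef) * circ
    ax, ay = _anchor_for(ages, ta, geometry)
    zi_x = (a_coef * rng.normal(0.0, sd_stat))[:, None]
    zi_y = (a_coef * rng.normal(0.0, sd_stat))[:, None]
    dev_x, _ = lfilter([1.0], [1.0, -a_coef], rng.standard_normal((n, n_frames)) * innov_sd,
                       axis=1, zi=zi_x)
    dev_y, _ = lfilter([1.0], [1.0, -a_coef], rng.standard_normal((n, n_frames)) * innov_sd,
                       axis=1, zi=zi_y)
    del innov_sd, circ
    pad = min(0.3, 0.1 * geometry.grid_cell)
    x = _reflect(ax[:, None] + dev_x, pad, geometry.width - pad)
    y = _reflect(ay[:, None] + dev_y, pad, geometry.height - pad)
    del dev_x, dev_y

    # foraging trips for transitioned bees: approach the exit, then vanish
    outside = np.zeros((n, n_frames), dtype=bool)
    trips_rows = []
    ex, ey = geometry.exit_point
    date = config.date_of_day(day)
    for i, bee in enumerate(alive):
        if ages[i] < ta[i]:
            continue
        n_tr = rng.poisson(bee.forager_trip_rate)
        if n_tr == 0:
            continue
        starts = np.sort(rng.uniform(8 * 3600, 18 * 3600, n_tr))
        durs = np.clip(rng.lognormal(math.log(35 * 60), 0.5, n_tr), 600, 7200)
        t_free = 0.0
        for s, d in zip(starts, durs):
            if s - 150.0 < t_free:
                continue  # overlaps the previous trip or its approach
            f_app = int((s - 120.0) / dt)
            f0 = int(s / dt)
            f1 = min(int((s + d) / dt), n_frames)
            if f0 >= n_frames or f1 <= f0:
                continue
            # pin the bee next to the exit during the approach window
            n_app = f0 - f_app
            x[i, f_app:f0] = ex - rng.uniform(0.5, 4.5, n_app)
            y[i, f_app:f0] = ey - rng.uniform(0.5, 4.5, n_app)
            outside[i, f0:f1] = True
            trips_rows.append({"bee_id": bee.bee_id, "date": date,
                               "exit_s": f0 * dt, "entry_s": f1 * dt})
            t_free = f1 * dt

    # ground-truth occupancy from the full (pre-dropout) trajectory
    map_a, map_b, w_a, w_b = maps.bracket(date)
    ix, iy = geometry.cell_index(x, y)
    inside = ~outside
    n_inside = inside.sum(axis=1)
    occ = {"bee_id": [a.bee_id for a in alive], "date": [date] * n}
    for sub in ("honey", "brood", "dancefloor"):
        fa = (map_a.merged_mask(sub)[iy, ix] & inside).sum(axis=1)
        fb = (map_b.merged_mask(sub)[iy, ix] & inside).sum(axis=1)
        with np.errstate(invalid="ignore"):
            occ[f"f_{sub}"] = np.where(n_inside > 0,
                                       (w_a * fa + w_b * fb) / np.maximum(n_inside, 1), 0.0)
    occ["time_inside_s"] = n_inside * dt
    occ["time_outside_s"] = outside.sum(axis=1) * dt
    occupancy = pd.DataFrame(occ)

    # emit detections: per-frame Bernoulli dropout, confidence distribution
    detected = (rng.random((n, n_frames)) < config.detection_prob) & inside
    side0 = rng.integers(0, 2, n)
    switch = rng.random((n, n_frames)) < 1e-4
    side = (side0[:, None] + np.cumsum(switch, axis=1)) % 2
    bee_idx, frame_idx = np.nonzero(detected)
    m = len(bee_idx)
    low = rng.random(m) < config.conf_below_frac
    conf = np.where(low, rng.uniform(0.2, 0.8, m), rng.uniform(0.801, 1.0, m))
    ms = np.round(frame_idx * dt * 1000.0).astype(np.int64)
    day_start = pd.Timestamp(date)
    ids = np.array([a.bee_id for a in alive])
    detections = pd.DataFrame({
        "bee_id": ids[bee_idx],
        "timestamp": day_start + pd.to_timedelta(ms, unit="ms"),
        "x_cm": x[bee_idx, frame_idx],
        "y_cm": y[bee_idx, frame_idx],
        "side": side[bee_idx, frame_idx].astype(np.int8),
        "confidence": conf,
    })
    trips = pd.DataFrame(trips_rows) if trips_rows else empty_trips
    return detections, occupancy, trips


def iter_detection_days(archetypes: Sequence[BeeArchetype], maps: CombMapSeries,
                        config: SimConfig, seed: int | None = None) -> Iterator[tuple]:
    """Yield ``(date, detections, occupancy, trips)`` one calendar day at a time.

    Streaming interface for analysis-scale runs where the full detection
    table would not fit comfortably in memory.
    """
    s = config.seed if seed is None else seed
    for day in range(config.n_days):
        det, occ, trips = simulate_day(day, archetypes, maps, config, s)
        yield config.date_of_day(day), det, occ, trips


def simulate_detections(archetypes: Sequence[BeeArchetype], maps: CombMapSeries,
                        config: SimConfig, seed: int | None = None
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full observation period and return detections + ground truth."""
    dets, occs, trips = [], [], []
    for _, det, occ, trip in iter_detection_days(archetypes, maps, config, seed):
        dets.append(det)
        occs.append(occ)
        trips.append(trip)

    def _concat(frames):
        nonempty = [f for f in frames if len(f)]
        return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]

    gt = GroundTruth(
        archetypes=archetypes_frame(archetypes, config),
        occupancy=_concat(occs),
        trips=_concat(trips),
    )
    return _concat(dets), gt


def write_ground_truth(gt: GroundTruth, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt.archetypes.to_csv(directory / "archetypes.csv", index=False)
    gt.occupancy.to_csv(directory / "occupancy.csv", index=False)
    gt.trips.to_csv(directory / "trips.csv", index=False)
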