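"""Per-day behavioral metrics from detection tables.

Twelve metrics summarise one bee's day, grouped as

* space use: fraction of observed time on honey, brood and dance-floor
  areas, and median distance to the nest exit;
* detection: total time observed, estimated time outside the nest, number
  of outside trips, and number of dance-floor visits;
* movement: median speed, speed circadian coefficient, dispersion (RMS
  distance from the day's centroid), and fraction of the nest visited
  (2 cm x 2 cm occupancy grid).

Processing follows a two-stage scheme: detections above a confidence
threshold (default 0.8) are first binned into 1-hour records, keeping only
hours with at least 10 qualifying detections; per-day values are then sums
(time observed, trips, dance-floor visits), observation-time-weighted
averages (substrate fractions, exit distance, speed), whole-day pooled
statistics (dispersion, nest fraction), or a single whole-day computation
(circadian coefficient from hourly median speeds; trips from 1-min bins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import CombMapSeries, NestGeometry, exit_distance

CONFIDENCE_THRESHOLD = 0.8
MIN_HOUR_DETECTIONS = 10
T_OBS_S = 2.0  # minimum observed time per 1-min bin to count as present
D_EXIT_CM = 18.75  # exit-distance gate for a plausible departure (1500 px)
SOLAR_NOON_H = 13.5  # local solar noon used by the circadian rhythm

#: Canonical metric column order for the behavioral-day table.
METRICS = [
    "f_honey",
    "f_brood",
    "f_dancefloor",
    "exit_distance_median",
    "time_observed",
    "time_outside",
    "n_outside_trips",
    "n_dancefloor_visits",
    "median_speed",
    "circadian_coeff",
    "dispersion",
    "fraction_nest_visited",
]


def default_speed_gap(frame_rate: float) -> float:
    """Maximum time between detections for a valid speed pair.

    At the reference 3 Hz this is the 1-second rule; at reduced frame rates
    the gap scales so consecutive frames still qualify.
    """
    return max(1.0, 1.5 / frame_rate)


def median_speed(times_s: np.ndarray, x: np.ndarray, y: np.ndarray,
                 side: np.ndarray, max_gap_s: float = 1.0) -> float:
    """Median speed (cm/s) over consecutive same-side detection pairs.

    Pairs spanning a comb-side switch or separated by more than
    ``max_gap_s`` are omitted.  Returns NaN if no pair qualifies.  Medians
    of an even number of values use the mean-of-middle-two convention.
    """
    if len(times_s) < 2:
        return math.nan
    dt = np.diff(times_s)
    ok = (dt > 0) & (dt <= max_gap_s) & (side[1:] == side[:-1])
    if not ok.any():
        return math.nan
    d = np.hypot(np.diff(x), np.diff(y))
    return float(np.median(d[ok] / dt[ok]))


def circadian_coefficient(hours: np.ndarray, speeds: np.ndarray,
                          m: float = SOLAR_NOON_H) -> float:
    """Normalized projection of hourly speeds onto a daily rhythm.

    ``C = sum_h s_h r(h) / sum_h s_h`` with ``r(h) = cos(2*pi*(h - m)/24)``,
    where ``hours`` are bin centres and ``m`` is local solar noon.  Bounded
    in [-1, 1]; +1/-1 occur only when the bee is observed solely at the
    peak/trough of the rhythm (e.g. not observed for most of the day).
    Positive values mean faster (or only) observed during the day.
    NaN speeds are treated as unobserved hours; returns NaN if nothing
    remains or all speeds are zero.
    """
    hours = np.asarray(hours, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    keep = np.isfinite(speeds)
    if not keep.any():
        return math.nan
    s = speeds[keep]
    if np.any(s < 0):
        raise ValueError("speeds must be nonnegative")
    total = s.sum()
    if total == 0:
        return math.nan
    r = np.cos(2.0 * np.pi * (hours[keep] - m) / 24.0)
    return float(np.dot(s, r) / total)


def detect_trips(seconds_of_day: np.ndarray, exit_dist: np.ndarray,
                 frame_rate: float, t_obs: float = T_OBS_S,
                 d_exit: float = D_EXIT_CM) -> tuple[int, float]:
    """Estimate outside trips for one bee-day from 1-min occupancy bins.

    A bee's barcode is not always detected even when it is in the hive, so
    departures are inferred jointly from non-detection and prior proximity
    to the exit: per 1-min bin compute the time observed
    (detections / frame_rate) and the median exit distance; an exit happens
    at bin t when observed time < ``t_obs`` and the previous bin's median
    exit distance < ``d_exit``; the bee re-enters at the first later bin
    with observed time >= ``t_obs``.  A trip still open at day end closes at
    midnight and its elapsed span counts as time outside.

    Returns ``(n_trips, time_outside_s)``.
    """
    sec = np.asarray(seconds_of_day, dtype=float)
    bins = np.minimum((sec // 60).astype(int), 1439)
    counts = np.bincount(bins, minlength=1440)
    obs = counts / frame_rate
    med = np.full(1440, np.inf)
    if len(sec):
        s = pd.Series(np.asarray(exit_dist, dtype=float))
        g = s.groupby(bins).median()
        med[g.index.to_numpy()] = g.to_numpy()
    prev_ok = (counts[:-1] > 0) & (med[:-1] < d_exit)
    candidates = np.flatnonzero((obs[1:] < t_obs) & prev_ok) + 1
    reentry = np.flatnonzero(obs >= t_obs)
    n_trips = 0
    time_outside = 0.0
    i = 0
    while i < len(candidates):
        b = candidates[i]
        j = int(np.searchsorted(reentry, b))
        e = int(reentry[j]) if j < len(reentry) else 1440
        n_trips += 1
        time_outside += (e - b) * 60.0
        i = int(np.searchsorted(candidates, e, side="left"))
    return n_trips, time_outside


def count_dancefloor_visits(on_dancefloor: np.ndarray) -> int:
    """Number of entries onto the dance floor from another substrate.

    Counts off->on transitions across consecutive (time-sorted) detections.
    A bee whose first detection is already on the dance floor has not
    entered it from another substrate, so a run starting on the dance floor
    contributes no entry.
    """
    d = np.asarray(on_dancefloor, dtype=bool)
    if len(d) < 2:
        return 0
    return int(np.count_nonzero(d[1:] & ~d[:-1]))


def dispersion(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square distance (cm) from the centroid of the detections."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        return math.nan
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.sqrt(np.mean(dx * dx + dy * dy)))


def fraction_nest_visited(x: np.ndarray, y: np.ndarray, geometry: NestGeometry) -> float:
    """Fraction of nest grid cells containing at least one detection."""
    if len(np.asarray(x)) == 0:
        return 0.0
    ix, iy = geometry.cell_index(x, y)
    visited = np.unique(ix.astype(np.int64) * geometry.n_cells_y + iy)
    return float(len(visited) / geometry.n_cells)


@dataclass
class HourlyRecord:
    """Aggregates for one bee in one hour (>= 10 confident detections)."""

    hour: int
    n_detections: int
    time_observed: float
    median_speed: float
    f_honey: float
    f_brood: float
    f_dancefloor: float
    median_exit_distance: float
    visited_cells: np.ndarray
    sum_x: float
    sum_y: float
    sum_x2: float
    sum_y2: float
    n_dancefloor_entries: int


def _hourly_records(sec: np.ndarray, x: np.ndarray, y: np.ndarray, side: np.ndarray,
                    maps_bracket, geometry: NestGeometry, frame_rate: float,
                    max_speed_gap_s: float) -> list[HourlyRecord]:
    map_a, map_b, w_a, w_b = maps_bracket
    hours = (sec // 3600).astype(int)
    ix, iy = geometry.cell_index(x, y)
    on_a = {s: map_a.merged_mask(s)[iy, ix] for s in ("honey", "brood", "dancefloor")}
    on_b = {s: map_b.merged_mask(s)[iy, ix] for s in ("honey", "brood", "dancefloor")}
    # the dance floor is fixed across maps, so entry counting is map-independent
    df_flags = on_a["dancefloor"]
    entries = np.flatnonzero(df_flags[1:] & ~df_flags[:-1]) + 1
    entry_hours = np.bincount(hours[entries], minlength=24) if len(entries) else np.zeros(24, int)
    dists = exit_distance(x, y, geometry)
    cell_id = ix.astype(np.int64) * geometry.n_cells_y + iy

    records = []
    order = np.argsort(hours, kind="stable")  # detections are time-sorted per hour already
    bounds = np.searchsorted(hours[order], np.arange(25))
    for h in range(24):
        sl = order[bounds[h]:bounds[h + 1]]
        if len(sl) < MIN_HOUR_DETECTIONS:
            continue
        records.append(HourlyRecord(
            hour=h,
            n_detections=len(sl),
            time_observed=len(sl) / frame_rate,
            median_speed=median_speed(sec[sl], x[sl], y[sl], side[sl], max_speed_gap_s),
            f_honey=float(w_a * on_a["honey"][sl].mean() + w_b * on_b["honey"][sl].mean()),
            f_brood=float(w_a * on_a["brood"][sl].mean() + w_b * on_b["brood"][sl].mean()),
            f_dancefloor=float(w_a * on_a["dancefloor"][sl].mean()
                               + w_b * on_b["dancefloor"][sl].mean()),
            median_exit_distance=float(np.median(dists[sl])),
            visited_cells=np.unique(cell_id[sl]),
            sum_x=float(x[sl].sum()),
            sum_y=float(y[sl].sum()),
            sum_x2=float((x[sl] ** 2).sum()),
            sum_y2=float((y[sl] ** 2).sum()),
            n_dancefloor_entries=int(entry_hours[h]),
        ))
    return records


def bin_hourly(detections: pd.DataFrame, maps: CombMapSeries, geometry: NestGeometry,
               frame_rate: float, confidence_threshold: float = CONFIDENCE_THRESHOLD,
               max_speed_gap_s: float | None = None) -> list[HourlyRecord]:
    """Hourly records for one bee on one calendar day.

    Detections must be time-sorted and belong to a single bee and date.
    Only detections with confidence strictly above the threshold count, and
    hours with fewer than 10 qualifying detections are omitted.
    """
    if max_speed_gap_s is None:
        max_speed_gap_s = default_speed_gap(frame_rate)
    det = detections[detections["confidence"] > confidence_threshold]
    if det.empty:
        return []
    ts = pd.to_datetime(det["timestamp"])
    date = ts.iloc[0].date()
    sec = (ts - pd.Timestamp(date)).dt.total_seconds().to_numpy()
    bracket = maps.bracket(date)
    return _hourly_records(sec, det["x_cm"].to_numpy(), det["y_cm"].to_numpy(),
                           det["side"].to_numpy(), bracket, geometry, frame_rate,
                           max_speed_gap_s)


def aggregate_day(hourly: Sequence[HourlyRecord], trips: tuple[int, float],
                  geometry: NestGeometry) -> dict | None:
    """Combine hourly records and the day's trip estimate into one row.

    Time observed, trips and dance-floor visits are sums; substrate
    fractions, exit distance and speed are averages weighted by time
    observed; dispersion and nest fraction pool the kept hours' detections;
    the circadian coefficient projects the hourly speed profile onto the
    daily rhythm.  Returns None when no hour was observed.
    """
    if not hourly:
        return None
    w = np.array([h.time_observed for h in hourly])
    total_w = w.sum()
    if total_w <= 0:
        return None
    n_det = sum(h.n_detections for h in hourly)

    def wavg(vals, weights):
        vals = np.asarray(vals, dtype=float)
        keep = np.isfinite(vals)
        if not keep.any():
            return math.nan
        return float(np.average(vals[keep], weights=weights[keep]))

    speeds = np.array([h.median_speed for h in hourly])
    hours_c = np.array([h.hour + 0.5 for h in hourly])
    sx = sum(h.sum_x for h in hourly)
    sy = sum(h.sum_y for h in hourly)
    sx2 = sum(h.sum_x2 for h in hourly)
    sy2 = sum(h.sum_y2 for h in hourly)
    var = max((sx2 + sy2) / n_det - (sx / n_det) ** 2 - (sy / n_det) ** 2, 0.0)
    visited = np.unique(np.concatenate([h.visited_cells for h in hourly]))
    n_trips, time_outside = trips
    return {
        "f_honey": wavg([h.f_honey for h in hourly], w),
        "f_brood": wavg([h.f_brood for h in hourly], w),
        "f_dancefloor": wavg([h.f_dancefloor for h in hourly], w),
        "exit_distance_median": wavg([h.median_exit_distance for h in hourly], w),
        "time_observed": float(total_w),
        "time_outside": float(time_outside),
        "n_outside_trips": int(n_trips),
        "n_dancefloor_visits": int(sum(h.n_dancefloor_entries for h in hourly)),
        "median_speed": wavg(speeds, w),
        "circadian_coeff": circadian_coefficient(hours_c, speeds),
        "dispersion": float(math.sqrt(var)),
        "fraction_nest_visited": float(len(visited) / geometry.n_cells),
        "n_detections": int(n_det),
    }


def compute_behavioral_days(detections: pd.DataFrame, maps: CombMapSeries,
                            registry: pd.DataFrame, frame_rate: float,
                            geometry: NestGeometry | None = None,
                            confidence_threshold: float = CONFIDENCE_THRESHOLD,
                            t_obs: float = T_OBS_S, d_exit: float = D_EXIT_CM,
                            max_speed_gap_s: float | None = None) -> pd.DataFrame:
    """Compute behavioral-day rows for every (bee, date) in a detection table.

    Returns a DataFrame with the 12 metric columns of :data:`METRICS` plus
    ``bee_id, date, age, cohort, n_detections``.
    """
    if geometry is None:
        geometry = maps.geometry
    if max_speed_gap_s is None:
        max_speed_gap_s = default_speed_gap(frame_rate)
    det = detections[detections["confidence"] > confidence_threshold]
    if det.empty:
        return pd.DataFrame(columns=["bee_id", "date", "age", "cohort", *METRICS,
                                     "n_detections"])
    ts = pd.to_datetime(det["timestamp"])
    dates = ts.dt.date.to_numpy()
    sec = (ts - ts.dt.normalize()).dt.total_seconds().to_numpy()
    x = det["x_cm"].to_numpy(dtype=float)
    y = det["y_cm"].to_numpy(dtype=float)
    side = det["side"].to_numpy()
    bees = det["bee_id"].to_numpy()

    reg = registry.set_index("bee_id")
    brackets: dict = {}
    rows = []
    frame = pd.DataFrame({"bee_id": bees, "date": dates})
    for (bee, date), idx in frame.groupby(["bee_id", "date"], sort=True).indices.items():
        idx = np.asarray(idx)
        idx = idx[np.argsort(sec[idx], kind="stable")]
        if date not in brackets:
            brackets[date] = maps.bracket(date)
        hourly = _hourly_records(sec[idx], x[idx], y[idx], side[idx], brackets[date],
                                 geometry, frame_rate, max_speed_gap_s)
        if not hourly:
            continue
        dists = exit_distance(x[idx], y[idx], geometry)
        trips = detect_trips(sec[idx], dists, frame_rate, t_obs, d_exit)
        row = aggregate_day(hourly, trips, geometry)
        if row is None:
            continue
        row["bee_id"] = bee
        row["date"] = date
        if bee in reg.index:
            birth = reg.at[bee, "birth_date"]
            row["age"] = (date - birth).days
            row["cohort"] = reg.at[bee, "cohort"]
        else:
            row["age"] = np.nan
            row["cohort"] = None
        rows.append(row)
    cols = ["bee_id", "date", "age", "cohort", *METRICS, "n_detections"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
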