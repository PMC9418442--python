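"""Shared domain types for hive-tracking analysis.

Coordinates are centimetres in a single 2-D hive plane shared by both comb
sides (front/back), origin at the top-left, y increasing downward.  The nest
exit sits at the lower-right corner ``(width, height)``.  Comb content is a
raster of substrate labels on a square grid (default 2 cm), re-measured every
few days; content on intermediate days is obtained by linear interpolation in
time between the bracketing measurement maps.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Raw substrate labels as they appear in comb-map rasters.
SUBSTRATES = (
    "honey",
    "pollen",
    "brood_young",
    "brood_capped",
    "empty",
    "wood",
    "gallery",
    "dancefloor",
)

_CODE = {name: i for i, name in enumerate(SUBSTRATES)}

#: Young and capped brood report as a single "brood" category downstream.
MERGED_LABEL = {
    "brood_young": "brood",
    "brood_capped": "brood",
}

#: Non-comb cells excluded when computing nest content fractions.
NON_COMB = ("wood", "gallery")


class DomainError(ValueError):
    """A query outside the model's domain (bounds, date range, ...)."""


def _as_day_number(d) -> float:
    """Convert a date-like or numeric value to a day number on a common axis."""
    if isinstance(d, _dt.datetime):
        return d.timestamp() / 86400.0
    if isinstance(d, _dt.date):
        return float(d.toordinal())
    if isinstance(d, pd.Timestamp):
        return d.timestamp() / 86400.0
    return float(d)


def interpolation_weights(query_date, date_before, date_after) -> tuple[float, float]:
    """Linear interpolation weights between two comb measurement days.

    Returns ``(w_A, w_B)`` for the earlier map A and the later map B such
    that ``w_A + w_B = 1`` and the nearer measurement receives the larger
    weight: ``w_A = (after - query) / (after - before)``.

    If both measurement dates equal the query (only one map exists), the
    result is ``(1.0, 0.0)``.
    """
    q = _as_day_number(query_date)
    a = _as_day_number(date_before)
    b = _as_day_number(date_after)
    if not (a <= q <= b):
        raise DomainError(
            f"query day {query_date!r} outside measurement interval "
            f"[{date_before!r}, {date_after!r}]"
        )
    if a == b:
        return (1.0, 0.0)
    w_a = (b - q) / (b - a)
    return (w_a, 1.0 - w_a)


@dataclass(frozen=True)
class NestGeometry:
    """Hive-plane geometry: size, exit location and the analysis grid."""

    width: float
    height: float
    grid_cell: float = 2.0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise DomainError("nest dimensions must be positive")
        if self.grid_cell <= 0:
            raise DomainError("grid cell size must be positive")

    @property
    def exit_point(self) -> tuple[float, float]:
        return (self.width, self.height)

    @property
    def n_cells_x(self) -> int:
        return int(math.ceil(self.width / self.grid_cell))

    @property
    def n_cells_y(self) -> int:
        return int(math.ceil(self.height / self.grid_cell))

    @property
    def n_cells(self) -> int:
        return self.n_cells_x * self.n_cells_y

    def cell_index(self, x, y):
        """Grid indices ``(ix, iy)`` under the half-open cell convention.

        Cells are ``[x0, x0 + grid_cell) x [y0, y0 + grid_cell)``, so a point
        on a shared edge belongs to the cell to its lower-right (larger
        index), deterministically.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(x < 0) or np.any(y < 0) or np.any(x >= self.width + self.grid_cell) \
                or np.any(y >= self.height + self.grid_cell):
            raise DomainError("coordinates outside nest bounds")
        ix = np.minimum((x // self.grid_cell).astype(int), self.n_cells_x - 1)
        iy = np.minimum((y // self.grid_cell).astype(int), self.n_cells_y - 1)
        return ix, iy


def exit_distance(x, y, geometry: NestGeometry):
    """Euclidean distance (cm) to the nest exit at the lower-right corner.

    Both comb sides share one plane, so switching sides adds no distance.
    """
    ex, ey = geometry.exit_point
    return np.hypot(np.asarray(x, dtype=float) - ex, np.asarray(y, dtype=float) - ey)


@dataclass
class CombMap:
    """Substrate label raster for one comb measurement date."""

    measurement_date: _dt.date
    codes: np.ndarray  # (n_cells_y, n_cells_x) int8 codes into SUBSTRATES
    geometry: NestGeometry
    _masks: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        expect = (self.geometry.n_cells_y, self.geometry.n_cells_x)
        if self.codes.shape != expect:
            raise DomainError(f"label grid shape {self.codes.shape} != {expect}")
        if self.codes.min() < 0 or self.codes.max() >= len(SUBSTRATES):
            raise DomainError("unknown substrate code in comb map")

    def merged_mask(self, substrate: str) -> np.ndarray:
        """Boolean cell mask for a merged substrate label (e.g. 'brood')."""
        if substrate not in self._masks:
            raw = [s for s in SUBSTRATES if MERGED_LABEL.get(s, s) == substrate]
            if not raw:
                raise DomainError(f"unknown substrate {substrate!r}")
            mask = np.zeros_like(self.codes, dtype=bool)
            for s in raw:
                mask |= self.codes == _CODE[s]
            self._masks[substrate] = mask
        return self._masks[substrate]

    def on_substrate(self, x, y, substrate: str) -> np.ndarray:
        ix, iy = self.geometry.cell_index(x, y)
        return self.merged_mask(substrate)[iy, ix]

    def content_fraction(self, substrate: str) -> float:
        """Fraction of comb-area cells (wood/gallery excluded) with this label."""
        comb = np.ones_like(self.codes, dtype=bool)
        for s in NON_COMB:
            comb &= self.codes != _CODE[s]
        denom = int(comb.sum())
        if denom == 0:
            return 0.0
        return float((self.merged_mask(substrate) & comb).sum() / denom)


def substrate_at(x: float, y: float, comb_map: CombMap) -> str:
    """Merged substrate label of the grid cell containing ``(x, y)``.

    Young and capped brood both report as ``"brood"``.
    """
    ix, iy = comb_map.geometry.cell_index(x, y)
    raw = SUBSTRATES[int(comb_map.codes[iy, ix])]
    return MERGED_LABEL.get(raw, raw)


class CombMapSeries:
    """Date-ordered series of comb maps with temporal interpolation.

    The dance-floor region is required to be identical in every map: it is
    defined once, over the whole observation period, rather than per
    measurement day.
    """

    def __init__(self, maps: Sequence[CombMap]):
        if not maps:
            raise DomainError("empty comb-map series")
        self.maps = sorted(maps, key=lambda m: m.measurement_date)
        self.geometry = self.maps[0].geometry
        df0 = self.maps[0].merged_mask("dancefloor")
        for m in self.maps[1:]:
            if m.geometry != self.geometry:
                raise DomainError("comb maps in a series must share geometry")
            if not np.array_equal(df0, m.merged_mask("dancefloor")):
                raise DomainError("dance-floor region must be fixed across maps")
        self._dates = [m.measurement_date for m in self.maps]

    def __len__(self):
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)

    def bracket(self, date) -> tuple[CombMap, CombMap, float, float]:
        """Bracketing maps and weights ``(map_A, map_B, w_A, w_B)`` for a date.

        Dates before the first (after the last) measurement clamp to the
        nearest map with full weight.
        """
        q = _as_day_number(date)
        days = [_as_day_number(d) for d in self._dates]
        if q <= days[0]:
            return (self.maps[0], self.maps[0], 1.0, 0.0)
        if q >= days[-1]:
            return (self.maps[-1], self.maps[-1], 1.0, 0.0)
        hi = int(np.searchsorted(days, q, side="left"))
        lo = hi - 1 if days[hi] > q else hi
        if days[lo] == q:
            return (self.maps[lo], self.maps[lo], 1.0, 0.0)
        w_a, w_b = interpolation_weights(q, days[lo], days[hi])
        return (self.maps[lo], self.maps[hi], w_a, w_b)

    def content_fraction(self, substrate: str, date) -> float:
        """Nest content fraction of a substrate, interpolated to ``date``."""
        map_a, map_b, w_a, w_b = self.bracket(date)
        return w_a * map_a.content_fraction(substrate) + w_b * map_b.content_fraction(substrate)

    @property
    def dancefloor_mask(self) -> np.ndarray:
        return self.maps[0].merged_mask("dancefloor")


@dataclass(frozen=True)
class BeeRecord:
    """Registry entry for one marked bee."""

    bee_id: str
    cohort_id: str
    birth_date: _dt.date
    death_date: _dt.date

    def __post_init__(self):
        if self.death_date < self.birth_date:
            raise DomainError("death_date precedes birth_date")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = ["bee_id", "timestamp", "x_cm", "y_cm", "side", "confidence"]
REGISTRY_COLUMNS = ["bee_id", "cohort", "birth_date", "death_date"]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


def write_detections(detections: pd.DataFrame, path) -> None:
    """Write a detection table as delimited text (ISO-8601 timestamps, ms)."""
    df = detections[DETECTION_COLUMNS].copy()
    ts = pd.to_datetime(df["timestamp"]).dt.round("ms")
    df["timestamp"] = ts.dt.strftime(_TS_FORMAT).str.slice(0, 23)
    df.to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bee_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["side"] = df["side"].astype(np.int8)
    for c in ("x_cm", "y_cm", "confidence"):
        df[c] = df[c].astype(float)
    return df


def write_registry(registry: pd.DataFrame, path) -> None:
    df = registry[REGISTRY_COLUMNS].copy()
    for c in ("birth_date", "death_date"):
        df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bee_id": str, "cohort": str})
    for c in ("birth_date", "death_date"):
        df[c] = pd.to_datetime(df[c]).dt.date
    return df


def comb_map_to_dict(comb_map: CombMap) -> dict:
    g = comb_map.geometry
    return {
        "measurement_date": comb_map.measurement_date.isoformat(),
        "origin_cm": [0.0, 0.0],
        "cell_size_cm": g.grid_cell,
        "nest_width_cm": g.width,
        "nest_height_cm": g.height,
        "labels": [[SUBSTRATES[c] for c in row] for row in comb_map.codes],
    }


def comb_map_from_dict(d: dict) -> CombMap:
    geometry = NestGeometry(
        width=float(d["nest_width_cm"]),
        height=float(d["nest_height_cm"]),
        grid_cell=float(d["cell_size_cm"]),
    )
    codes = np.array([[_CODE[lab] for lab in row] for row in d["labels"]], dtype=np.int8)
    return CombMap(
        measurement_date=_dt.date.fromisoformat(d["measurement_date"]),
        codes=codes,
        geometry=geometry,
    )


def write_comb_maps(series: CombMapSeries, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in series:
        p = directory / f"combmap_{m.measurement_date.isoformat()}.json"
        p.write_text(json.dumps(comb_map_to_dict(m), indent=1))
        paths.append(p)
    return paths


def read_comb_maps(paths_or_directory) -> CombMapSeries:
    p = Path(paths_or_directory) if not isinstance(paths_or_directory, (list, tuple)) else None
    if p is not None and p.is_dir():
        files: Iterable = sorted(p.glob("combmap_*.json"))
    else:
        files = [Path(f) for f in paths_or_directory]
    maps = [comb_map_from_dict(json.loads(Path(f).read_text())) for f in files]
    return CombMapSeries(maps)
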