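"""A-priori habitat masks, sea-ice membership, trip stages, size matching.

The study region is partitioned into four bathymetry/latitude habitats:

* ``ANT_SHELF``    — Antarctic continental shelf: depth in (0, 2000] m, south of 60S;
* ``KERG_PLATEAU`` — Kerguelen Plateau: depth in (0, 1000] m, at or north of 60S;
* ``OCEANIC_EAST`` — deep ocean (> 1000 m) at or east of 70E;
* ``OCEANIC_WEST`` — deep ocean (> 1000 m) west of 70E;
* ``OTHER``        — residual cases (land, shallow unclassifiable cells).

Rules are applied in the precedence order above so that a point satisfying
several definitions (e.g. 1500 m south of 60S) gets the shelf label, keeping
the shelf/oceanic dichotomy sharp.  Boundary conventions: depth bands are
half-open (plateau (0, 1000], shelf (0, 2000], oceanic (1000, inf)); lat
exactly -60 falls in the northern rule set; lon exactly 70 is EAST.

A location is "in sea-ice" when that day's concentration exceeds 15%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

from .geo import RasterGrid, Track

ICE_THRESHOLD = 0.15


class Habitat(str, Enum):
    ANT_SHELF = "ANT_SHELF"
    KERG_PLATEAU = "KERG_PLATEAU"
    OCEANIC_EAST = "OCEANIC_EAST"
    OCEANIC_WEST = "OCEANIC_WEST"
    OTHER = "OTHER"


#: fixed order used for precedence and tie-breaking
LABEL_ORDER = [
    Habitat.ANT_SHELF,
    Habitat.KERG_PLATEAU,
    Habitat.OCEANIC_EAST,
    Habitat.OCEANIC_WEST,
    Habitat.OTHER,
]

SHELF_LABELS = (Habitat.ANT_SHELF, Habitat.KERG_PLATEAU)


def classify_locations(lat, lon, depth_m) -> np.ndarray:
    """Vectorized habitat classification; returns an object array of Habitat.

    Total: every (lat, lon, depth) triple receives exactly one label; land
    (depth <= 0) and NaN depth map to OTHER, never an exception.
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    depth = np.atleast_1d(np.asarray(depth_m, dtype=float))
    water = np.isfinite(depth) & (depth > 0)
    conds = [
        water & (depth <= 2000.0) & (lat < -60.0),
        water & (depth <= 1000.0) & (lat >= -60.0),
        water & (depth > 1000.0) & (lon >= 70.0),
        water & (depth > 1000.0) & (lon < 70.0),
    ]
    out = np.empty(lat.shape, dtype=object)
    out[:] = Habitat.OTHER
    # apply in reverse so earlier (higher-precedence) rules overwrite later ones
    for habitat, cond in list(zip(LABEL_ORDER[:4], conds))[::-1]:
        out[cond] = habitat
    return out


def classify_location(lat: float, lon: float, depth_m: float) -> Habitat:
    """Habitat label for a single location (see :func:`classify_locations`)."""
    return classify_locations([lat], [lon], [depth_m])[0]


def in_ice(concentration) -> np.ndarray:
    """True where sea-ice concentration strictly exceeds 15%; NaN counts as False."""
    conc = np.asarray(concentration, dtype=float)
    with np.errstate(invalid="ignore"):
        return (conc > ICE_THRESHOLD) & np.isfinite(conc)


@dataclass(frozen=True)
class StageWindows:
    """Three inclusive day-since-departure intervals defining trip stages."""

    sex: str
    windows: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def stage_of(self, t) -> np.ndarray:
        """Stage index 1..3 per day, 0 outside every window."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=int)
        for i, (lo, hi) in enumerate(self.windows, start=1):
            out[(t >= lo) & (t <= hi)] = i
        return out


# Stage 1 covers days 21-87 for both sexes (the first three weeks are transit).
# Male stages 2 and 3 follow the mid-year haul out; female stages are contiguous.
_MALE_WINDOWS = ((21, 87), (146, 212), (213, 279))
_FEMALE_WINDOWS = ((21, 87), (88, 154), (155, 221))


def stage_windows(sex: str) -> StageWindows:
    if sex == "male":
        return StageWindows("male", _MALE_WINDOWS)
    if sex == "female":
        return StageWindows("female", _FEMALE_WINDOWS)
    raise ValueError(f"unknown sex {sex!r}")


@dataclass
class StageOccupancy:
    """Per-stage habitat occupancy for one seal."""

    seal_id: str
    stage: int
    percentages: dict  # Habitat -> percent of classified days
    dominant: Habitat | None
    tie: bool
    n_days_classified: int


def dominant_habitat(
    track: Track, bathy: RasterGrid, windows: StageWindows, stage: int
) -> StageOccupancy:
    """Occupancy percentages and the dominant habitat over one stage window.

    Days counted are non-gap daily positions whose time-since-departure falls
    inside the (inclusive) window and whose position has a bathymetry value.
    With no classifiable days the occupancy is returned empty
    (``n_days_classified == 0``, ``dominant is None``) so callers can exclude
    the seal from that stage's summary.  Percentage ties are broken by the
    fixed label order and flagged.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    lo, hi = windows.windows[stage - 1]
    sel = (track.t >= lo) & (track.t <= hi) & ~track.gap
    depth = bathy.lookup_many(track.lon[sel], track.lat[sel])
    ok = np.isfinite(depth)
    labels = classify_locations(track.lat[sel][ok], track.lon[sel][ok], depth[ok])
    n = int(ok.sum())
    if n == 0:
        return StageOccupancy(track.seal_id, stage, {}, None, False, 0)
    counts = Counter(labels.tolist())
    pct = {h: 100.0 * c / n for h, c in counts.items() if c}
    best = max(pct.values())
    top = [h for h in LABEL_ORDER if pct.get(h, 0.0) == best]
    return StageOccupancy(track.seal_id, stage, pct, top[0], len(top) > 1, n)


def size_match(
    female_lengths: Mapping[str, float], male_lengths: Mapping[str, float]
) -> tuple[set, set, tuple[float, float]]:
    """Size-match the sexes on the female length distribution.

    Bounds are the empirical 1st and 99th percentiles of the female standard
    lengths (linear-interpolation definition); individuals of either sex with
    length inside [lower, upper] (inclusive) are retained.  Returns
    (retained_female_ids, retained_male_ids, (lower, upper)).
    """
    if len(female_lengths) < 3:
        raise ValueError("size matching needs at least 3 females")
    f = np.asarray(list(female_lengths.values()), dtype=float)
    lower, upper = np.percentile(f, [1.0, 99.0])
    keep_f = {k for k, v in female_lengths.items() if lower <= v <= upper}
    keep_m = {k for k, v in male_lengths.items() if lower <= v <= upper}
    return keep_f, keep_m, (float(lower), float(upper))
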