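"""Mid-year haul-out detection and haul-out phenology summaries.

A mid-year haul out is a period a seal spends on or next to the coast in the
middle of its postmolt trip: at least 5 consecutive daily positions ("longer
than 4 days") within 4 km of the nearest land, starting no earlier than 30
days after departure ("at sea for at least a month") and no earlier than 30
days after the previous haul-out ended.  Single-day offshore excursions are
merged before run-length testing to absorb location noise.

Phenology summaries are restricted to seals whose track spans at least 150
days, excluding early tag failures and delayed departures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import RasterGrid, Track, great_circle_km, wrap_doy

COAST_KM = 4.0
MIN_DURATION_DAYS = 5       # "longer than 4 days"
MIN_DAYS_AT_SEA = 30        # "at least a month"
MERGE_GAP_DAYS = 1
MIN_TRACK_SPAN_DAYS = 150


@dataclass(frozen=True)
class HaulOutEvent:
    seal_id: str
    start_day: float   # days since departure
    end_day: float
    start_doy: int     # calendar day of haul-out start
    duration_days: int


def coast_distance_grid(bathy: RasterGrid) -> RasterGrid:
    """Distance (km) from each cell centre to the nearest land cell centre.

    Land is any bathymetry cell with depth <= 0.  Brute-force great-circle
    search; the grids used here are desk-scale so this is cheap.
    """
    land = bathy.values <= 0
    if not land.any():
        raise ValueError("bathymetry grid has no land cells")
    lon_g, lat_g = np.meshgrid(bathy.lon_axis, bathy.lat_axis)
    land_lon = lon_g[land]
    land_lat = lat_g[land]
    out = np.empty(bathy.values.shape)
    for i in range(len(bathy.lat_axis)):  # row-wise to bound memory
        d = great_circle_km(
            bathy.lon_axis[None, :].T, np.full((len(bathy.lon_axis), 1), bathy.lat_axis[i]),
            land_lon[None, :], land_lat[None, :],
        )
        out[i, :] = d.min(axis=1)
    return RasterGrid(bathy.lon_axis, bathy.lat_axis, out, "distance_to_coast_km")


def detect_haulouts(
    track: Track,
    coast_dist: RasterGrid,
    coast_km: float = COAST_KM,
    min_duration_days: int = MIN_DURATION_DAYS,
    min_days_at_sea: int = MIN_DAYS_AT_SEA,
    merge_gap_days: int = MERGE_GAP_DAYS,
) -> list[HaulOutEvent]:
    """Detect mid-year haul-out events along one daily track.

    Returns maximal runs of consecutive coastal days (distance-to-coast
    <= ``coast_km``) of length >= ``min_duration_days``, starting at least
    ``min_days_at_sea`` days after departure and after the previous event's
    end.  Runs separated by <= ``merge_gap_days`` offshore days are merged
    first.  The sequence may be empty.
    """
    dist = coast_dist.lookup_many(track.lon, track.lat)
    coastal = np.isfinite(dist) & (dist <= coast_km) & ~track.gap

    # bridge offshore interruptions of <= merge_gap_days before run-length testing
    merged = coastal.copy()
    idx = np.flatnonzero(coastal)
    if idx.size:
        gaps = np.diff(idx)
        for k, g in enumerate(gaps):
            if 1 < g <= merge_gap_days + 1:
                merged[idx[k] : idx[k + 1]] = True

    events: list[HaulOutEvent] = []
    i = 0
    n = len(merged)
    prev_event_end = -np.inf
    while i < n:
        if merged[i]:
            j = i
            while j + 1 < n and merged[j + 1]:
                j += 1
            length = j - i + 1
            start_t = float(track.t[i])
            if (
                length >= min_duration_days
                and start_t >= min_days_at_sea
                and start_t >= prev_event_end + min_days_at_sea
            ):
                events.append(
                    HaulOutEvent(
                        seal_id=track.seal_id,
                        start_day=start_t,
                        end_day=float(track.t[j]),
                        start_doy=int(wrap_doy(track.doy[i])),
                        duration_days=length,
                    )
                )
                prev_event_end = float(track.t[j])
            i = j + 1
        else:
            i += 1
    return events


def eligible_for_haulout_stats(track: Track, min_span_days: float = MIN_TRACK_SPAN_DAYS) -> bool:
    """True iff the track spans at least ``min_span_days`` days."""
    return track.span_days >= min_span_days


def daily_percent_hauled(
    tracks: Sequence[Track], events: Iterable[HaulOutEvent]
) -> pd.Series:
    """Percent of transmitting seals hauled out on each calendar day.

    For each day-of-year: 100 x (seals inside an event) / (seals with a
    non-gap location that day).  Days on which no seal transmitted are
    missing (NaN).
    """
    by_seal: dict[str, list[HaulOutEvent]] = {}
    for ev in events:
        by_seal.setdefault(ev.seal_id, []).append(ev)

    at_sea = np.zeros(366, dtype=int)   # index doy-1
    hauled = np.zeros(366, dtype=int)
    for tr in tracks:
        keep = ~tr.gap
        doys = wrap_doy(tr.doy[keep]).astype(int)
        t = tr.t[keep]
        seen = np.zeros(366, dtype=bool)
        hauled_seen = np.zeros(366, dtype=bool)
        in_event = np.zeros(t.shape, dtype=bool)
        for ev in by_seal.get(tr.seal_id, []):
            in_event |= (t >= ev.start_day) & (t <= ev.end_day)
        seen[doys - 1] = True
        hauled_seen[doys[in_event] - 1] = True
        at_sea += seen
        hauled += hauled_seen

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(at_sea > 0, 100.0 * hauled / np.maximum(at_sea, 1), np.nan)
    return pd.Series(pct, index=pd.RangeIndex(1, 367, name="doy"), name="percent_hauled")
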