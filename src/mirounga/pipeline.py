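"""End-to-end assembly: from tracks, dives and rasters to the analysis table.

The analysis table has one row per (non-gap) seal-day carrying everything
the model-comparison stage consumes: sex, trip stage, habitat label, sea-ice
membership, move persistence, percent of benthic dives and drift rate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .dives import (
    DiveRecord,
    classify_benthic,
    daily_drift_rate,
    daily_percent_benthic,
    drift_rates_by_day,
)
from .geo import IceSeries, RasterGrid, SealMeta, Track, max_distance_from_colony
from .habitats import (
    StageOccupancy,
    classify_locations,
    dominant_habitat,
    in_ice,
    stage_windows,
)
from .haulout import coast_distance_grid, detect_haulouts, eligible_for_haulout_stats
from .movement import estimate_persistence

logger = logging.getLogger(__name__)


def classify_dives(
    dives: Sequence[DiveRecord], tracks: Sequence[Track], bathy: RasterGrid
) -> pd.DataFrame:
    """Benthic/pelagic label per dive, using the seafloor at the day's position.

    Returns columns seal_id, day, cls; unclassifiable dives (land cell,
    missing bathymetry, no matching track day) are dropped and counted in a
    log message.
    """
    pos = {}
    for tr in tracks:
        for t, lon, lat, gap in zip(tr.t, tr.lon, tr.lat, tr.gap):
            if not gap:
                pos[(tr.seal_id, int(t))] = (lon, lat)
    rows = []
    n_skipped = 0
    for dv in dives:
        key = (dv.seal_id, int(np.floor(dv.t)))
        if key not in pos:
            n_skipped += 1
            continue
        lon, lat = pos[key]
        floor = bathy.lookup_many([lon], [lat])[0]
        cls = classify_benthic(dv, floor)
        if cls is None:
            n_skipped += 1
            continue
        rows.append({"seal_id": dv.seal_id, "day": key[1], "cls": cls})
    if n_skipped:
        logger.info("classify_dives: %d dives unclassified (land/missing position)", n_skipped)
    return pd.DataFrame(rows, columns=["seal_id", "day", "cls"])


def compute_occupancies(
    tracks: Sequence[Track], metas: Sequence[SealMeta], bathy: RasterGrid
) -> list[StageOccupancy]:
    """Stage occupancies (stages 1-3) for every seal with classifiable days."""
    sex_of = {m.seal_id: m.sex for m in metas}
    out = []
    for tr in tracks:
        windows = stage_windows(sex_of[tr.seal_id])
        for stage in (1, 2, 3):
            out.append(dominant_habitat(tr, bathy, windows, stage))
    return out


def build_analysis_table(
    metas: Sequence[SealMeta],
    tracks: Sequence[Track],
    bathy: RasterGrid,
    ice: IceSeries | None = None,
    dives: Sequence[DiveRecord] | None = None,
    lam: float = 10.0,
) -> pd.DataFrame:
    """One row per usable seal-day with all behavioural covariates.

    Columns: seal_id, sex, t, doy, lon, lat, depth, habitat, stage, in_ice,
    gamma, percent_benthic, drift_rate.  ``in_ice`` is NaN where the ice
    concentration is unavailable (counted as unclassified); gamma is NaN on
    missing-flagged days; dive columns are NaN on days without data.
    """
    sex_of = {m.seal_id: m.sex for m in metas}
    benthic_daily = None
    drift_daily = None
    if dives is not None:
        cls = classify_dives(dives, tracks, bathy)
        benthic_daily = daily_percent_benthic(cls).set_index(["seal_id", "day"])
        drift_daily = daily_drift_rate(drift_rates_by_day(dives)).set_index(["seal_id", "day"])

    frames = []
    for tr in tracks:
        sex = sex_of[tr.seal_id]
        windows = stage_windows(sex)
        keep = ~tr.gap
        t = tr.t[keep]
        lon, lat, doy = tr.lon[keep], tr.lat[keep], tr.doy[keep]
        depth = bathy.lookup_many(lon, lat)
        habitat = np.array([h.value for h in classify_locations(lat, lon, depth)])
        stage = windows.stage_of(t)

        ice_flag = np.full(t.shape, np.nan)
        if ice is not None:
            conc = ice.concentration(lon, lat, doy)
            ice_flag = np.where(np.isfinite(conc), in_ice(conc).astype(float), np.nan)

        gamma = np.full(t.shape, np.nan)
        if len(tr) >= 4:
            series = estimate_persistence(tr, lam=lam)
            gmap = {
                float(d): g
                for d, g, miss in zip(series.day, series.gamma, series.missing)
                if not miss
            }
            gamma = np.array([gmap.get(float(x), np.nan) for x in t])

        df = pd.DataFrame(
            {
                "seal_id": tr.seal_id, "sex": sex, "t": t, "doy": doy,
                "lon": lon, "lat": lat, "depth": depth, "habitat": habitat,
                "stage": stage, "in_ice": ice_flag, "gamma": gamma,
            }
        )
        if benthic_daily is not None:
            key = pd.MultiIndex.from_arrays([np.repeat(tr.seal_id, len(t)), t.astype(int)])
            df["percent_benthic"] = benthic_daily["percent_benthic"].reindex(key).to_numpy()
            df["drift_rate"] = drift_daily["drift_rate"].reindex(key).to_numpy()
        else:
            df["percent_benthic"] = np.nan
            df["drift_rate"] = np.nan
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def pipeline_summary_inputs(metas, tracks, bathy):
    """Occupancies, haul-out events, eligibility and max distances in one pass."""
    coast = coast_distance_grid(bathy)
    occupancies = compute_occupancies(tracks, metas, bathy)
    events = []
    eligible = set()
    max_dist = {}
    colony = {(m.seal_id): (m.colony_lon, m.colony_lat) for m in metas}
    for tr in tracks:
        events.extend(detect_haulouts(tr, coast))
        if eligible_for_haulout_stats(tr):
            eligible.add(tr.seal_id)
        max_dist[tr.seal_id] = max_distance_from_colony(tr, *colony[tr.seal_id])
    return occupancies, events, eligible, max_dist
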