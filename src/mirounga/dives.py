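"""Benthic/pelagic dive classification and drift-rate body-condition proxy.

Dives arrive as abstracted 4-point time/depth profiles (plus implicit surface
endpoints), the compressed form transmitted by CTD-SRDL tags.  Two derived
quantities feed the analysis:

* the daily percentage of benthic dives (maximum depth within 20 m of the
  seafloor), a coarse prey-type indicator, and
* the daily drift rate (m/s) of passive drift segments, a buoyancy and hence
  lipid-store proxy: negative rates mean the seal sinks (lean), rates rising
  toward zero mean improving condition.

Drift segments are accepted by four explicit filters (relative duration,
absolute rate, start depth, uniqueness), then reduced to a per-day median
and smoothed with a centred rolling median.  All thresholds are module
constants and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BENTHIC_BAND_M = 20.0        # "within 20 m of the bottom"
DRIFT_MIN_FRACTION = 0.35    # drift segment must span >= 35% of the dive
DRIFT_MAX_RATE = 0.6         # |vertical rate| bound, m/s
DRIFT_MIN_START_DEPTH = 100.0
SMOOTH_WINDOW_DAYS = 5

DIVE_COLUMNS = [
    "seal_id", "t", "duration_s", "max_depth_m",
    "f1", "f2", "f3", "f4", "d1", "d2", "d3", "d4",
]


@dataclass(frozen=True)
class DiveRecord:
    """One abstracted dive: duration, max depth and 4 inflection points.

    ``f`` holds the four inflection times as fractions of dive duration in
    (0, 1), strictly increasing; ``d`` the corresponding depths (m, positive
    down).  The profile implicitly starts and ends at the surface (0, 0) and
    (1, 0).
    """

    seal_id: str
    t: float            # start time, days since departure
    duration_s: float
    max_depth: float
    f: tuple[float, float, float, float]
    d: tuple[float, float, float, float]

    def __post_init__(self):
        f = self.f
        if not (0.0 < f[0] < f[1] < f[2] < f[3] < 1.0):
            raise ValueError("inflection fractions must be strictly increasing in (0, 1)")
        if min(self.d) < 0:
            raise ValueError("profile depths must be >= 0")
        if max(self.d) > self.max_depth + 1.0:
            raise ValueError("profile depth exceeds max_depth by more than 1 m")

    def segments(self):
        """The 5 inter-point segments as (f_start, d_start, f_end, d_end)."""
        fs = (0.0, *self.f, 1.0)
        ds = (0.0, *self.d, 0.0)
        return [(fs[i], ds[i], fs[i + 1], ds[i + 1]) for i in range(5)]


def dives_to_frame(dives: Iterable[DiveRecord]) -> pd.DataFrame:
    rows = [
        {
            "seal_id": dv.seal_id, "t": dv.t, "duration_s": dv.duration_s,
            "max_depth_m": dv.max_depth,
            **{f"f{i+1}": dv.f[i] for i in range(4)},
            **{f"d{i+1}": dv.d[i] for i in range(4)},
        }
        for dv in dives
    ]
    return pd.DataFrame(rows, columns=DIVE_COLUMNS)


def frame_to_dives(df: pd.DataFrame) -> list[DiveRecord]:
    missing = [c for c in DIVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dive table is missing column(s) {missing}")
    return [
        DiveRecord(
            seal_id=str(r.seal_id), t=float(r.t), duration_s=float(r.duration_s),
            max_depth=float(r.max_depth_m),
            f=(r.f1, r.f2, r.f3, r.f4), d=(r.d1, r.d2, r.d3, r.d4),
        )
        for r in df.itertuples()
    ]


def write_dives(dives: Iterable[DiveRecord], path) -> None:
    dives_to_frame(dives).to_csv(path, index=False)


def read_dives(path) -> list[DiveRecord]:
    return frame_to_dives(pd.read_csv(path))


def classify_benthic(dive: DiveRecord, seafloor_depth: float, band_m: float = BENTHIC_BAND_M):
    """'benthic' if max depth is within ``band_m`` of the seafloor, else 'pelagic'.

    The band extends symmetrically above and below the gridded floor; the
    upper tolerance absorbs bathymetry grid error for dives nominally deeper
    than the cell value.  Over land cells (floor <= 0) or missing bathymetry
    the dive is unclassifiable and ``None`` is returned.
    """
    if not np.isfinite(seafloor_depth) or seafloor_depth <= 0:
        return None
    if seafloor_depth - band_m <= dive.max_depth <= seafloor_depth + band_m:
        return "benthic"
    return "pelagic"


def daily_percent_benthic(classified: pd.DataFrame) -> pd.DataFrame:
    """Per seal-day percentage of benthic dives.

    ``classified`` needs columns seal_id, day, cls (values 'benthic' /
    'pelagic'; unclassified rows should already be dropped).  Days with zero
    classified dives simply do not appear.
    """
    if classified.empty:
        return pd.DataFrame(columns=["seal_id", "day", "percent_benthic", "n_classified"])
    g = classified.groupby(["seal_id", "day"])["cls"]
    out = g.agg(
        percent_benthic=lambda s: 100.0 * (s == "benthic").sum() / len(s),
        n_classified="size",
    ).reset_index()
    return out


def detect_drift_dive(
    dive: DiveRecord,
    min_fraction: float = DRIFT_MIN_FRACTION,
    max_rate: float = DRIFT_MAX_RATE,
    min_start_depth: float = DRIFT_MIN_START_DEPTH,
):
    """Detect a passive drift segment; returns (segment_index, rate_m_s) or None.

    A segment qualifies when it (a) spans at least ``min_fraction`` of the
    dive duration, (b) has |vertical rate| <= ``max_rate`` m/s, (c) starts
    deeper than ``min_start_depth`` m.  Exactly one segment may qualify;
    ambiguous profiles are rejected.  Rates are signed with depth increase
    negative (a sinking, negatively buoyant seal).
    """
    hits = []
    for k, (f0, d0, f1, d1) in enumerate(dive.segments()):
        span = f1 - f0
        if span < min_fraction:
            continue
        dt = span * dive.duration_s
        rate = -(d1 - d0) / dt  # depth increase -> negative rate
        if abs(rate) > max_rate:
            continue
        if d0 <= min_start_depth:
            continue
        hits.append((k, rate))
    if len(hits) == 1:
        return hits[0]
    return None


def drift_rates_by_day(dives: Sequence[DiveRecord], **kwargs) -> pd.DataFrame:
    """One row (seal_id, day, rate) per detected drift dive."""
    rows = []
    for dv in dives:
        hit = detect_drift_dive(dv, **kwargs)
        if hit is not None:
            rows.append({"seal_id": dv.seal_id, "day": int(np.floor(dv.t)), "rate": hit[1]})
    return pd.DataFrame(rows, columns=["seal_id", "day", "rate"])


def daily_drift_rate(
    rates: pd.DataFrame, smooth_window: int = SMOOTH_WINDOW_DAYS
) -> pd.DataFrame:
    """Smoothed daily drift-rate series per seal.

    Per day: median of that day's detected drift rates (robust to single
    outliers).  Days between the first and last drift dive with no detection
    are linearly interpolated and flagged.  A centred rolling median of
    ``smooth_window`` days is then applied across the daily series.

    Returns columns seal_id, day, drift_rate, n_drift_dives, interpolated.
    """
    cols = ["seal_id", "day", "drift_rate", "n_drift_dives", "interpolated"]
    if rates.empty:
        return pd.DataFrame(columns=cols)
    pieces = []
    for seal_id, grp in rates.groupby("seal_id"):
        daily = grp.groupby("day")["rate"].agg(["median", "size"])
        full = pd.RangeIndex(int(daily.index.min()), int(daily.index.max()) + 1, name="day")
        daily = daily.reindex(full)
        interpolated = daily["size"].isna()
        series = daily["median"].interpolate(method="linear", limit_area="inside")
        smoothed = series.rolling(smooth_window, center=True, min_periods=1).median()
        pieces.append(
            pd.DataFrame(
                {
                    "seal_id": seal_id,
                    "day": full,
                    "drift_rate": smoothed.to_numpy(),
                    "n_drift_dives": daily["size"].fillna(0).astype(int).to_numpy(),
                    "interpolated": interpolated.to_numpy(),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)[cols]
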