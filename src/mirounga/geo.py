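"""Domain types, track I/O, daily regularization, spherical geometry, raster lookups.

Conventions used throughout the package:

* longitudes live in [-180, 180) degrees East;
* distances are great-circle kilometres on a sphere of radius 6371.0 km;
* bathymetry is stored as positive metres below sea level (land cells have
  depth <= 0), sea-ice concentration as a fraction in [0, 1];
* tracks are regular daily series (one position per 24 h) with a boolean
  gap flag marking interpolated days inside transmission gaps longer than
  ``MAX_GAP_DAYS``; flagged days are excluded from downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0  # 111.1949... km per degree of latitude
MAX_GAP_DAYS = 5.0
YEAR_DAYS = 365

RASTER_KINDS = ("bathymetry_depth_m", "ice_concentration_fraction", "distance_to_coast_km")

TRACK_COLUMNS = ["seal_id", "t", "doy", "lon", "lat", "gap"]
META_COLUMNS = ["seal_id", "sex", "standard_length_m", "departure_doy", "colony_lon", "colony_lat"]


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


def wrap_doy(doy):
    """Fold a (possibly fractional or negative) day-of-year into [1, 365]."""
    return ((np.asarray(doy) - 1) % YEAR_DAYS) + 1


@dataclass(frozen=True)
class SealMeta:
    """Capture metadata for one instrumented seal."""

    seal_id: str
    sex: str
    standard_length: float  # metres, nose-to-tail
    departure_doy: int      # calendar day-of-year of trip start
    colony_lon: float
    colony_lat: float

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r} for seal {self.seal_id}")
        if not self.standard_length > 0:
            raise ValueError(f"standard_length must be > 0 (seal {self.seal_id})")
        if not 1 <= self.departure_doy <= 366:
            raise ValueError(f"departure_doy out of [1, 366] (seal {self.seal_id})")


@dataclass
class Track:
    """A regular daily track: one location per 24-h step since departure."""

    seal_id: str
    t: np.ndarray      # days since departure, consecutive integers as floats
    doy: np.ndarray    # calendar day-of-year
    lon: np.ndarray    # degrees East in [-180, 180)
    lat: np.ndarray    # degrees North
    gap: np.ndarray = field(default=None)  # True where interpolated across a long gap

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.doy = np.asarray(self.doy, dtype=float)
        self.lon = normalize_lon(self.lon)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.gap is None:
            self.gap = np.zeros(self.t.shape, dtype=bool)
        else:
            self.gap = np.asarray(self.gap, dtype=bool)
        n = len(self.t)
        if any(len(a) != n for a in (self.doy, self.lon, self.lat, self.gap)):
            raise ValueError(f"track arrays for seal {self.seal_id} have unequal lengths")
        if n > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError(f"non-monotone time in track for seal {self.seal_id}")
            if np.any(np.abs(steps - 1.0) > 1e-6):
                raise ValueError(f"track for seal {self.seal_id} is not on a 24-hr step")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def span_days(self) -> float:
        """Trip span in days (0 for tracks with fewer than 2 positions)."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seal_id": self.seal_id,
                "t": self.t,
                "doy": self.doy,
                "lon": self.lon,
                "lat": self.lat,
                "gap": self.gap.astype(int),
            }
        )


def read_tracks(path) -> list[Track]:
    """Read one :class:`Track` per seal from a CSV file.

    The file must have columns ``seal_id, t, doy, lon, lat`` (``gap`` optional).
    Rows are sorted by time within each seal; longitudes are normalized to
    [-180, 180).  Non-monotone time within a seal raises a ``ValueError``
    naming the seal.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} is missing column(s) {missing}")
    if "gap" not in df.columns:
        df["gap"] = 0
    tracks = []
    for seal_id, grp in df.groupby("seal_id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        if grp["t"].duplicated().any():
            raise ValueError(f"non-monotone time (duplicate t) in track for seal {seal_id}")
        tracks.append(
            Track(
                seal_id=str(seal_id),
                t=grp["t"].to_numpy(),
                doy=grp["doy"].to_numpy(),
                lon=grp["lon"].to_numpy(),
                lat=grp["lat"].to_numpy(),
                gap=grp["gap"].to_numpy().astype(bool),
            )
        )
    return tracks


def write_tracks(tracks: Iterable[Track], path) -> None:
    pd.concat([tr.to_frame() for tr in tracks], ignore_index=True).to_csv(path, index=False)


def read_seal_meta(path) -> list[SealMeta]:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing column(s) {missing}")
    return [
        SealMeta(
            seal_id=str(r.seal_id),
            sex=str(r.sex),
            standard_length=float(r.standard_length_m),
            departure_doy=int(r.departure_doy),
            colony_lon=float(r.colony_lon),
            colony_lat=float(r.colony_lat),
        )
        for r in df.itertuples()
    ]


def write_seal_meta(metas: Iterable[SealMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "seal_id": m.seal_id,
                "sex": m.sex,
                "standard_length_m": m.standard_length,
                "departure_doy": m.departure_doy,
                "colony_lon": m.colony_lon,
                "colony_lat": m.colony_lat,
            }
            for m in metas
        ]
    ).to_csv(path, index=False)


def regularize_daily(
    raw: Sequence[tuple[float, float, float]],
    seal_id: str = "seal",
    departure_doy: int = 1,
    max_gap_days: float = MAX_GAP_DAYS,
) -> Track:
    """Reduce irregular fixes to one location per day by linear interpolation.

    ``raw`` holds (t_hours, lon, lat) tuples with strictly increasing times.
    Positions are interpolated at integer days from the first fix, treating
    lon/lat as locally planar; interpolation across the antimeridian takes
    the short way round.  Days that fall inside a fix gap longer than
    ``max_gap_days`` are kept but flagged so downstream statistics can skip
    them.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("raw fixes must be (t_hours, lon, lat) triples")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 fixes to regularize a track")
    t_days = arr[:, 0] / 24.0
    if np.any(np.diff(t_days) <= 0):
        raise ValueError("fix times must be strictly increasing")
    # unwrap longitude so interpolation crosses the antimeridian the short way
    lon_unwrapped = np.degrees(np.unwrap(np.radians(normalize_lon(arr[:, 1]))))
    lat = arr[:, 2]

    n_days = int(math.floor(t_days[-1] - t_days[0])) + 1
    day_t = t_days[0] + np.arange(n_days)
    lon_i = np.interp(day_t, t_days, lon_unwrapped)
    lat_i = np.interp(day_t, t_days, lat)

    # flag days strictly inside a fix gap longer than max_gap_days
    right = np.searchsorted(t_days, day_t, side="left")
    right = np.clip(right, 1, len(t_days) - 1)
    gap_len = t_days[right] - t_days[right - 1]
    on_fix = np.min(np.abs(day_t[:, None] - t_days[None, :]), axis=1) < 1e-9
    gap_flag = (gap_len > max_gap_days) & ~on_fix

    t_out = np.arange(n_days, dtype=float)
    return Track(
        seal_id=seal_id,
        t=t_out,
        doy=wrap_doy(departure_doy + t_out),
        lon=normalize_lon(lon_i),
        lat=lat_i,
        gap=gap_flag,
    )


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def max_distance_from_colony(track: Track, colony_lon: float, colony_lat: float) -> float:
    """Maximum great-circle distance of any (non-gap) daily position from the colony."""
    keep = ~track.gap
    if not np.any(keep):
        raise ValueError(f"track for seal {track.seal_id} has no usable positions")
    d = great_circle_km(track.lon[keep], track.lat[keep], colony_lon, colony_lat)
    return float(np.max(d))


@dataclass
class RasterGrid:
    """A regular lon/lat raster with bit-reproducible nearest-cell lookup."""

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    values: np.ndarray  # shape (len(lat_axis), len(lon_axis))
    kind: str

    def __post_init__(self):
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in RASTER_KINDS:
            raise ValueError(f"unknown raster kind {self.kind!r}")
        for name, ax in (("lon_axis", self.lon_axis), ("lat_axis", self.lat_axis)):
            if len(ax) > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        if self.values.shape != (len(self.lat_axis), len(self.lon_axis)):
            raise ValueError("values must have shape (n_lat, n_lon)")
        if self.kind == "ice_concentration_fraction":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("ice concentration must lie in [0, 1]")

    def _nearest_index(self, axis: np.ndarray, x: np.ndarray) -> np.ndarray:
        # argmin of |axis - x|; exact distance ties resolve to the lower index
        # because argmin returns the first minimum of an ascending scan.
        asc = axis if axis[0] <= axis[-1] else axis[::-1]
        idx = np.abs(asc[None, :] - np.atleast_1d(x)[:, None]).argmin(axis=1)
        if axis[0] > axis[-1]:
            idx = len(axis) - 1 - idx
        return idx

    def in_bounds(self, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon_lo, lon_hi = min(self.lon_axis[0], self.lon_axis[-1]), max(self.lon_axis[0], self.lon_axis[-1])
        lat_lo, lat_hi = min(self.lat_axis[0], self.lat_axis[-1]), max(self.lat_axis[0], self.lat_axis[-1])
        return (lon >= lon_lo) & (lon <= lon_hi) & (lat >= lat_lo) & (lat <= lat_hi)

    def lookup(self, lon: float, lat: float) -> float:
        """Nearest-cell value at (lon, lat); raises on out-of-bounds points."""
        if not bool(self.in_bounds(lon, lat)[0]):
            raise ValueError(f"point (lon={lon}, lat={lat}) is outside the {self.kind} grid")
        i = self._nearest_index(self.lat_axis, np.asarray([lat]))[0]
        j = self._nearest_index(self.lon_axis, np.asarray([lon]))[0]
        return float(self.values[i, j])

    def lookup_many(self, lon, lat) -> np.ndarray:
        """Vectorized nearest-cell lookup; out-of-bounds points yield NaN."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ok = self.in_bounds(lon, lat)
        out = np.full(lon.shape, np.nan)
        if np.any(ok):
            i = self._nearest_index(self.lat_axis, lat[ok])
            j = self._nearest_index(self.lon_axis, lon[ok])
            out[ok] = self.values[i, j]
        return out


class IceSeries:
    """Daily sea-ice concentration grids keyed by calendar day-of-year."""

    def __init__(self, grids: Mapping[int, RasterGrid]):
        if not grids:
            raise ValueError("IceSeries needs at least one daily grid")
        first = next(iter(grids.values()))
        for g in grids.values():
            if g.kind != "ice_concentration_fraction":
                raise ValueError("IceSeries grids must have kind ice_concentration_fraction")
            if not (np.array_equal(g.lon_axis, first.lon_axis) and np.array_equal(g.lat_axis, first.lat_axis)):
                raise ValueError("all IceSeries grids must share axes")
        self.grids = dict(grids)

    def __getitem__(self, doy: int) -> RasterGrid:
        return self.grids[int(wrap_doy(doy))]

    def concentration(self, lon, lat, doy) -> np.ndarray:
        """Concentration at positions on given days; NaN outside the grid."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        doy = np.atleast_1d(np.asarray(doy))
        out = np.full(lon.shape, np.nan)
        for d in np.unique(wrap_doy(np.round(doy).astype(int))):
            sel = wrap_doy(np.round(doy).astype(int)) == d
            out[sel] = self[int(d)].lookup_many(lon[sel], lat[sel])
        return out


# --- NetCDF I/O (classic format via the scipy backend) ---------------------

def write_raster(grid: RasterGrid, path) -> None:
    da = xr.DataArray(
        grid.values,
        coords={"lat": grid.lat_axis, "lon": grid.lon_axis},
        dims=("lat", "lon"),
        name="values",
        attrs={"kind": grid.kind},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_raster(path) -> RasterGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds["values"]
        return RasterGrid(
            lon_axis=da["lon"].values.copy(),
            lat_axis=da["lat"].values.copy(),
            values=da.values.copy(),
            kind=str(da.attrs["kind"]),
        )


def write_ice_series(series: IceSeries, path) -> None:
    doys = sorted(series.grids)
    first = series.grids[doys[0]]
    cube = np.stack([series.grids[d].values for d in doys])
    da = xr.DataArray(
        cube,
        coords={"doy": doys, "lat": first.lat_axis, "lon": first.lon_axis},
        dims=("doy", "lat", "lon"),
        name="ice_concentration",
        attrs={"kind": "ice_concentration_fraction"},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_ice_series(path) -> IceSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds["ice_concentration"]
        lon = da["lon"].values.copy()
        lat = da["lat"].values.copy()
        grids = {
            int(d): RasterGrid(lon, lat, da.sel(doy=d).values.copy(), "ice_concentration_fraction")
            for d in da["doy"].values
        }
    return IceSeries(grids)
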