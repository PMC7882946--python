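"""Fully synthetic biologging study generator.

Emulates the four inputs the analysis consumes — bathymetry, a daily sea-ice
season, a seal population with tracks, and abstracted dive records — with
the statistical structure the pipeline assumes:

* a colony island on a shallow sub-Antarctic plateau, a circum-Antarctic
  shelf band, and deep basins east and west of the 70E meridian, so all four
  habitat labels are realizable;
* a sinusoidally advancing/retreating ice edge, northernmost in austral
  winter;
* sex-specific habitat preference, stage-varying movement (directed transit
  legs with high move persistence, area-restricted search with low
  persistence inside the preferred habitat), and mid-trip haul-out episodes;
* benthic/pelagic/drift dive structure tied to a latent body-condition
  (drift-rate) trajectory that starts negative (lean, post-molt) and rises
  toward a plateau.

Every generator is deterministic under a fixed :class:`SimConfig.seed`, and
the latent truth (per-day persistence, behavioural mode, preferred habitat,
drift rate, haul-out episodes) is exported alongside the data for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dives import DiveRecord, write_dives
from .geo import (
    KM_PER_DEG,
    IceSeries,
    RasterGrid,
    SealMeta,
    Track,
    great_circle_km,
    normalize_lon,
    wrap_doy,
    write_ice_series,
    write_raster,
    write_seal_meta,
    write_tracks,
)

HABITAT_KEYS = ("ANT_SHELF", "KERG_PLATEAU", "OCEANIC_EAST", "OCEANIC_WEST")


def _default_preference():
    # stage-1 dominant-habitat proportions observed in this population
    return {
        "male": {"ANT_SHELF": 0.55, "KERG_PLATEAU": 0.29, "OCEANIC_EAST": 0.14, "OCEANIC_WEST": 0.02},
        "female": {"ANT_SHELF": 0.04, "KERG_PLATEAU": 0.10, "OCEANIC_EAST": 0.50, "OCEANIC_WEST": 0.36},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study (defaults emulate the real cohort)."""

    n_females: int = 102
    n_males: int = 85
    seed: int = 0

    # trips
    trip_length_days: dict = field(default_factory=lambda: {"female": 240.0, "male": 300.0})
    trip_length_sd_days: float = 30.0
    min_trip_days: float = 150.0
    departure_doy_mean: dict = field(default_factory=lambda: {"female": 38.0, "male": 17.0})
    departure_doy_sd: float = 12.0
    length_mean: dict = field(default_factory=lambda: {"female": 2.33, "male": 2.37})
    length_sd: float = 0.18

    # movement
    habitat_preference: dict = field(default_factory=_default_preference)
    gamma_transit: float = 0.9
    gamma_forage: dict = field(default_factory=lambda: {"shelf": 0.35, "oceanic": 0.75})
    step_speed_km: float = 90.0
    step_sd_km: float = 16.0
    forage_attraction_km: float = 150.0

    # dives
    dives_per_day: float = 15.0
    benthic_prob: dict = field(
        default_factory=lambda: {
            ("male", "ANT_SHELF"): 0.40,
            ("male", "KERG_PLATEAU"): 0.30,
            ("female", "ANT_SHELF"): 0.10,
            ("female", "KERG_PLATEAU"): 0.05,
        }
    )
    drift_dive_fraction: float = 0.2
    drift_start_rate: float = -0.25      # m/s at departure (lean seal sinks)
    drift_rise_per_day: float = 0.0025   # daily lipid-gain rate, stage-1 slope
    drift_plateau_day: float = 90.0
    drift_ceiling_rate: float = -0.03
    drift_noise_sd: float = 0.02

    # haul-outs
    haulout_prob: dict = field(default_factory=lambda: {"female": 0.09, "male": 0.83})
    haulout_start_mean: dict = field(
        default_factory=lambda: {"ANT_SHELF": 150.0, "KERG_PLATEAU": 105.0,
                                 "OCEANIC_EAST": 110.0, "OCEANIC_WEST": 110.0}
    )
    haulout_start_sd: float = 25.0
    haulout_duration_range: tuple = (5, 20)

    # ice season
    ice_edge_north: float = -56.0   # winter maximum of the 15% contour
    ice_edge_south: float = -69.5   # summer minimum
    ice_peak_doy: int = 258         # mid-September maximum extent
    ice_ramp_deg: float = 1.5
    ice_conc: float = 0.8

    # geography
    colony: tuple = (70.2, -49.3)
    grid_lon: tuple = (40.0, 110.0, 0.5)
    grid_lat: tuple = (-72.0, -44.0, 0.5)

    def validate(self) -> None:
        for sex, prefs in self.habitat_preference.items():
            vals = np.array([prefs[h] for h in HABITAT_KEYS])
            if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"habitat_preference[{sex!r}] must be a probability vector")
        for p in self.haulout_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("haulout probabilities must lie in [0, 1]")


#: foraging target point for each habitat (lon, lat)
HABITAT_TARGETS = {
    "ANT_SHELF": (92.0, -67.5),
    "KERG_PLATEAU": (73.0, -54.0),
    "OCEANIC_EAST": (95.0, -57.5),
    "OCEANIC_WEST": (50.0, -57.5),
}


def _axes(config: SimConfig):
    lo, hi, step = config.grid_lon
    lon = np.arange(lo, hi + step / 2, step)
    lo, hi, step = config.grid_lat
    lat = np.arange(lo, hi + step / 2, step)
    return lon, lat


def make_bathymetry(config: SimConfig) -> RasterGrid:
    """Deterministic bathymetry with all four habitats realizable.

    Layout: deep (~3800 m) basins everywhere, a shallow (600 m) plateau
    around the colony north of 60S, a circum-Antarctic shelf band (600 m)
    south of 65.5S, land along the southern edge (the continent) and a small
    island at the colony.
    """
    lon, lat = _axes(config)
    lon_g, lat_g = np.meshgrid(lon, lat)
    depth = 3800.0 - 150.0 * np.cos(np.radians(lon_g * 3)) * np.sin(np.radians(lat_g * 2))

    # Antarctic continental shelf band and the continent
    shelf = (lat_g <= -65.5) & (lat_g > -70.75)
    depth[shelf] = 600.0 + 40.0 * np.sin(np.radians(lon_g[shelf] * 5))
    depth[lat_g <= -70.75] = -200.0

    # Kerguelen Plateau (kept north of 60S so its cells classify as plateau)
    plateau = (lon_g >= 65.0) & (lon_g <= 80.0) & (lat_g >= -59.0) & (lat_g <= -46.0)
    depth[plateau] = 600.0 + 30.0 * np.cos(np.radians(lat_g[plateau] * 7))

    # colony island
    c_lon, c_lat = config.colony
    island = (np.abs(lon_g - c_lon) <= 0.7) & (np.abs(lat_g - c_lat) <= 0.7)
    depth[island] = -50.0

    return RasterGrid(lon, lat, depth, "bathymetry_depth_m")


def ice_edge_latitude(config: SimConfig, doy) -> np.ndarray:
    """Southernmost latitude of the 15% ice contour as a function of day-of-year."""
    doy = np.asarray(doy, dtype=float)
    mean = 0.5 * (config.ice_edge_north + config.ice_edge_south)
    amp = 0.5 * (config.ice_edge_north - config.ice_edge_south)
    return mean + amp * np.cos(2.0 * np.pi * (doy - config.ice_peak_doy) / 365.0)


def make_ice_series(config: SimConfig) -> IceSeries:
    """Daily ice grids: ~0.8 concentration south of the seasonal edge, 0 north.

    The transition ramps linearly over ``ice_ramp_deg`` degrees of latitude;
    the edge latitude follows a sinusoid peaking (northernmost) in austral
    winter.
    """
    lon, lat = _axes(config)
    grids = {}
    for doy in range(1, 366):
        edge = float(ice_edge_latitude(config, doy))
        ramp = np.clip((edge - lat) / config.ice_ramp_deg, 0.0, 1.0)
        vals = np.repeat((config.ice_conc * ramp)[:, None], len(lon), axis=1)
        grids[doy] = RasterGrid(lon, lat, vals, "ice_concentration_fraction")
    return IceSeries(grids)


def _km_to_deg(dx_km, dy_km, lat):
    dlon = dx_km / (KM_PER_DEG * max(np.cos(np.radians(lat)), 0.05))
    dlat = dy_km / KM_PER_DEG
    return dlon, dlat


def _unit_towards(lon, lat, target):
    dx = (normalize_lon(target[0] - lon)) * KM_PER_DEG * np.cos(np.radians(lat))
    dy = (target[1] - lat) * KM_PER_DEG
    norm = float(np.hypot(dx, dy))
    if norm < 1e-9:
        return np.zeros(2)
    return np.array([dx, dy]) / norm


def ar_displacement_series(
    gammas, rng: np.random.Generator, step_sd_km: float = 16.0, initial: tuple = (90.0, 0.0)
) -> np.ndarray:
    """Pure first-difference autoregression d_t = gamma_t d_{t-1} + eps_t.

    The movement kernel underlying :func:`simulate_track`, without the
    navigation (steering) term: useful for testing the persistence
    estimator against known gamma at equal step variance.
    """
    gammas = np.asarray(gammas, dtype=float)
    d = np.zeros((len(gammas) + 1, 2))
    d[0] = initial
    for i, g in enumerate(gammas):
        d[i + 1] = g * d[i] + rng.normal(0.0, step_sd_km, 2)
    return d


def draw_population(config: SimConfig, rng: np.random.Generator) -> list[SealMeta]:
    """Draw seal metadata (ids, sexes, lengths, departure days)."""
    metas = []
    for sex, n in (("female", config.n_females), ("male", config.n_males)):
        for i in range(n):
            length = float(np.clip(rng.normal(config.length_mean[sex], config.length_sd), 1.63, 3.18))
            dep = int(np.clip(round(rng.normal(config.departure_doy_mean[sex], config.departure_doy_sd)), 1, 366))
            metas.append(
                SealMeta(
                    seal_id=f"{sex[0]}{i + 1:03d}",
                    sex=sex,
                    standard_length=length,
                    departure_doy=dep,
                    colony_lon=config.colony[0],
                    colony_lat=config.colony[1],
                )
            )
    return metas


def simulate_track(
    meta: SealMeta,
    config: SimConfig,
    rng: np.random.Generator,
    bathy: RasterGrid | None = None,
) -> tuple[Track, pd.DataFrame]:
    """Simulate one daily track plus its latent record.

    Daily displacements follow the first-difference autoregression
    d_t = gamma_t d_{t-1} + eps_t, with innovations steered toward the
    seal's current target during transit legs; gamma_t is high in transit,
    low during area-restricted search in the preferred habitat.  Seals that
    draw a mid-year haul out return to the colony, sit at the coast for a
    drawn number of days, then head back out.

    Returns (track, truth) where truth has one row per day with columns
    t, gamma (NaN on haul-out days), mode, target_habitat, drift_rate,
    hauled.
    """
    config.validate()
    sex = meta.sex
    prefs = config.habitat_preference[sex]
    p = np.array([prefs[h] for h in HABITAT_KEYS])
    habitat = rng.choice(HABITAT_KEYS, p=p / p.sum())
    target = HABITAT_TARGETS[habitat]
    target = (target[0] + rng.uniform(-3, 3), target[1] + rng.uniform(-1.5, 1.5))
    shelf_class = "shelf" if habitat in ("ANT_SHELF", "KERG_PLATEAU") else "oceanic"
    gamma_forage = config.gamma_forage[shelf_class]

    L = int(np.clip(rng.normal(config.trip_length_days[sex], config.trip_length_sd_days),
                    config.min_trip_days, 320))
    does_haulout = rng.random() < config.haulout_prob[sex]
    h_start = float(np.clip(rng.normal(config.haulout_start_mean[habitat], config.haulout_start_sd), 45, L - 40)) \
        if does_haulout else np.inf
    h_dur = int(rng.integers(config.haulout_duration_range[0], config.haulout_duration_range[1] + 1))
    colony = (meta.colony_lon, meta.colony_lat)
    dist_target_colony = float(great_circle_km(target[0], target[1], colony[0], colony[1]))
    return_leg_start = h_start - dist_target_colony / config.step_speed_km - 3.0

    lon = np.empty(L)
    lat = np.empty(L)
    gamma_true = np.full(L, np.nan)
    mode = np.empty(L, dtype=object)
    hauled = np.zeros(L, dtype=bool)

    lon[0], lat[0] = colony[0], colony[1] - 1.2  # launch just offshore of the island
    mode[0] = "transit"
    state = "transit_out"
    d = config.step_speed_km * _unit_towards(lon[0], lat[0], target)
    hauled_days_left = 0
    lon_lo, lon_hi = config.grid_lon[0] + 0.5, config.grid_lon[1] - 0.5
    lat_lo, lat_hi = config.grid_lat[0] + 1.5, config.grid_lat[1] - 0.5

    for t in range(1, L):
        if state == "transit_out":
            if float(great_circle_km(lon[t - 1], lat[t - 1], target[0], target[1])) < 120.0:
                state = "forage"
        if state == "forage" and t >= return_leg_start and does_haulout and not np.any(hauled):
            state = "transit_home"
        if state == "transit_home":
            if float(great_circle_km(lon[t - 1], lat[t - 1], colony[0], colony[1])) < 80.0:
                state = "haulout"
                hauled_days_left = h_dur
        if state == "haulout" and hauled_days_left == 0:
            state = "transit_back"
            d = config.step_speed_km * _unit_towards(lon[t - 1], lat[t - 1], target)
        if state == "transit_back":
            if float(great_circle_km(lon[t - 1], lat[t - 1], target[0], target[1])) < 120.0:
                state = "forage"

        if state == "haulout":
            lon[t], lat[t] = colony
            gamma_true[t] = np.nan
            mode[t] = "haulout"
            hauled[t] = True
            hauled_days_left -= 1
            d = np.zeros(2)
            continue

        if state in ("transit_out", "transit_home", "transit_back"):
            g = config.gamma_transit
            goal = colony if state == "transit_home" else target
            drift = (1.0 - g) * config.step_speed_km * _unit_towards(lon[t - 1], lat[t - 1], goal)
            mode[t] = "transit"
        else:
            g = gamma_forage
            # weak attraction keeps the seal inside its habitat patch
            dist = float(great_circle_km(lon[t - 1], lat[t - 1], target[0], target[1]))
            pull = 0.4 * config.step_speed_km if dist > config.forage_attraction_km else 0.0
            drift = (1.0 - g) * pull * _unit_towards(lon[t - 1], lat[t - 1], target)
            mode[t] = "forage"

        eps = rng.normal(0.0, config.step_sd_km, size=2)
        d = g * d + drift + eps
        gamma_true[t] = g

        dlon, dlat = _km_to_deg(d[0], d[1], lat[t - 1])
        new_lon = lon[t - 1] + dlon
        new_lat = lat[t - 1] + dlat
        # reflect off the domain walls and the continent
        if new_lat < lat_lo or new_lat > lat_hi:
            d[1] = -d[1]
            new_lat = np.clip(new_lat, lat_lo, lat_hi)
        if new_lon < lon_lo or new_lon > lon_hi:
            d[0] = -d[0]
            new_lon = np.clip(new_lon, lon_lo, lon_hi)
        if bathy is not None and mode[t] == "forage":
            db = bathy.lookup_many(np.array([new_lon]), np.array([new_lat]))[0]
            if np.isfinite(db) and db <= 0:  # stepped onto land: bounce back
                d = -0.5 * d
                new_lon, new_lat = lon[t - 1], lat[t - 1]
        lon[t], lat[t] = new_lon, new_lat

    t_arr = np.arange(L, dtype=float)
    drift_rate = latent_drift_rate(config, t_arr)
    track = Track(
        seal_id=meta.seal_id,
        t=t_arr,
        doy=wrap_doy(meta.departure_doy + t_arr),
        lon=lon,
        lat=lat,
    )
    truth = pd.DataFrame(
        {
            "seal_id": meta.seal_id,
            "t": t_arr,
            "gamma": gamma_true,
            "mode": mode,
            "target_habitat": habitat,
            "drift_rate": drift_rate,
            "hauled": hauled,
        }
    )
    return track, truth


def latent_drift_rate(config: SimConfig, day) -> np.ndarray:
    """Latent body-condition (drift-rate) trajectory, m/s, by day of trip.

    Piecewise linear: starts negative (lean post-molt seal), rises at
    ``drift_rise_per_day`` until ``drift_plateau_day``, then plateaus, never
    exceeding ``drift_ceiling_rate``.
    """
    day = np.asarray(day, dtype=float)
    raw = config.drift_start_rate + config.drift_rise_per_day * np.minimum(day, config.drift_plateau_day)
    return np.minimum(raw, config.drift_ceiling_rate)


def _drift_dive(seal_id, t, rate, start_depth, rng) -> DiveRecord:
    """A dive whose long middle segment drifts at ``rate`` m/s."""
    duration = float(rng.uniform(1300, 1800))
    f = (0.12, 0.2, 0.8, 0.88)
    span = f[2] - f[1]
    d1 = start_depth * rng.uniform(0.85, 0.95)
    d2 = start_depth
    d3 = max(d2 - rate * span * duration, 1.0)  # negative rate -> deeper
    d4 = d3 * 0.4
    depths = (d1, d2, d3, d4)
    return DiveRecord(seal_id, t, duration, max(depths) + 0.5, f, depths)


def _shaped_dive(seal_id, t, max_depth, rng) -> DiveRecord:
    """A U-shaped foraging dive with no qualifying drift segment."""
    duration = float(rng.uniform(900, 1500))
    f = (0.18, 0.4, 0.62, 0.84)
    d = (0.85 * max_depth, max_depth, max_depth, 0.7 * max_depth)
    return DiveRecord(seal_id, t, duration, max_depth, f, d)


def simulate_dives(
    track: Track,
    bathy: RasterGrid,
    config: SimConfig,
    rng: np.random.Generator,
    sex: str,
    truth: pd.DataFrame,
) -> list[DiveRecord]:
    """Simulate the day's transmitted dives along one track.

    Over shelf cells a dive is benthic with probability
    ``benthic_prob[(sex, habitat)]`` (max depth within 20 m of the
    seafloor), otherwise pelagic (max depth at least 21 m above the floor).
    A fraction of dives are drift dives whose middle segment moves at the
    seal's latent drift rate for that day (plus noise).  No dives are
    produced on haul-out days or over land.
    """
    from .habitats import classify_locations  # local import to avoid cycle

    dives: list[DiveRecord] = []
    hauled = truth.set_index("t")["hauled"] if "hauled" in truth.columns else None
    rate_of_day = truth.set_index("t")["drift_rate"]
    floors = bathy.lookup_many(track.lon, track.lat)
    labels = classify_locations(track.lat, track.lon, floors)
    for i, t in enumerate(track.t):
        if hauled is not None and bool(hauled.get(t, False)):
            continue
        floor = floors[i]
        if not np.isfinite(floor) or floor <= 45.0:
            continue
        n = int(rng.poisson(config.dives_per_day))
        if n == 0:
            continue
        habitat = labels[i].value
        p_benthic = config.benthic_prob.get((sex, habitat), 0.0)
        r_day = float(rate_of_day.get(t, config.drift_ceiling_rate))
        for _ in range(n):
            t_dive = float(t) + float(rng.uniform(0, 0.95))
            if floor > 320.0 and rng.random() < config.drift_dive_fraction:
                rate = r_day + float(rng.normal(0.0, config.drift_noise_sd))
                rate = float(np.clip(rate, -0.55, 0.55))
                dv = _drift_dive(track.seal_id, t_dive, rate, 260.0, rng)
                if dv.max_depth <= floor - 25.0:  # keep drift dives off the seafloor
                    dives.append(dv)
                    continue
            if rng.random() < p_benthic:
                max_depth = floor - float(rng.uniform(0.0, 12.0))
                dives.append(_shaped_dive(track.seal_id, t_dive, max_depth, rng))
            else:
                hi = min(600.0, floor - 25.0)
                max_depth = float(rng.uniform(min(150.0, hi - 10.0), hi))
                dives.append(_shaped_dive(track.seal_id, t_dive, max_depth, rng))
    return dives


def simulate_occupancy_table(
    rng: np.random.Generator,
    n_females: int = 20,
    n_males: int = 20,
    n_days: int = 150,
    base_logit: float = -2.0,
    sex_effect: float = 0.0,
    stage_effect: float = 0.0,
    interaction: float = 0.0,
    seal_sd: float = 0.3,
) -> pd.DataFrame:
    """Binary sea-ice occupancy table with controllable covariate effects.

    Generates one row per seal-day with a logistic probability
    ``base + sex_effect*[male] + stage_effect*(stage-1)
    + interaction*[male]*(stage-1) + u_seal`` where u_seal is a per-seal
    normal intercept.  Days split evenly into stages 1-3.  Used for
    model-selection recovery tests: with ``interaction`` nonzero the
    sex-by-stage interaction model should win; with all effects zero the
    null should.
    """
    rows = []
    for s in range(n_females + n_males):
        sex = "female" if s < n_females else "male"
        is_male = 1.0 if sex == "male" else 0.0
        u = rng.normal(0.0, seal_sd)
        for d in range(n_days):
            stage = 1 + min(3 * d // n_days, 2)
            logit = (
                base_logit
                + sex_effect * is_male
                + stage_effect * (stage - 1)
                + interaction * is_male * (stage - 1)
                + u
            )
            p = 1.0 / (1.0 + np.exp(-logit))
            rows.append(
                {"seal_id": f"s{s:03d}", "sex": sex, "stage": stage,
                 "in_ice": float(rng.random() < p)}
            )
    return pd.DataFrame(rows)


@dataclass
class SimStudy:
    """A complete synthetic study: inputs plus exported generative truth."""

    config: SimConfig
    metas: list
    bathy: RasterGrid
    ice: IceSeries
    tracks: list
    dives: list
    truth: pd.DataFrame  # per seal-day latent record


def simulate_study(config: SimConfig, with_dives: bool = True, with_ice: bool = True) -> SimStudy:
    """Generate the whole study deterministically from ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    pop_seq, *seal_seqs = root.spawn(1 + config.n_females + config.n_males)
    rng_pop = np.random.default_rng(pop_seq)
    metas = draw_population(config, rng_pop)
    bathy = make_bathymetry(config)
    ice = make_ice_series(config) if with_ice else None

    tracks, truths, dives = [], [], []
    for meta, seq in zip(metas, seal_seqs):
        rng = np.random.default_rng(seq)
        track, truth = simulate_track(meta, config, rng, bathy)
        tracks.append(track)
        truths.append(truth)
        if with_dives:
            dives.extend(simulate_dives(track, bathy, config, rng, meta.sex, truth))
    return SimStudy(
        config=config,
        metas=metas,
        bathy=bathy,
        ice=ice,
        tracks=tracks,
        dives=dives,
        truth=pd.concat(truths, ignore_index=True),
    )


def write_study(study: SimStudy, outdir) -> None:
    """Write the four input files plus the truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_seal_meta(study.metas, outdir / "meta.csv")
    write_tracks(study.tracks, outdir / "tracks.csv")
    write_dives(study.dives, outdir / "dives.csv")
    write_raster(study.bathy, outdir / "bathymetry.nc")
    if study.ice is not None:
        write_ice_series(study.ice, outdir / "ice.nc")
    study.truth.to_csv(outdir / "truth.csv", index=False)
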