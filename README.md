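# mirounga

Habitat-partitioning analysis for southern elephant seal (*Mirounga
leonina*) biologging data: a tested, reusable pipeline from raw
track and dive records to habitat occupancy by sex and trip stage,
haul-out phenology, foraging-behaviour metrics and body-condition
trajectories, with AICc-ranked model comparisons.

At Iles Kerguelen, similarly sized adult female and subadult male
elephant seals partition the Southern Ocean sharply: males
predominantly use shelf waters (the nearby Kerguelen Plateau or the
distant Antarctic continental shelf), while females use deep oceanic
waters east and west of the 70°E meridian. This package implements
the full analysis chain needed to quantify that partitioning from
CTD-SRDL satellite-tag data, and bundles a synthetic-data generator
so every stage can be exercised and validated without any data
download.

## What the pipeline computes

- **Habitat masks** — four a-priori habitats from bathymetry and
  latitude: Antarctic shelf (0–2000 m, south of 60°S), Kerguelen
  Plateau (0–1000 m, north of 60°S), Oceanic East/West (>1000 m,
  split at 70°E); plus sea-ice membership (concentration > 15% at
  that location on that day).
- **Trip stages and dominant habitat** — three 66-day stage windows
  per sex (males: days 21–87, 146–212, 213–279; females: 21–87,
  88–154, 155–221); per stage, the habitat with the greatest
  percentage of classified days is the seal's *dominant habitat*.
- **Mid-year haul-outs** — runs of > 4 consecutive days within 4 km
  of the coast after ≥ 30 days at sea, with daily haul-out
  percentages for seals tracked ≥ 150 days.
- **Move persistence** — a continuous 0–1 index γ_t of directional
  and speed autocorrelation, estimated from the first-difference
  autoregression d_t = γ_t·d_{t−1} + ε_t by penalized weighted least
  squares with a logit-scale smoothness penalty (low γ = area-
  restricted search, high γ = directed travel).
- **Benthic diving and drift rate** — dives classified benthic when
  the maximum depth is within 20 m of the seafloor; drift dives
  detected from 4-point abstracted profiles by explicit segment
  filters, giving a daily drift rate (m/s) whose sign and trend track
  buoyancy and hence lipid store.
- **Model comparison** — candidate (generalized) linear models over
  sex, habitat and stage with ridge-shrunk per-seal intercepts,
  ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with Akaike weights
  w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2) and the rule of parsimony
  (fewest parameters among models with ΔAICc < 2).

## Worked example

```python
import mirounga as mg

# a small synthetic study: 6 females + 6 males with sex-specific
# habitat preference, drift dives and a seasonal ice edge
cfg = mg.SimConfig(n_females=6, n_males=6, seed=101)
study = mg.simulate_study(cfg)

occ = mg.compute_occupancies(study.tracks, study.metas, study.bathy)
stage1 = [o for o in occ if o.stage == 1 and o.n_days_classified > 0]
for o in stage1[:3]:
    print(o.seal_id, o.dominant.value, round(max(o.percentages.values()), 1))
```

prints, for example:

```
f001 OCEANIC_WEST 100.0
f002 OCEANIC_WEST 100.0
f003 OCEANIC_EAST 100.0
```

i.e. each female's stage-1 dominant habitat and the percentage of
classified days she spent there. Ranking the published sea-ice
candidate models from their log-likelihoods:

```python
from mirounga.stats import score_model, rank_models
ranked = rank_models([
    score_model("sex + stage + sex:stage", -6470.1, 7, 100_000),
    score_model("null", -6898.3, 2, 100_000),
])
print(round(ranked[0].aicc, 1), round(ranked[1].delta, 1))
# 12954.2 846.4
```

The same machinery is exposed on the command line:

```bash
mirounga simulate --seed 42 --out data/
mirounga process  --data data/ --out analysis.csv
mirounga report   --data data/ --analysis analysis.csv --out report/
```

`report/` then holds the dominant-habitat, haul-out, sea-ice and
behaviour summary tables as CSV.

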