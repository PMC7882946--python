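"""AICc ranking, Akaike weights, parsimony selection, candidate fits, summaries.

Candidate models for each response (sea-ice occupancy, benthic diving, move
persistence, drift rate) are compared with the small-sample corrected
information criterion

    AICc = -2 logLik + 2k + 2k(k+1) / (n - k - 1),

ranked by Delta AICc (difference from the best candidate) and weighted by
the normalized evidence w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2).
Where several candidates rank highly (Delta < 2), the one with the fewest
parameters wins under the rule of parsimony.

Fits are comparative by construction: every candidate is fitted on the same
rows with the same machinery (per-seal intercepts shrunk by an identical
ridge penalty standing in for a random-intercept term), so AICc differences
are meaningful even though no claim is made of numerical equality with a
full REML mixed-model fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .habitats import SHELF_LABELS, Habitat, StageOccupancy

logger = logging.getLogger(__name__)

PARSIMONY_DELTA = 2.0
DEFAULT_RIDGE_TAU = 1.0
DEFAULT_SUBSAMPLE = 100_000
RESPONSE_FAMILY = {
    "in_ice": "binomial",
    "benthic": "binomial",
    "gamma": "gaussian_logit",
    "drift_rate": "gaussian",
}


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up to an integer (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelScore:
    label: str
    loglik: float
    k: int
    n: int
    aicc: float
    delta: float | None = None
    weight: float | None = None


def score_model(label: str, loglik: float, k: int, n: int) -> ModelScore:
    return ModelScore(label, loglik, k, n, aicc(loglik, k, n))


def rank_models(scores: Sequence[ModelScore]) -> list[ModelScore]:
    """Fill Delta AICc and Akaike weights; returns scores sorted best-first."""
    if not scores:
        raise ValueError("rank_models needs at least one candidate")
    best = min(s.aicc for s in scores)
    deltas = [s.aicc - best for s in scores]
    rel = np.exp(-0.5 * np.asarray(deltas))
    weights = rel / rel.sum()
    ranked = [
        replace(s, delta=d, weight=float(w))
        for s, d, w in zip(scores, deltas, weights)
    ]
    return sorted(ranked, key=lambda s: s.aicc)


def parsimony_select(ranked: Sequence[ModelScore], delta_max: float = PARSIMONY_DELTA) -> str:
    """Among candidates with Delta AICc < ``delta_max``, pick the fewest-parameter one.

    Ties on parameter count go to the smaller AICc.
    """
    if any(s.delta is None for s in ranked):
        ranked = rank_models(ranked)
    top = [s for s in ranked if s.delta < delta_max]
    return min(top, key=lambda s: (s.k, s.aicc)).label


# --- design matrices --------------------------------------------------------

def _dummies(df: pd.DataFrame, col: str) -> pd.DataFrame:
    d = pd.get_dummies(df[col].astype("category"), prefix=col, drop_first=True, dtype=float)
    return d


def build_design(df: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a formula over categorical covariates.

    ``formula`` is a '+'-separated list of terms: '1' (intercept only),
    main effects ('sex'), and ':'-interactions ('sex:stage').  Categorical
    levels are treatment-coded (first level dropped).
    """
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    cols = [pd.Series(1.0, index=df.index, name="(Intercept)")]
    for term in terms:
        if term == "1":
            continue
        parts = [p.strip() for p in term.split(":")]
        block = None
        for p in parts:
            if p not in df.columns:
                raise ValueError(f"covariate {p!r} not in table")
            dm = _dummies(df, p)
            if block is None:
                block = dm
            else:
                block = pd.DataFrame(
                    {
                        f"{c1}:{c2}": block[c1] * dm[c2]
                        for c1 in block.columns
                        for c2 in dm.columns
                    },
                    index=df.index,
                )
        if block is not None:
            cols.append(block)
    X = pd.concat(cols, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def _seal_dummies(df: pd.DataFrame) -> np.ndarray:
    codes = df["seal_id"].astype("category").cat.codes.to_numpy()
    Z = np.zeros((len(df), codes.max() + 1))
    Z[np.arange(len(df)), codes] = 1.0
    return Z


def _fit_penalized_logistic(X, Z, y, tau, max_iter=50, tol=1e-8):
    """IRLS for a logistic model with ridge-penalized per-seal intercepts.

    Fixed effects are unpenalized; seal-effect coefficients carry an L2
    penalty tau/2 * ||u||^2 standing in for a random-intercept term with
    prior variance 1/tau on the logit scale.  Returns the joint
    log-likelihood at the fit: binomial data likelihood minus the
    shrinkage term, so candidates that push between-seal structure into
    the seal effects pay for it.
    """
    M = np.hstack([X, Z])
    p = X.shape[1]
    pen = np.concatenate([np.zeros(p), np.full(Z.shape[1], tau)])
    c = np.zeros(M.shape[1])
    ll_old = -np.inf
    ll = 0.0
    for _ in range(max_iter):
        eta = np.clip(M @ c, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = M.T @ (y - mu) - pen * c
        H = (M.T * w) @ M
        H[np.diag_indices_from(H)] += pen + 1e-10
        c = c + np.linalg.solve(H, grad)
        eta = np.clip(M @ c, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(
            np.sum(y * np.log(np.maximum(mu, 1e-12)) + (1 - y) * np.log(np.maximum(1 - mu, 1e-12)))
            - 0.5 * np.sum(pen * c * c)
        )
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    return ll


def _fit_penalized_gaussian(X, Z, y, tau):
    """Ridge-penalized least squares analogue; returns the joint logLik.

    The response is standardized to unit variance inside the fit so the
    seal-effect prior (variance 1/tau) has a consistent scale across
    responses; the standardization shifts every candidate's logLik by the
    same constant and cancels out of AICc differences.
    """
    sd = float(np.std(y))
    ys = (y - float(np.mean(y))) / max(sd, 1e-12)
    M = np.hstack([X, Z])
    p = X.shape[1]
    pen = np.concatenate([np.zeros(p), np.full(Z.shape[1], tau)])
    A = M.T @ M
    A[np.diag_indices_from(A)] += pen + 1e-10
    c = np.linalg.solve(A, M.T @ ys)
    resid = ys - M @ c
    n = len(ys)
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0) - 0.5 * float(np.sum(pen * c * c))


def fit_candidates(
    table: pd.DataFrame,
    response: str,
    formulas: Sequence[str],
    tau: float = DEFAULT_RIDGE_TAU,
    subsample: int = DEFAULT_SUBSAMPLE,
    rng: np.random.Generator | None = None,
) -> list[ModelScore]:
    """Fit each candidate formula to ``table`` and return comparable scores.

    ``response`` is one of in_ice / benthic (binary, logistic) or gamma
    (logit-transformed Gaussian) / drift_rate (Gaussian).  All candidates
    share the same (optionally subsampled) rows and the same per-seal ridge
    term, so AICc values are comparable across the set.  k counts fixed
    effects plus variance terms (seal term; plus a residual variance for
    Gaussian responses).  Rank-deficient designs (e.g. duplicated
    covariates) are dropped with a logged warning.
    """
    family = RESPONSE_FAMILY.get(response)
    if family is None:
        raise ValueError(f"unknown response {response!r}")
    df = table.dropna(subset=[response]).reset_index(drop=True)
    if len(df) > subsample:
        rng = rng or np.random.default_rng(0)
        rows = rng.choice(len(df), size=subsample, replace=False)
        df = df.iloc[np.sort(rows)].reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    if family == "gaussian_logit":
        y = np.log(np.clip(y, 1e-6, 1 - 1e-6) / (1 - np.clip(y, 1e-6, 1 - 1e-6)))
    Z = _seal_dummies(df)
    n = len(df)
    scores = []
    for formula in formulas:
        X, names = build_design(df, formula)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.warning("dropping rank-deficient candidate %r", formula)
            continue
        if family == "binomial":
            ll = _fit_penalized_logistic(X, Z, y, tau)
            k = X.shape[1] + 1
        else:
            ll = _fit_penalized_gaussian(X, Z, y, tau)
            k = X.shape[1] + 2
        scores.append(score_model(formula, ll, k, n))
    return scores


# --- report tables ----------------------------------------------------------

def summarize(
    metas,
    occupancies: Sequence[StageOccupancy],
    events,
    eligible_ids: set,
    table: pd.DataFrame | None = None,
    max_distances: Mapping[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the report tables.

    Returns a dict with keys:

    * ``dominant``  — per sex x stage: seal counts and (half-up rounded)
      percentages per dominant habitat, plus a combined shelf percentage;
    * ``haulout``   — per sex: haul-out prevalence among eligible seals, and
      mean start day-of-year per stage-1 dominant habitat;
    * ``ice``       — per sex x stage: percent of classified seal-days in ice;
    * ``behavior``  — per sex x habitat x stage: mean percent-benthic, mean
      persistence, mean drift rate;
    * ``distance``  — per-seal maximum distance from the colony.

    Empty cells are emitted with count 0 and missing percentage.
    """
    sex_of = {m.seal_id: m.sex for m in metas}
    out: dict[str, pd.DataFrame] = {}

    occ = pd.DataFrame(
        [
            {
                "seal_id": o.seal_id,
                "sex": sex_of.get(o.seal_id),
                "stage": o.stage,
                "dominant": o.dominant.value if o.dominant else None,
                "tie": o.tie,
                "n_days_classified": o.n_days_classified,
            }
            for o in occupancies
            if o.n_days_classified > 0
        ]
    )
    rows = []
    if not occ.empty:
        for (sex, stage), grp in occ.groupby(["sex", "stage"]):
            n_tot = len(grp)
            shelf_n = int(grp["dominant"].isin([h.value for h in SHELF_LABELS]).sum())
            for h in Habitat:
                n_h = int((grp["dominant"] == h.value).sum())
                rows.append(
                    {
                        "sex": sex, "stage": stage, "habitat": h.value,
                        "n": n_h, "n_total": n_tot,
                        "percent": round_half_up(100.0 * n_h / n_tot),
                    }
                )
            rows.append(
                {
                    "sex": sex, "stage": stage, "habitat": "SHELF_COMBINED",
                    "n": shelf_n, "n_total": n_tot,
                    "percent": round_half_up(100.0 * shelf_n / n_tot),
                }
            )
    out["dominant"] = pd.DataFrame(rows, columns=["sex", "stage", "habitat", "n", "n_total", "percent"])

    ev = pd.DataFrame(
        [
            {"seal_id": e.seal_id, "start_day": e.start_day, "start_doy": e.start_doy,
             "duration_days": e.duration_days}
            for e in events
        ]
    )
    h_rows = []
    stage1_dom = occ[occ["stage"] == 1].set_index("seal_id")["dominant"] if not occ.empty else pd.Series(dtype=object)
    for sex in ("female", "male"):
        elig = [sid for sid in eligible_ids if sex_of.get(sid) == sex]
        with_event = [sid for sid in elig if not ev.empty and (ev["seal_id"] == sid).any()]
        pct = round_half_up(100.0 * len(with_event) / len(elig)) if elig else None
        h_rows.append(
            {"sex": sex, "habitat": "ALL", "n_eligible": len(elig),
             "n_with_haulout": len(with_event), "percent": pct, "mean_start_doy": np.nan}
        )
        if not ev.empty:
            sub = ev[ev["seal_id"].isin(elig)].copy()
            sub["dominant"] = sub["seal_id"].map(stage1_dom)
            for h, grp in sub.groupby("dominant"):
                h_rows.append(
                    {"sex": sex, "habitat": h, "n_eligible": len(elig),
                     "n_with_haulout": grp["seal_id"].nunique(), "percent": None,
                     "mean_start_doy": float(grp["start_doy"].mean())}
                )
    out["haulout"] = pd.DataFrame(h_rows)

    if table is not None and not table.empty and "in_ice" in table.columns:
        ice = (
            table.dropna(subset=["in_ice"])
            .groupby(["sex", "stage"])["in_ice"]
            .agg(n="size", percent_in_ice=lambda s: 100.0 * s.mean())
            .reset_index()
        )
        out["ice"] = ice
        beh = (
            table.groupby(["sex", "habitat", "stage"])
            .agg(
                n=("seal_id", "size"),
                mean_percent_benthic=("percent_benthic", "mean"),
                mean_gamma=("gamma", "mean"),
                mean_drift_rate=("drift_rate", "mean"),
            )
            .reset_index()
        )
        out["behavior"] = beh
    else:
        out["ice"] = pd.DataFrame(columns=["sex", "stage", "n", "percent_in_ice"])
        out["behavior"] = pd.DataFrame(
            columns=["sex", "habitat", "stage", "n", "mean_percent_benthic", "mean_gamma", "mean_drift_rate"]
        )

    if max_distances:
        out["distance"] = pd.DataFrame(
            [
                {"seal_id": sid, "sex": sex_of.get(sid), "max_distance_km": d}
                for sid, d in sorted(max_distances.items())
            ]
        )
    else:
        out["distance"] = pd.DataFrame(columns=["seal_id", "sex", "max_distance_km"])
    return out
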