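"""Spatial goodness-of-fit: observed system vs the simulated ensemble.

Three complementary checks, all judging the observed flow system against
the reference distribution the fitted model implies (the ensemble):

* **index envelopes** — does each observed spatial index fall inside the
  range (or a quantile band) of its simulated values, year by year;
* **Mahalanobis distances** — for each location and year, the
  covariance-weighted squared distance

      D^2 = (x - mu)' Sigma^{-1} (x - mu)

  between the observed inflow (or outflow) vector ``x`` and the mean
  ``mu`` and covariance ``Sigma`` of the corresponding simulated
  vectors.  D^2 accounts for dependence between corridors; values near
  zero mean the model reproduces the location's flow profile, large
  values localise misfit;
* **corridor checks** — per-corridor comparison of the observed flow
  with the simulated range over the years.

With a finite ensemble the sample covariance can be ill-conditioned or
singular, so ``Sigma`` is regularised by linear shrinkage toward its
diagonal, ``Sigma* = (1 - lam) Sigma + lam diag(Sigma)``, with the
analytic (Schafer–Strimmer) shrinkage intensity by default; a
pseudo-inverse is the last resort (warned).  Distances are reported per
year, never aggregated over time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .flow_data import FlowPanel, to_matrix
from .indices import INDEX_NAMES, index_series, ensemble_summary
from .simulate import Ensemble

__all__ = [
    "mahalanobis_d2",
    "analytic_shrinkage",
    "country_inflow_distance",
    "index_envelope",
    "corridor_check",
    "evaluate_system",
    "EvaluationReport",
]


# ---------------------------------------------------------------------------
# Mahalanobis machinery
# ---------------------------------------------------------------------------


def analytic_shrinkage(simulated: np.ndarray) -> float:
    """Analytic intensity for shrinking a sample covariance toward its diagonal.

    Schafer–Strimmer estimator: the ratio of the summed sampling
    variances of the off-diagonal covariance entries to their summed
    squares, clipped to [0, 1].  0 keeps the sample covariance, 1 keeps
    only the diagonal.
    """
    X = np.asarray(simulated, dtype=float)
    S, p = X.shape
    if S < 3:
        return 1.0
    Xc = X - X.mean(axis=0)
    W = Xc[:, :, None] * Xc[:, None, :]  # per-draw outer products
    Wbar = W.mean(axis=0)
    var_s = S / ((S - 1) ** 3) * ((W - Wbar) ** 2).sum(axis=0)
    cov = S / (S - 1) * Wbar
    off = ~np.eye(p, dtype=bool)
    denom = float((cov[off] ** 2).sum())
    if denom == 0.0:
        return 1.0
    lam = float(var_s[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def mahalanobis_d2(
    observed: np.ndarray,
    simulated: np.ndarray,
    regularisation: float | None = None,
) -> float:
    """Squared Mahalanobis distance of ``observed`` from the ensemble cloud.

    ``simulated`` is an (S, p) array of simulated vectors; ``observed``
    has length p.  ``regularisation`` is the shrinkage intensity toward
    the diagonal (``None`` selects the analytic intensity; 0 disables
    regularisation; 1 reduces D^2 to a sum of squared componentwise
    z-scores).
    """
    x = np.asarray(observed, dtype=float)
    X = np.asarray(simulated, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 simulated vectors")
    if x.shape != (X.shape[1],):
        raise ValueError(
            f"observed length {x.shape} does not match simulated width {X.shape[1]}"
        )
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    lam = analytic_shrinkage(X) if regularisation is None else float(regularisation)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage intensity must be in [0, 1], got {lam}")
    sigma = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))
    diff = x - mu
    try:
        c, low = scipy.linalg.cho_factor(sigma)
        sol = scipy.linalg.cho_solve((c, low), diff)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        warnings.warn(
            "ensemble covariance singular after regularisation; "
            "falling back to the pseudo-inverse",
            stacklevel=2,
        )
        sol = np.linalg.pinv(sigma) @ diff
    return float(max(diff @ sol, 0.0))


# ---------------------------------------------------------------------------
# location-profile distances
# ---------------------------------------------------------------------------


def _profile_vectors(
    panel: FlowPanel, ensemble: Ensemble, location: str, year: int, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    if location not in ensemble.labels:
        raise KeyError(f"location {location!r} not in ensemble")
    if year not in ensemble.years:
        raise KeyError(f"year {year} not in ensemble (has {ensemble.years})")
    j = ensemble.labels.index(location)
    observed = to_matrix(panel, year)
    if observed.labels != ensemble.labels:
        raise ValueError("panel and ensemble label orderings differ")
    keep = [i for i in range(len(ensemble.labels)) if i != j]
    block = ensemble.draws[year]
    if direction == "in":
        x = observed.values[keep, j]
        sims = block[:, keep, j]
    elif direction == "out":
        x = observed.values[j, keep]
        sims = block[:, j, keep]
    else:
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    return x, sims


def country_inflow_distance(
    panel: FlowPanel,
    ensemble: Ensemble,
    country: str,
    year: int,
    regularisation: float | None = None,
    direction: str = "in",
) -> float:
    """D^2 of one location's observed inflow profile for one year.

    The profile is the (n-1)-vector of flows into ``country`` from every
    other origin (``direction="out"`` uses outflows symmetrically),
    compared with the same vectors extracted from each ensemble draw.
    """
    x, sims = _profile_vectors(panel, ensemble, country, year, direction)
    return mahalanobis_d2(x, sims, regularisation=regularisation)


# ---------------------------------------------------------------------------
# envelopes and corridor checks
# ---------------------------------------------------------------------------


def index_envelope(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    quantiles: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Coverage of observed index values by the simulated distribution.

    ``observed`` and ``simulated`` are tidy index tables
    (:func:`migsim.indices.index_series` output).  The default envelope
    is the full simulated range; pass ``quantiles`` (e.g. ``(0.025,
    0.975)``) for a quantile band.  Output per (index, year): observed
    value, envelope bounds, ensemble mean, and the inside flag.
    """
    obs = observed[observed["source"] == "observed"]
    sim = simulated[simulated["source"] == "simulated"]
    if obs.empty or sim.empty:
        raise ValueError("need observed and simulated index rows")
    keys_obs = set(map(tuple, obs[["index", "year"]].to_numpy()))
    keys_sim = set(map(tuple, sim[["index", "year"]].to_numpy()))
    if keys_obs - keys_sim:
        raise ValueError(
            f"no simulated values for observed keys {sorted(keys_obs - keys_sim)}"
        )
    rows = []
    for (name, year), g in sim.groupby(["index", "year"]):
        o = obs[(obs["index"] == name) & (obs["year"] == year)]
        if o.empty:
            continue
        value = float(o["value"].iloc[0])
        v = g["value"].to_numpy()
        if quantiles is None:
            lo, hi = float(v.min()), float(v.max())
        else:
            lo, hi = (float(q) for q in np.quantile(v, quantiles))
        rows.append(
            {
                "index": name,
                "year": int(year),
                "observed": value,
                "env_min": lo,
                "env_max": hi,
                "sim_mean": float(v.mean()),
                "inside": bool(lo <= value <= hi),
            }
        )
    return pd.DataFrame(rows).sort_values(["index", "year"]).reset_index(drop=True)


def corridor_check(
    panel: FlowPanel, ensemble: Ensemble, origin: str, destination: str
) -> pd.DataFrame:
    """Observed flow vs simulated range for one corridor, per year."""
    labels = ensemble.labels
    if origin not in labels or destination not in labels:
        raise KeyError(f"unknown corridor ({origin!r}, {destination!r})")
    if origin == destination:
        raise KeyError("a corridor joins two distinct locations")
    i, j = labels.index(origin), labels.index(destination)
    rows = []
    for year in ensemble.years:
        observed = to_matrix(panel, year).values[i, j]
        sims = ensemble.draws[year][:, i, j]
        lo, hi = float(sims.min()), float(sims.max())
        rows.append(
            {
                "origin": origin,
                "destination": destination,
                "year": year,
                "observed": float(observed),
                "sim_min": lo,
                "sim_max": hi,
                "sim_mean": float(sims.mean()),
                "inside": bool(lo <= observed <= hi),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Bundle of the three Step-4 checks, exportable to JSON/CSV."""

    index_coverage: pd.DataFrame
    country_distances: pd.DataFrame
    corridor_checks: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "index_coverage": self.index_coverage.to_dict(orient="records"),
            "country_distances": self.country_distances.to_dict(orient="records"),
            "corridor_checks": self.corridor_checks.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_system(
    panel: FlowPanel,
    ensemble: Ensemble,
    which: Sequence[str] = INDEX_NAMES,
    mode: str = "minimum",
    quantiles: tuple[float, float] | None = None,
    regularisation: float | None = None,
    corridors: Sequence[tuple[str, str]] = (),
    direction: str = "in",
) -> EvaluationReport:
    """Run all Step-4 checks for the years covered by the ensemble."""
    years = ensemble.years
    sub = FlowPanel(
        panel.data[panel.data["year"].isin(years)], locations=panel.locations
    )
    obs_idx = index_series(sub, which=which, mode=mode)
    sim_idx = index_series(ensemble, which=which, mode=mode)
    coverage = index_envelope(obs_idx, sim_idx, quantiles=quantiles)

    dist_rows = []
    for year in years:
        for country in ensemble.labels:
            d2 = country_inflow_distance(
                panel,
                ensemble,
                country,
                year,
                regularisation=regularisation,
                direction=direction,
            )
            dist_rows.append({"country": country, "year": year, "d2": d2})
    distances = pd.DataFrame(dist_rows)

    checks = (
        pd.concat(
            [corridor_check(panel, ensemble, o, d) for o, d in corridors],
            ignore_index=True,
        )
        if corridors
        else pd.DataFrame(
            columns=[
                "origin",
                "destination",
                "year",
                "observed",
                "sim_min",
                "sim_max",
                "sim_mean",
                "inside",
            ]
        )
    )
    return EvaluationReport(
        index_coverage=coverage, country_distances=distances, corridor_checks=checks
    )
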