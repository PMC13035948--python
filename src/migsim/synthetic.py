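"""Known-truth synthetic flow panels.

Complete bilateral panels are drawn from a log-linear Poisson process

    flow_ijt ~ Poisson( exp(alpha_i + gamma_j + delta_t + beta' x_ijt) )

with origin, destination and year fixed effects and dyadic covariates
shaped like the drivers used in gravity-style flow regressions:

* a continuous symmetric covariate — the log of pairwise Euclidean
  distances between random planar points, giving the correlated,
  triangle-inequality-respecting structure of real geography;
* binary symmetric tie covariates (contiguity / shared-language
  analogues) with a stated prevalence;
* a signed, time-varying log-ratio covariate (a log population- or
  GDP-ratio analogue), antisymmetric in the dyad and AR(1) over years.

A Poisson data-generating process is used (rather than the truncated
normal of the downstream simulator) because the estimation contract is
the Poisson pseudo-likelihood: known-truth parameter recovery requires
the mean model to be exactly the one being estimated.  The truncated
normal machinery is exercised downstream, on fitted values.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .flow_data import FlowPanel

__all__ = [
    "SyntheticTruth",
    "generate_attributes",
    "generate_panel",
    "generate_reciprocity_regime",
    "default_truth",
]


@dataclass
class SyntheticTruth:
    """Parameters of the synthetic log-linear Poisson flow process.

    The default scale (15 locations, 5 years, ``intercept=3.0``) gives
    mean flows of a few dozen movers per corridor — large enough that the
    spatial indices are stable, small enough that a full panel fits and
    simulates in well under a second.
    """

    n_locations: int = 15
    years: tuple[int, ...] = (2002, 2003, 2004, 2005, 2006)
    #: overall log-scale of flows (delta of the first year)
    intercept: float = 3.0
    #: true coefficients, keyed by covariate column name
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "log_distance": -0.8,
            "tie": 0.5,
            "log_ratio": 0.4,
        }
    )
    #: standard deviations of the origin / destination / year fixed effects
    fe_sd: dict[str, float] = field(
        default_factory=lambda: {"origin": 0.5, "destination": 0.5, "year": 0.1}
    )
    #: prevalence of the binary symmetric tie covariate
    tie_prevalence: float = 0.15
    #: AR(1) autocorrelation of the time-varying log-ratio covariate
    log_ratio_rho: float = 0.8
    #: marginal standard deviation of the log-ratio covariate
    log_ratio_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 3:
            raise ValueError("need at least 3 locations")
        if not 0.0 <= self.tie_prevalence <= 1.0:
            raise ValueError(
                f"tie prevalence must be in [0, 1], got {self.tie_prevalence}"
            )
        self.years = tuple(int(y) for y in self.years)

    @property
    def labels(self) -> list[str]:
        return [f"L{i:02d}" for i in range(self.n_locations)]


def default_truth(**overrides) -> SyntheticTruth:
    """The package's reference synthetic scenario (15 locations x 5 years)."""
    return SyntheticTruth(**overrides)


def _dyad_frame(labels: Sequence[str], years: Sequence[int]) -> pd.DataFrame:
    n = len(labels)
    oi, dj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = oi != dj
    oi, dj = oi[off], dj[off]
    frames = []
    for year in years:
        frames.append(
            pd.DataFrame(
                {
                    "origin": [labels[i] for i in oi],
                    "destination": [labels[j] for j in dj],
                    "year": int(year),
                    "_oi": oi,
                    "_dj": dj,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_attributes(
    n_locations: int,
    years: Sequence[int],
    tie_prevalence: float = 0.15,
    log_ratio_rho: float = 0.8,
    log_ratio_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the dyadic covariate table.

    Returns a frame keyed by (origin, destination, year) with columns
    ``log_distance`` (symmetric), ``tie`` (binary symmetric, stated
    prevalence) and ``log_ratio`` (antisymmetric, AR(1) over years).
    """
    if n_locations < 3:
        raise ValueError("need at least 3 locations")
    if not 0.0 <= tie_prevalence <= 1.0:
        raise ValueError(f"tie prevalence must be in [0, 1], got {tie_prevalence}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    labels = [f"L{i:02d}" for i in range(n_locations)]
    years = [int(y) for y in years]

    # planar points on the unit square; log pairwise distance
    points = rng.uniform(0.0, 1.0, size=(n_locations, 2))
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    with np.errstate(divide="ignore"):
        log_dist = np.log(dist)

    # symmetric binary tie: draw upper triangle, mirror
    tie = np.zeros((n_locations, n_locations), dtype=float)
    iu = np.triu_indices(n_locations, k=1)
    tie[iu] = (rng.uniform(size=len(iu[0])) < tie_prevalence).astype(float)
    tie = tie + tie.T

    # per-location AR(1) log-size; dyadic log-ratio is antisymmetric
    t = len(years)
    innov_sd = log_ratio_sd * np.sqrt(1.0 - log_ratio_rho**2)
    size = np.empty((t, n_locations))
    size[0] = rng.normal(0.0, log_ratio_sd, size=n_locations)
    for k in range(1, t):
        size[k] = log_ratio_rho * size[k - 1] + rng.normal(
            0.0, innov_sd, size=n_locations
        )

    df = _dyad_frame(labels, years)
    yi = {y: k for k, y in enumerate(years)}
    oi = df["_oi"].to_numpy()
    dj = df["_dj"].to_numpy()
    ti = df["year"].map(yi).to_numpy()
    df["log_distance"] = log_dist[oi, dj]
    df["tie"] = tie[oi, dj]
    # log-ratio of destination size to origin size (antisymmetric by construction)
    df["log_ratio"] = size[ti, dj] - size[ti, oi]
    return df.drop(columns=["_oi", "_dj"])


def _fixed_effects(truth: SyntheticTruth, rng: np.random.Generator):
    n, t = truth.n_locations, len(truth.years)
    alpha = rng.normal(0.0, truth.fe_sd["origin"], size=n)
    gamma = rng.normal(0.0, truth.fe_sd["destination"], size=n)
    delta = rng.normal(0.0, truth.fe_sd["year"], size=t)
    # first level of each dimension is the reference category
    alpha -= alpha[0]
    gamma -= gamma[0]
    delta = delta - delta[0] + truth.intercept
    return alpha, gamma, delta


def _mean_matrix_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Dyad-year frame with covariates and the true Poisson mean ``mu``."""
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed, spawn_key=(2,)))
    attrs = generate_attributes(
        truth.n_locations,
        truth.years,
        tie_prevalence=truth.tie_prevalence,
        log_ratio_rho=truth.log_ratio_rho,
        log_ratio_sd=truth.log_ratio_sd,
        seed=truth.seed,
    )
    alpha, gamma, delta = _fixed_effects(truth, rng)
    labels = truth.labels
    li = {lab: i for i, lab in enumerate(labels)}
    yi = {y: k for k, y in enumerate(truth.years)}
    eta = (
        alpha[attrs["origin"].map(li).to_numpy()]
        + gamma[attrs["destination"].map(li).to_numpy()]
        + delta[attrs["year"].map(yi).to_numpy()]
    )
    for name, coef in truth.beta.items():
        if name not in attrs.columns:
            raise KeyError(f"truth.beta names unknown covariate {name!r}")
        eta = eta + coef * attrs[name].to_numpy()
    mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        bad = attrs.iloc[int(np.argmax(~np.isfinite(mu)))]
        raise ValueError(
            f"mean overflow for dyad ({bad['origin']}, {bad['destination']}, "
            f"{bad['year']}); reduce intercept or coefficient scale"
        )
    attrs = attrs.copy()
    attrs["mu"] = mu
    return attrs


def generate_panel(truth: SyntheticTruth) -> FlowPanel:
    """Draw a complete Poisson flow panel from the truth.

    The returned panel carries the covariate columns, so it can be fed
    directly to the estimator; regeneration from the same truth (including
    seed) is bit-identical.
    """
    frame = _mean_matrix_frame(truth)
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed, spawn_key=(3,)))
    frame["flow"] = rng.poisson(frame.pop("mu").to_numpy()).astype(float)
    return FlowPanel(frame, locations=truth.labels)


def generate_reciprocity_regime(
    truth: SyntheticTruth,
    reciprocity_boost: float,
    seed: int | None = None,
    origin_shock_sd: float = 0.8,
) -> FlowPanel:
    """Draw a panel whose corridors are more reciprocal than any log-linear
    model of its covariates can represent.

    A multiplicative fixed-effects model constrains every corridor's
    directional ratio to ``m_ij / m_ji = r_i / r_j``, a node-potential
    structure that spreads whatever net imbalance the margins carry
    across *all* corridors, the reciprocal ones included.  This regime
    breaks that constraint from the data side.  With mixing weight
    ``w = boost / (1 + boost)``:

    * the two directions of every *tie* corridor (the symmetric binary
      covariate marks, e.g., partnership or shared-language pairs) are
      pulled toward balance while keeping the corridor total,
      ``mu'_ij = (1 - w_ij) mu_ij + w_ij (mu_ij + mu_ji) / 2`` with
      ``w_ij = w * tie_ij`` — two-way exchange on exactly the corridors
      whose covariate the regression treats symmetrically;
    * mean-zero origin-year shocks (s.d. ``w * origin_shock_sd`` on the
      log scale) emulate origin-specific emigration waves.  They leave
      the observed-vs-simulated comparison untouched when row
      calibration is on (calibration transfers observed row totals into
      every draw) but inflate the clustered uncertainty of the fitted
      flows the way real residual heterogeneity does.

    Corridor totals on tie pairs are preserved, so the symmetric
    covariate effects are unchanged in expectation; node margins remain
    unbalanced through the non-tie corridors.  A fixed-effects PPML fit
    must therefore tilt the tie corridors that the data keep balanced:
    the simulated ensemble under-predicts reciprocity while reproducing
    the concentration of flows.  ``boost = 0`` reduces exactly to
    :func:`generate_panel` on the same seed path.
    """
    if reciprocity_boost < 0:
        raise ValueError("reciprocity_boost must be >= 0")
    frame = _mean_matrix_frame(truth)
    w = reciprocity_boost / (1.0 + reciprocity_boost)
    draw_seed = truth.seed if seed is None else seed
    if w > 0:
        li = {lab: i for i, lab in enumerate(truth.labels)}
        yi = {y: k for k, y in enumerate(truth.years)}
        rng_shock = np.random.default_rng(
            np.random.SeedSequence(draw_seed, spawn_key=(7,))
        )
        shocks = rng_shock.normal(
            0.0, w * origin_shock_sd, size=(len(truth.years), truth.n_locations)
        )
        frame["mu"] = frame["mu"] * np.exp(
            shocks[frame["year"].map(yi).to_numpy(), frame["origin"].map(li).to_numpy()]
        )
        mirror = frame[["origin", "destination", "year", "mu"]].rename(
            columns={"origin": "destination", "destination": "origin", "mu": "mu_rev"}
        )
        frame = frame.merge(mirror, on=["origin", "destination", "year"], how="left")
        wc = w * frame["tie"].to_numpy()
        frame["mu"] = (1.0 - wc) * frame["mu"] + wc * 0.5 * (
            frame["mu"] + frame["mu_rev"]
        )
        frame = frame.drop(columns=["mu_rev"])
    rng = np.random.default_rng(np.random.SeedSequence(draw_seed, spawn_key=(3,)))
    frame["flow"] = rng.poisson(frame.pop("mu").to_numpy()).astype(float)
    return FlowPanel(frame, locations=truth.labels)


def misfit_scenario(seed: int = 0) -> SyntheticTruth:
    """Reference scenario for spatial-misfit experiments.

    Larger flows (intercept 7 gives corridors of a few hundred to a few
    tens of thousands of movers, the scale of European bilateral flows),
    a quarter of dyads carrying a strong symmetric tie, five years.
    Used with :func:`generate_reciprocity_regime` at a large boost, the
    fitted model reproduces concentration but under-predicts
    reciprocity.
    """
    truth = SyntheticTruth(
        n_locations=15,
        years=(2002, 2003, 2004, 2005, 2006),
        intercept=7.0,
        tie_prevalence=0.25,
        fe_sd={"origin": 0.8, "destination": 0.8, "year": 0.1},
        seed=seed,
    )
    truth.beta["tie"] = 1.5
    return truth
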