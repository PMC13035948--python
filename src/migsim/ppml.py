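"""Poisson pseudo-maximum-likelihood (PPML) flow regressions.

Bilateral flows are modelled multiplicatively,

    E[y_ijt | x] = exp( alpha_i + gamma_j + delta_t + beta' x_ijt ),

and estimated by Poisson pseudo-likelihood: consistent whenever the
conditional mean is correctly specified, regardless of the distribution
of the flows, and defined for zero flows — the standard estimator for
gravity-style flow equations.  Fixed effects are absorbed by explicit
dummy encoding (panels at the scale handled here — tens of thousands of
dyad-years, on the order of a hundred coefficients — fit densely without
difficulty); the generalized linear model itself is solved by
statsmodels' iteratively reweighted least squares.

On top of the fit this module provides the inference layer that flow
panels need and generic GLM software does not:

* multiway (inclusion–exclusion) cluster-robust covariances, e.g.
  three-way by origin, destination and year;
* the RESET specification test (significance of the squared fitted
  linear predictor, judged with the clustered covariance);
* pseudo-R² fit statistics (squared correlation, adjusted McFadden
  pseudo-R², and its within-fixed-effects version);
* response-scale confidence intervals for fitted flows, which feed the
  downstream ensemble simulator.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.special
from scipy import stats
import statsmodels.api as sm

from .flow_data import DIMENSIONS, FlowPanel, ModelSpec

logger = logging.getLogger("migsim")

__all__ = [
    "FittedModel",
    "FitStatistics",
    "ResetResult",
    "fit_ppml",
    "clustered_vcov",
    "reset_test",
    "fit_statistics",
    "effect_size",
    "fitted_intervals",
]

#: IRLS convergence tolerance (relative change of the deviance-like criterion)
IRLS_TOL = 1e-8
#: IRLS iteration cap
IRLS_MAXITER = 100
#: relative pivot threshold below which a design column is declared collinear
COLLINEARITY_RTOL = 1e-9


class EstimationError(RuntimeError):
    """PPML estimation failed (non-convergence or a degenerate design)."""


@dataclass
class FitStatistics:
    """Goodness-of-fit block of a PPML regression.

    ``squared_correlation`` is the squared linear correlation between
    observed and fitted flows; ``adjusted_pseudo_r2`` is McFadden's
    statistic with a degrees-of-freedom penalty, 1 - (ll - k)/ll_null;
    the within version replaces the null by the fixed-effects-only model,
    isolating the contribution of the substantive predictors.
    """

    squared_correlation: float
    adjusted_pseudo_r2: float
    within_adjusted_pseudo_r2: float | None
    reset_p: float | None = None


@dataclass
class ResetResult:
    statistic: float | None
    p_value: float | None
    degenerate: bool = False
    powers: tuple[int, ...] = (2,)


@dataclass
class FittedModel:
    """A fitted PPML flow regression with everything inference needs."""

    spec: ModelSpec
    params: pd.Series
    vcov: pd.DataFrame
    frame: pd.DataFrame  # estimation records: keys, flow, transformed terms
    design: pd.DataFrame  # named design matrix (intercept, terms, FE dummies)
    fitted: np.ndarray  # exp(eta), aligned with frame
    linear_predictor: np.ndarray
    loglik: float
    loglik_null: float
    loglik_fe_only: float | None
    n_obs: int
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def term_names(self) -> list[str]:
        """Names of the substantive (non-fixed-effect, non-intercept) terms."""
        return [self.spec.term_name(p) for p in self.spec.predictors
                if self.spec.term_name(p) in self.params.index]

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se()
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    def fitted_frame(self) -> pd.DataFrame:
        out = self.frame[["origin", "destination", "year", "flow"]].copy()
        out["fitted"] = self.fitted
        return out


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _build_design(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Intercept + substantive terms + FE dummies (reference level dropped)."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(frame))}
    for pred in spec.predictors:
        term = spec.term_name(pred)
        cols[term] = frame[term].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=frame.index)
    for dim in spec.fixed_effects:
        dummies = pd.get_dummies(frame[dim], prefix=dim, dtype=float)
        X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)  # first level = reference
    return X


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop perfectly collinear columns via pivoted QR, keeping earlier columns."""
    arr = X.to_numpy(dtype=float)
    _, R, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    keep_mask = np.zeros(arr.shape[1], dtype=bool)
    thresh = COLLINEARITY_RTOL * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > thresh))
    keep_mask[piv[:rank]] = True
    dropped = [c for c, k in zip(X.columns, keep_mask) if not k]
    if dropped:
        warnings.warn(
            f"dropping perfectly collinear design column(s): {dropped}",
            stacklevel=3,
        )
    return X.loc[:, keep_mask], dropped


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson pseudo log-likelihood (gamma-function continuation for real y)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(term - mu - scipy.special.gammaln(y + 1.0)))


def _glm_fit(y: np.ndarray, X: pd.DataFrame):
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
    if not res.converged:
        raise EstimationError(
            f"IRLS did not converge in {IRLS_MAXITER} iterations "
            f"(deviance trace tail: {res.fit_history['deviance'][-5:]})"
        )
    return res


# ---------------------------------------------------------------------------
# main fit
# ---------------------------------------------------------------------------


def fit_ppml(panel: FlowPanel, spec: ModelSpec) -> FittedModel:
    """Estimate the PPML regression defined by ``spec`` on ``panel``.

    Zero flows are retained (the Poisson pseudo-likelihood handles them);
    reference categories of each fixed-effect dimension are dropped for
    identifiability, and any remaining perfectly collinear columns are
    dropped with a warning naming them.  The solution satisfies the
    first-order conditions sum((y - mu) * x) = 0 for every retained
    column, so fitted and observed totals agree whenever an intercept or
    fixed-effect set is present.
    """
    frame = spec.build_design_frame(panel)
    if frame.empty:
        raise EstimationError("no estimable records after transforms")
    y = frame["flow"].to_numpy(dtype=float)
    X, dropped = _drop_collinear(_build_design(frame, spec))

    res = _glm_fit(y, X)
    mu = np.asarray(res.mu)
    eta = np.log(mu)
    loglik = _poisson_loglik(y, mu)

    # intercept-only null
    res_null = _glm_fit(y, pd.DataFrame({"const": np.ones(len(y))}, index=frame.index))
    loglik_null = _poisson_loglik(y, np.asarray(res_null.mu))

    # fixed-effects-only baseline (for the within pseudo-R²)
    loglik_fe_only = None
    if spec.fixed_effects and spec.predictors:
        fe_spec = ModelSpec(
            predictors={}, fixed_effects=spec.fixed_effects, clusters=spec.clusters
        )
        X_fe, _ = _drop_collinear(_build_design(frame, fe_spec))
        res_fe = _glm_fit(y, X_fe)
        loglik_fe_only = _poisson_loglik(y, np.asarray(res_fe.mu))

    model = FittedModel(
        spec=spec,
        params=pd.Series(res.params, index=X.columns),
        vcov=pd.DataFrame(np.nan, index=X.columns, columns=X.columns),
        frame=frame,
        design=X,
        fitted=mu,
        linear_predictor=eta,
        loglik=loglik,
        loglik_null=loglik_null,
        loglik_fe_only=loglik_fe_only,
        n_obs=len(y),
        dropped_columns=dropped,
    )
    model.vcov = clustered_vcov(model, spec.clusters)
    return model


# ---------------------------------------------------------------------------
# multiway clustered covariance
# ---------------------------------------------------------------------------


def _sandwich(
    scores: np.ndarray, bread: np.ndarray, groups: np.ndarray | None, k: int
) -> np.ndarray:
    """One-way cluster sandwich with the standard finite-sample factor
    G/(G-1) * (n-1)/(n-k); without clusters this reduces to the HC1
    correction n/(n-k)."""
    n = scores.shape[0]
    if groups is None:  # each observation its own cluster
        meat = scores.T @ scores
        factor = n / max(n - k, 1)
    else:
        sums = (
            pd.DataFrame(scores)
            .groupby(pd.Series(groups), sort=False)
            .sum()
            .to_numpy()
        )
        meat = sums.T @ sums
        G = sums.shape[0]
        factor = (G / max(G - 1, 1)) * ((n - 1) / max(n - k, 1))
    return factor * (bread @ meat @ bread)


def clustered_vcov(
    model: FittedModel, cluster_dims: Sequence[str] = ()
) -> pd.DataFrame:
    """Cluster-robust covariance of the PPML coefficients.

    With no cluster dimensions this is the heteroskedasticity-robust
    sandwich.  With one or more dimensions the multiway estimator is the
    inclusion–exclusion sum over all non-empty subsets ``C`` of the
    dimensions, with sign ``(-1)^(|C|+1)``, of the one-way sandwich
    clustered on the intersection of the dimensions in ``C``.  Each
    one-way sandwich carries the conventional finite-sample factor
    ``G/(G-1) * (n-1)/(n-k)`` (``n/(n-k)`` when unclustered).  The
    inclusion–exclusion combination is not guaranteed positive
    semidefinite; negative eigenvalues are truncated at zero (with a
    warning), the conventional repair.
    """
    X = model.design.to_numpy(dtype=float)
    y = model.frame["flow"].to_numpy(dtype=float)
    mu = model.fitted
    scores = (y - mu)[:, None] * X
    info = (X * mu[:, None]).T @ X
    bread = np.linalg.pinv(info)

    dims = tuple(cluster_dims)
    for dim in dims:
        if dim not in DIMENSIONS:
            raise ValueError(f"unknown cluster dimension {dim!r}")
        n_clusters = model.frame[dim].nunique()
        if n_clusters < 2:
            raise ValueError(
                f"cluster dimension {dim!r} has a single cluster; "
                f"clustered inference is degenerate"
            )

    k = X.shape[1]
    if not dims:
        V = _sandwich(scores, bread, None, k)
    else:
        V = np.zeros_like(bread)
        for r in range(1, len(dims) + 1):
            for subset in itertools.combinations(dims, r):
                key = (
                    model.frame[list(subset)]
                    .astype(str)
                    .agg("\x1f".join, axis=1)
                    .to_numpy()
                )
                V += ((-1.0) ** (r + 1)) * _sandwich(scores, bread, key, k)

    V = 0.5 * (V + V.T)
    eigval, eigvec = np.linalg.eigh(V)
    if eigval.min() < 0:
        if eigval.min() < -1e-12 * max(eigval.max(), 1.0):
            warnings.warn(
                "multiway clustered covariance is not PSD "
                f"(min eigenvalue {eigval.min():.3g}); truncating at zero",
                stacklevel=2,
            )
        V = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
        V = 0.5 * (V + V.T)
    return pd.DataFrame(V, index=model.design.columns, columns=model.design.columns)


# ---------------------------------------------------------------------------
# RESET specification test
# ---------------------------------------------------------------------------


def reset_test(model: FittedModel, cubic: bool = False) -> ResetResult:
    """RESET: re-estimate with powers of the fitted linear predictor added.

    The linear predictor is standardised before powering (numerically
    safer; spans the same augmentation space given the intercept), the
    model is refit with the extra column(s), and their joint significance
    is judged by a Wald test with the model's clustered covariance.  A
    small p-value signals that the multiplicative mean specification is
    inadequate.
    """
    eta = model.linear_predictor
    sd = eta.std()
    if sd == 0:
        return ResetResult(None, None, degenerate=True)
    z = (eta - eta.mean()) / sd
    powers = (2, 3) if cubic else (2,)
    aug_names = [f"_reset_pow{p}" for p in powers]
    X_aug = model.design.copy()
    for name, p in zip(aug_names, powers):
        X_aug[name] = z**p

    X_kept, dropped = _drop_collinear(X_aug)
    if any(name in dropped for name in aug_names):
        return ResetResult(None, None, degenerate=True, powers=powers)

    y = model.frame["flow"].to_numpy(dtype=float)
    res = _glm_fit(y, X_kept)
    aug_model = FittedModel(
        spec=model.spec,
        params=pd.Series(res.params, index=X_kept.columns),
        vcov=pd.DataFrame(),
        frame=model.frame,
        design=X_kept,
        fitted=np.asarray(res.mu),
        linear_predictor=np.log(np.asarray(res.mu)),
        loglik=np.nan,
        loglik_null=np.nan,
        loglik_fe_only=None,
        n_obs=model.n_obs,
    )
    V = clustered_vcov(aug_model, model.spec.clusters)
    b = aug_model.params[aug_names].to_numpy()
    Vb = V.loc[aug_names, aug_names].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(Vb, b))
    except np.linalg.LinAlgError:
        return ResetResult(None, None, degenerate=True, powers=powers)
    p = float(stats.chi2.sf(stat, df=len(aug_names)))
    return ResetResult(stat, p, powers=powers)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def fit_statistics(model: FittedModel, include_reset: bool = True) -> FitStatistics:
    """Squared correlation, adjusted pseudo-R² (and within version), RESET p."""
    y = model.frame["flow"].to_numpy(dtype=float)
    mu = model.fitted
    if np.std(mu) == 0 or np.std(y) == 0:
        warnings.warn(
            "degenerate correlation (constant observed or fitted flows); "
            "squared correlation reported as 0",
            stacklevel=2,
        )
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, mu)[0, 1] ** 2)

    if model.loglik_null == 0:
        raise ZeroDivisionError(
            "null log-likelihood is zero; adjusted pseudo-R² undefined"
        )
    adj = 1.0 - (model.loglik - model.k) / model.loglik_null

    within = None
    if model.loglik_fe_only is not None and model.loglik_fe_only != 0:
        k_extra = len(model.term_names)
        within = 1.0 - (model.loglik - k_extra) / model.loglik_fe_only

    reset_p = None
    if include_reset:
        rr = reset_test(model)
        reset_p = rr.p_value
    return FitStatistics(
        squared_correlation=r2,
        adjusted_pseudo_r2=float(adj),
        within_adjusted_pseudo_r2=None if within is None else float(within),
        reset_p=reset_p,
    )


# ---------------------------------------------------------------------------
# effect sizes and fitted intervals
# ---------------------------------------------------------------------------


def effect_size(
    beta: float, kind: str, delta_pct: float | None = None
) -> float:
    """Percent change in flows implied by a coefficient.

    ``exponential`` — the exact percent difference for a 0→1 switch of a
    binary predictor in a multiplicative mean model, ``100*(exp(beta)-1)``.
    ``elasticity`` — the linear approximation for a ``delta_pct`` percent
    increase of a log-transformed predictor, ``beta * delta_pct``.
    """
    if not np.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta}")
    if kind == "exponential":
        return float(100.0 * (np.exp(beta) - 1.0))
    if kind == "elasticity":
        if delta_pct is None:
            raise ValueError("delta_pct is required for kind='elasticity'")
        return float(beta * delta_pct)
    raise ValueError(f"unknown kind {kind!r}; expected 'exponential' or 'elasticity'")


def fitted_intervals(model: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """Response-scale confidence bands for every fitted flow.

    Built on the link scale and exponentiated: ``exp(eta ± z se(eta))``
    with ``se(eta)`` from the clustered coefficient covariance (fixed
    effect estimation uncertainty included).  Positivity of the lower
    bound is automatic.  Columns: origin, destination, year, flow,
    fitted, se_eta, lower, upper; metadata in ``DataFrame.attrs``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    X = model.design.to_numpy(dtype=float)
    V = model.vcov.to_numpy()
    se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, V, X), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = model.fitted_frame()
    out["se_eta"] = se_eta
    out["lower"] = np.exp(model.linear_predictor - z * se_eta)
    out["upper"] = np.exp(model.linear_predictor + z * se_eta)
    out.attrs["interval_scale"] = "link-scale, exponentiated"
    out.attrs["level"] = level
    return out
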