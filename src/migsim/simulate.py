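"""Ensemble simulation of complete flow systems from a fitted model.

Uncertainty in the fitted flows is propagated into the spatial domain by
drawing, independently for each dyad and year,

    y*_ij ~ TruncatedNormal( yhat_ij, sigma_ij^2 ; a, b ),

where ``yhat_ij`` is the fitted flow, ``sigma_ij`` is recovered from the
width of the fitted flow's confidence interval, and the truncation
interval (default ``[0, inf)``) keeps simulated flows nonnegative.  One
draw across all dyads of a year is one simulated flow system; repeating
the draw S times yields an ensemble — the model-implied reference
distribution against which the observed system is judged.

Optionally each simulated matrix is row-calibrated: every origin's
simulated outflows are rescaled multiplicatively so the row total
matches the observed outflow total of that origin and year.  Scaling
preserves zeros (no corridor appears that the model did not predict)
and makes every simulated system's aggregate volume match the observed
one.

Sampling is inverse-CDF (scipy's ``truncnorm``), so ensembles are exact
functions of the root seed; per-(year, draw) substreams are derived with
``numpy.random.SeedSequence`` spawn keys, making draws reproducible
independently of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flow_data import FlowMatrix, FlowPanel
from .ppml import FittedModel, fitted_intervals

__all__ = [
    "SimulationConfig",
    "Ensemble",
    "sigma_from_interval",
    "draw_truncated_flows",
    "calibrate_rows",
    "simulate_ensemble",
]


class CalibrationError(RuntimeError):
    """A row cannot be scaled to its observed target."""


@dataclass
class SimulationConfig:
    """Controls of the ensemble simulator.

    ``level`` must match the confidence level of the intervals from which
    ``sigma`` is recovered.  The upper truncation bound defaults to
    infinity: nonnegativity is the only restriction the method itself
    imposes, and any finite default would be arbitrary.
    """

    S: int = 1000
    level: float = 0.95
    lower: float = 0.0
    upper: float = float("inf")
    calibrate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.lower < 0:
            raise ValueError(f"lower bound must be >= 0, got {self.lower}")
        if not self.lower < self.upper:
            raise ValueError(
                f"need lower < upper, got [{self.lower}, {self.upper}]"
            )


@dataclass
class Ensemble:
    """S simulated flow matrices per year.

    ``draws[year]`` is an ``(S, n, n)`` array sharing the label ordering
    in ``labels``; diagonals are zero in every draw.
    """

    labels: list[str]
    draws: dict[int, np.ndarray]
    config: SimulationConfig
    model_id: str = ""

    @property
    def years(self) -> list[int]:
        return sorted(self.draws)

    @property
    def S(self) -> int:
        return self.config.S

    def matrices(self, year: int):
        """Iterate the draws of one year as FlowMatrix objects."""
        for s in range(self.S):
            yield FlowMatrix(
                labels=self.labels, values=self.draws[year][s], year=year
            )


def sigma_from_interval(
    lower: float | np.ndarray, upper: float | np.ndarray, level: float
) -> float | np.ndarray:
    """Standard deviation implied by a normal confidence interval's width.

    For a symmetric normal interval at confidence ``level`` the width is
    ``2 z sigma`` with ``z`` the standard-normal quantile at
    ``(1 + level) / 2``; inverting gives ``sigma = width / (2 z)``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(upper < lower):
        raise ValueError("upper interval bound below lower bound")
    z = stats.norm.ppf(0.5 + level / 2.0)
    sigma = (upper - lower) / (2.0 * z)
    return float(sigma) if sigma.ndim == 0 else sigma


def draw_truncated_flows(
    fitted: np.ndarray,
    sigmas: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One truncated-normal draw per dyad (inverse-CDF sampling).

    Dyads with ``sigma == 0`` return the fitted value clipped to the
    truncation interval (the degenerate distribution).
    """
    fitted = np.asarray(fitted, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if fitted.shape != sigmas.shape:
        raise ValueError("fitted and sigmas must be aligned")
    if np.any(sigmas < 0):
        raise ValueError("sigma must be nonnegative")
    out = np.clip(fitted, config.lower, config.upper)
    pos = sigmas > 0
    if np.any(pos):
        u = rng.uniform(size=int(pos.sum()))
        a = (config.lower - fitted[pos]) / sigmas[pos]
        b = (config.upper - fitted[pos]) / sigmas[pos]
        out[pos] = stats.truncnorm.ppf(
            u, a, b, loc=fitted[pos], scale=sigmas[pos]
        )
    return out


def calibrate_rows(
    matrix: FlowMatrix, observed_outflows: Mapping[str, float] | pd.Series
) -> FlowMatrix:
    """Scale each row multiplicatively to match its observed outflow total.

    A zero observed target zeroes the row; a zero simulated row with a
    positive target cannot be scaled and raises, naming the origin.
    Relative proportions within a row — and in particular its zeros —
    are preserved.
    """
    values = matrix.values.copy()
    row_sums = values.sum(axis=1)
    for i, label in enumerate(matrix.labels):
        try:
            target = float(observed_outflows[label])
        except KeyError:
            raise CalibrationError(f"no observed outflow total for origin {label!r}")
        if target < 0:
            raise CalibrationError(f"negative outflow target for origin {label!r}")
        if target == 0.0:
            values[i, :] = 0.0
        elif row_sums[i] == 0.0:
            raise CalibrationError(
                f"simulated outflows from origin {label!r} sum to zero but the "
                f"observed total is {target}; the row cannot be calibrated"
            )
        else:
            values[i, :] *= target / row_sums[i]
    return FlowMatrix(labels=list(matrix.labels), values=values, year=matrix.year)


def _rng_for(seed: int, year_index: int, draw: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(year_index, draw))
    )


def simulate_ensemble(
    model: FittedModel,
    panel: FlowPanel,
    config: SimulationConfig,
    years: Sequence[int] | None = None,
) -> Ensemble:
    """Generate the full ensemble implied by a fitted model.

    Fitted flows and their confidence intervals come from the model (the
    interval is built on the link scale and exponentiated, then its width
    is converted to a response-scale sigma); calibration targets come
    from the observed panel.  Years default to the model's estimation
    years.
    """
    bands = fitted_intervals(model, level=config.level)
    bands["sigma"] = sigma_from_interval(
        bands["lower"].to_numpy(), bands["upper"].to_numpy(), config.level
    )
    labels = panel.locations
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    use_years = sorted(
        int(y) for y in (bands["year"].unique() if years is None else years)
    )

    draws: dict[int, np.ndarray] = {}
    for yi, year in enumerate(use_years):
        sub = bands[bands["year"] == year]
        if sub.empty:
            raise KeyError(f"year {year} has no fitted flows")
        ri = sub["origin"].map(pos).to_numpy()
        ci = sub["destination"].map(pos).to_numpy()
        fitted_flat = sub["fitted"].to_numpy()
        sigma_flat = sub["sigma"].to_numpy()
        targets = panel.outflow_totals(year)

        block = np.zeros((config.S, n, n))
        for s in range(config.S):
            rng = _rng_for(config.seed, yi, s)
            flat = draw_truncated_flows(fitted_flat, sigma_flat, config, rng)
            mat = np.zeros((n, n))
            mat[ri, ci] = flat
            fm = FlowMatrix(labels=list(labels), values=mat, year=year)
            if config.calibrate:
                fm = calibrate_rows(fm, targets)
            block[s] = fm.values
        draws[year] = block
    return Ensemble(labels=list(labels), draws=draws, config=config)
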