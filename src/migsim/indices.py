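"""System-level spatial indices of flow matrices.

Four indices summarise the spatial organisation of an origin-destination
matrix ``M`` with ``n`` locations and off-diagonal cells ``m_ij``
(structural zeros on the diagonal never enter any sum):

Aggregate coefficient of variation (ACV)
    flow-weighted sum over origins of each origin's coefficient of
    variation of outflows — dispersion relative to the mean, highly
    sensitive to one or two dominant corridors (primacy).  Unbounded
    above; 0 when every outflow from each origin is equal.

Gini index
    mean absolute difference between every ordered pair of corridor
    flows, normalised to [0, 1]; sensitive to the middle of the flow
    distribution.  The default denominator ``(2 n (n-1) - 1) * sum(m)``
    follows the migration-index convention adopted here; the textbook
    ``2 N * sum(m)`` form (``N = n (n-1)`` corridors) is available via
    ``normalisation="standard"`` since the default form does not reach
    exactly 1 at maximal concentration.

Migration inequality index
    half the total absolute deviation from the uniform benchmark in
    which all ``n (n-1)`` corridors carry the same flow, as a share of
    total flow; 0 for the uniform system, approaching 1 when a single
    corridor carries everything.

Reciprocity
    the share of movers matched by a counter-flow in the same corridor:
    ``sum_ij min(m_ij, m_ji) / sum_ij m_ij`` in the default ``minimum``
    mode (a value of 0.7 means 70% of movers are in corridors with
    two-way exchange).  ``maximum`` and ``geometric_mean`` modes replace
    the min accordingly; the geometric mean of a corridor with one zero
    flow is 0.

All four are invariant to relabeling and to a positive rescaling of all
flows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flow_data import FlowMatrix, FlowPanel, to_matrix
from .simulate import Ensemble

__all__ = [
    "acv",
    "gini",
    "inequality",
    "reciprocity",
    "index_series",
    "ensemble_summary",
    "INDEX_NAMES",
    "UndefinedIndexError",
]

INDEX_NAMES = ("acv", "gini", "inequality", "reciprocity")

RECIPROCITY_MODES = ("minimum", "maximum", "geometric_mean")


class UndefinedIndexError(ValueError):
    """The index is undefined on this matrix (no flow to normalise by)."""


def _off_values(M: FlowMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = M.values if isinstance(M, FlowMatrix) else np.asarray(M, dtype=float)
    n = values.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return values, mask


def acv(M: FlowMatrix | np.ndarray) -> float:
    values, mask = _off_values(M)
    n = values.shape[0]
    total = values[mask].sum()
    if total <= 0:
        raise UndefinedIndexError("ACV undefined on an all-zero matrix")
    out = values.copy()
    np.fill_diagonal(out, np.nan)
    row = np.nanmean(out, axis=1)  # mean off-diagonal outflow per origin
    # per-origin sd over the n-1 outflows with the 1/(n-1) divisor
    sd = np.sqrt(np.nansum((out - row[:, None]) ** 2, axis=1) / (n - 1))
    weights = np.nansum(out, axis=1) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(row > 0, sd / row, 0.0)  # zero-outflow origins contribute 0
    return float(np.sum(cv * weights))


def gini(M: FlowMatrix | np.ndarray, normalisation: str = "as-defined") -> float:
    values, mask = _off_values(M)
    n = values.shape[0]
    flows = values[mask]
    total = flows.sum()
    if total <= 0:
        raise UndefinedIndexError("Gini undefined on an all-zero matrix")
    # sum over all ordered pairs of |m_ij - m_kl| via the sorted-flows identity
    x = np.sort(flows)
    N = len(x)
    ranks = np.arange(1, N + 1)
    pair_sum = 2.0 * float(np.sum((2 * ranks - N - 1) * x))
    if normalisation == "as-defined":
        denom = (2.0 * n * (n - 1) - 1.0) * total
    elif normalisation == "standard":
        denom = 2.0 * N * total
    else:
        raise ValueError(
            f"unknown normalisation {normalisation!r}; "
            f"expected 'as-defined' or 'standard'"
        )
    return float(pair_sum / denom)


def inequality(M: FlowMatrix | np.ndarray) -> float:
    values, mask = _off_values(M)
    n = values.shape[0]
    flows = values[mask]
    total = flows.sum()
    if total <= 0:
        raise UndefinedIndexError("inequality index undefined on an all-zero matrix")
    uniform = total / (n * (n - 1))
    return float(np.abs(flows - uniform).sum() / (2.0 * total))


def reciprocity(M: FlowMatrix | np.ndarray, mode: str = "minimum") -> float:
    values, mask = _off_values(M)
    total = values[mask].sum()
    if total <= 0:
        raise UndefinedIndexError("reciprocity undefined on an all-zero matrix")
    trans = values.T
    if mode == "minimum":
        paired = np.minimum(values, trans)
    elif mode == "maximum":
        paired = np.maximum(values, trans)
    elif mode == "geometric_mean":
        paired = np.sqrt(values * trans)
    else:
        raise ValueError(
            f"unknown reciprocity mode {mode!r}; expected one of "
            f"{RECIPROCITY_MODES}"
        )
    return float(paired[mask].sum() / total)


_FUNCS = {
    "acv": acv,
    "gini": gini,
    "inequality": inequality,
    "reciprocity": reciprocity,
}


def compute_index(M: FlowMatrix | np.ndarray, name: str, mode: str = "minimum") -> float:
    if name not in _FUNCS:
        raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    if name == "reciprocity":
        return reciprocity(M, mode=mode)
    return _FUNCS[name](M)


def index_series(
    systems: FlowPanel | Ensemble,
    which: Sequence[str] = INDEX_NAMES,
    mode: str = "minimum",
) -> pd.DataFrame:
    """Tidy long table of index values per year (and per draw for ensembles).

    Columns: ``year, source, draw, index, value``; ``source`` is
    ``observed`` for panels and ``simulated`` for ensemble draws, in
    which case ``draw`` is the draw id (observed rows carry ``draw=-1``).
    """
    bad = [w for w in which if w not in INDEX_NAMES]
    if bad:
        raise ValueError(f"unknown indices {bad}; expected subset of {INDEX_NAMES}")
    rows = []
    if isinstance(systems, FlowPanel):
        for year in systems.years:
            M = to_matrix(systems, year)
            for name in which:
                rows.append(
                    (year, "observed", -1, name, compute_index(M, name, mode))
                )
    elif isinstance(systems, Ensemble):
        for year in systems.years:
            block = systems.draws[year]
            for s in range(block.shape[0]):
                for name in which:
                    rows.append(
                        (
                            year,
                            "simulated",
                            s,
                            name,
                            compute_index(block[s], name, mode),
                        )
                    )
    else:
        raise TypeError(f"expected FlowPanel or Ensemble, got {type(systems)}")
    return pd.DataFrame(rows, columns=["year", "source", "draw", "index", "value"])


def ensemble_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Min / max / mean of simulated index values per (index, year)."""
    sim = series[series["source"] == "simulated"]
    if sim.empty:
        raise ValueError("no simulated rows to summarise")
    return (
        sim.groupby(["index", "year"])["value"]
        .agg(["min", "max", "mean"])
        .reset_index()
    )
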