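"""Core data model and I/O for bilateral flow panels and per-year flow matrices.

An origin-destination (OD) flow system records, for each ordered pair of
locations ``(i, j)`` and each year, the number of movers from *i* to *j*.
Two containers are used throughout the package:

``FlowPanel``
    long-format dyad-year records (one row per origin, destination, year)
    together with any dyadic predictor columns.  This is the estimation
    format: regressions run on the panel.
``FlowMatrix``
    the square OD matrix of a single year, with a structurally zero
    diagonal.  This is the format on which spatial indices are defined.

Flows are stored as nonnegative *reals*, not integers: empirical flow
estimates are frequently themselves model outputs (posterior means), and
row-calibrated simulated systems are non-integral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("migsim")

#: canonical column names of the long flow format
FLOW_COLUMNS = ("origin", "destination", "year", "flow")

#: fixed-effect / cluster dimensions recognised by model specifications
DIMENSIONS = ("origin", "destination", "year")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input table violates a structural invariant of the flow format."""


# ---------------------------------------------------------------------------
# FlowPanel
# ---------------------------------------------------------------------------


@dataclass
class FlowPanel:
    """Long-format bilateral flow panel.

    Parameters
    ----------
    data
        One row per (origin, destination, year).  Must contain the columns
        ``origin, destination, year, flow``; any further columns are treated
        as dyadic predictors.  Diagonal records (origin == destination) are
        not allowed.
    locations
        Ordered location labels.  Defaults to the lexicographically sorted
        labels occurring in ``data``; every matrix built from this panel
        uses this ordering.
    """

    data: pd.DataFrame
    locations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in FLOW_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"flow panel is missing columns: {missing}")
        df = self.data.copy()
        df["origin"] = df["origin"].astype(str)
        df["destination"] = df["destination"].astype(str)
        df["year"] = df["year"].astype(int)
        df["flow"] = df["flow"].astype(float)

        diag = df["origin"] == df["destination"]
        if diag.any():
            key = df.loc[diag, ["origin", "year"]].iloc[0]
            raise ValidationError(
                f"diagonal record(s) present (origin == destination), e.g. "
                f"({key['origin']}, {key['origin']}, {key['year']}); the OD "
                f"diagonal is structurally zero and must not appear"
            )
        if (df["flow"] < 0).any():
            bad = df.loc[df["flow"] < 0].iloc[0]
            raise ValidationError(
                f"negative flow for ({bad['origin']}, {bad['destination']}, "
                f"{bad['year']}): {bad['flow']}"
            )
        dup = df.duplicated(subset=["origin", "destination", "year"])
        if dup.any():
            bad = df.loc[dup, ["origin", "destination", "year"]].iloc[0]
            raise ValidationError(
                f"duplicate (origin, destination, year) key: "
                f"({bad['origin']}, {bad['destination']}, {bad['year']})"
            )

        observed = sorted(set(df["origin"]) | set(df["destination"]))
        if not self.locations:
            self.locations = observed
        else:
            extra = set(observed) - set(self.locations)
            if extra:
                raise ValidationError(
                    f"labels in data but not in the supplied ordering: {sorted(extra)}"
                )
            self.locations = list(self.locations)
        self.data = df.sort_values(["year", "origin", "destination"]).reset_index(
            drop=True
        )

    # -- basic accessors ----------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c not in FLOW_COLUMNS]

    @property
    def complete(self) -> bool:
        """True when every ordered dyad appears in every year."""
        n, t = self.n_locations, len(self.years)
        return len(self.data) == n * (n - 1) * t

    def total_flow(self, year: int | None = None) -> float:
        df = self.data if year is None else self.data[self.data["year"] == year]
        return float(df["flow"].sum())

    def outflow_totals(self, year: int) -> pd.Series:
        """Observed total outflow per origin for one year (calibration targets)."""
        sub = self.data[self.data["year"] == year]
        totals = sub.groupby("origin")["flow"].sum()
        return totals.reindex(self.locations, fill_value=0.0)


def read_flow_panel(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> FlowPanel:
    """Read a long-format flow CSV into a validated :class:`FlowPanel`.

    ``schema`` maps canonical names (``origin``, ``destination``, ``year``,
    ``flow``) to the column names actually used in the file.  Rows with
    ``origin == destination`` are rejected with their count reported.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    diag = df["origin"].astype(str) == df["destination"].astype(str)
    if diag.any():
        keys = df.loc[diag, ["origin", "destination", "year"]]
        first = keys.iloc[0]
        raise ValidationError(
            f"{path}: {int(diag.sum())} row(s) with origin == destination, "
            f"first offending key ({first['origin']}, {first['destination']}, "
            f"{first['year']})"
        )
    return FlowPanel(df)


def write_flow_panel(panel: FlowPanel, path: str | Path) -> None:
    """Write a panel back to CSV (canonical column order, UTF-8, header)."""
    cols = list(FLOW_COLUMNS) + panel.predictors
    panel.data[cols].to_csv(path, index=False)


def read_predictors(path: str | Path) -> pd.DataFrame:
    """Read a dyadic predictor CSV.

    Expected columns: ``origin, destination, year, <predictor...>``.  A file
    without a ``year`` column holds time-invariant predictors and is
    broadcast across years when merged.
    """
    df = pd.read_csv(path)
    for col in ("origin", "destination"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
        df[col] = df[col].astype(str)
    if "year" in df.columns:
        df["year"] = df["year"].astype(int)
    return df


def merge_predictors(panel: FlowPanel, predictors: pd.DataFrame) -> FlowPanel:
    """Attach a predictor table to a panel (left join on the dyad-year key).

    Time-invariant predictor tables (no ``year`` column) are broadcast to
    every year of the panel.
    """
    keys = ["origin", "destination"] + (["year"] if "year" in predictors else [])
    merged = panel.data.merge(predictors, on=keys, how="left", validate="m:1")
    return FlowPanel(merged, locations=panel.locations)


# ---------------------------------------------------------------------------
# FlowMatrix
# ---------------------------------------------------------------------------


@dataclass
class FlowMatrix:
    """Square OD matrix of a single year; rows are origins, columns destinations.

    The diagonal is structurally zero: staying in place is not a flow.
    """

    labels: list[str]
    values: np.ndarray
    year: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("diagonal cells must be exactly 0 (structural zeros)")
        off = self.values[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValidationError("off-diagonal cells must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_records(self) -> pd.DataFrame:
        """Flatten back to long format (off-diagonal cells only)."""
        n = len(self.labels)
        idx = ~np.eye(n, dtype=bool)
        rows, cols = np.nonzero(idx)
        return pd.DataFrame(
            {
                "origin": [self.labels[i] for i in rows],
                "destination": [self.labels[j] for j in cols],
                "year": self.year,
                "flow": self.values[rows, cols],
            }
        )


def to_matrix(panel: FlowPanel, year: int) -> FlowMatrix:
    """Assemble the OD matrix of one year from a panel.

    Missing dyads of an incomplete panel are filled as zero flows (with a
    warning): the uniform-benchmark denominators of the spatial indices
    require a full matrix.
    """
    if year not in panel.years:
        raise KeyError(f"year {year} not present in panel (has {panel.years})")
    labels = panel.locations
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    sub = panel.data[panel.data["year"] == year]
    if len(sub) < n * (n - 1):
        warnings.warn(
            f"panel is incomplete for year {year}: "
            f"{n * (n - 1) - len(sub)} missing dyad(s) filled as zero flow",
            stacklevel=2,
        )
    values = np.zeros((n, n))
    values[
        sub["origin"].map(pos).to_numpy(), sub["destination"].map(pos).to_numpy()
    ] = sub["flow"].to_numpy()
    return FlowMatrix(labels=list(labels), values=values, year=year)


def matrices_by_year(panel: FlowPanel) -> dict[int, FlowMatrix]:
    return {year: to_matrix(panel, year) for year in panel.years}


def read_matrix_csv(path: str | Path, year: int) -> FlowMatrix:
    """Read a wide matrix CSV (first column = origin label, rest = destinations)."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValidationError(f"{path}: row labels do not match column labels")
    return FlowMatrix(labels=labels, values=df.to_numpy(dtype=float), year=year)


def write_matrix_csv(matrix: FlowMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        path, index_label="origin"
    )


# ---------------------------------------------------------------------------
# ModelSpec
# ---------------------------------------------------------------------------

_TRANSFORMS = ("none", "log", "lag", "log_lag")


@dataclass
class ModelSpec:
    """Specification of a Poisson pseudo-likelihood flow regression.

    Parameters
    ----------
    predictors
        Mapping of predictor column name to transform: ``none`` (use as is),
        ``log`` (natural log), ``lag`` (value of the same dyad in year-1)
        or ``log_lag`` (log of the lagged value).  Records whose lag refers
        to a year outside the panel are dropped from estimation (logged,
        never imputed).
    fixed_effects
        Subset of ``(origin, destination, year)`` absorbed as dummy
        intercepts.
    clusters
        Cluster dimensions for the multiway-clustered covariance; empty
        means heteroskedasticity-robust (each record its own cluster).
    """

    predictors: dict[str, str] = field(default_factory=dict)
    fixed_effects: tuple[str, ...] = ("origin", "destination", "year")
    clusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, tr in self.predictors.items():
            if tr not in _TRANSFORMS:
                raise ValueError(
                    f"unknown transform {tr!r} for predictor {name!r}; "
                    f"expected one of {_TRANSFORMS}"
                )
        self.fixed_effects = tuple(self.fixed_effects)
        self.clusters = tuple(self.clusters)
        for dim in self.fixed_effects + self.clusters:
            if dim not in DIMENSIONS:
                raise ValueError(f"unknown dimension {dim!r}; expected {DIMENSIONS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            predictors=dict(raw.get("predictors", {})),
            fixed_effects=tuple(raw.get("fixed_effects", DIMENSIONS)),
            clusters=tuple(raw.get("clusters", ())),
        )

    def term_name(self, predictor: str) -> str:
        tr = self.predictors[predictor]
        return {"none": predictor, "log": f"log_{predictor}",
                "lag": f"lag_{predictor}", "log_lag": f"log_lag_{predictor}"}[tr]

    def build_design_frame(self, panel: FlowPanel) -> pd.DataFrame:
        """Apply transforms, returning the estimation frame.

        Lagged predictors align on (origin, destination, year-1); rows
        without a lag value (first panel year) are dropped with a log
        message.  The result carries ``flow`` plus one column per
        transformed term plus the key columns.
        """
        df = panel.data.copy()
        for name, tr in self.predictors.items():
            if name not in df.columns:
                raise SchemaError(f"predictor {name!r} not found in panel")
            if tr in ("lag", "log_lag"):
                lagged = df[["origin", "destination", "year", name]].copy()
                lagged["year"] = lagged["year"] + 1
                lagged = lagged.rename(columns={name: f"__lag_{name}"})
                df = df.merge(
                    lagged, on=["origin", "destination", "year"], how="left"
                )
                values = df[f"__lag_{name}"]
            else:
                values = df[name]
            if tr in ("log", "log_lag"):
                with np.errstate(divide="ignore", invalid="ignore"):
                    values = np.log(values.astype(float))
            df[self.term_name(name)] = values
        terms = [self.term_name(p) for p in self.predictors]
        before = len(df)
        df = df.dropna(subset=terms) if terms else df
        dropped = before - len(df)
        if dropped:
            logger.info(
                "dropped %d record(s) without a defined transform value "
                "(lagged terms have no year-1 reference in the first panel year)",
                dropped,
            )
        keep = ["origin", "destination", "year", "flow"] + terms
        return df[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


@dataclass
class PanelReport:
    n_records: int
    n_locations: int
    n_years: int
    expected_records: int
    complete: bool
    zero_flow_share: float
    per_year_totals: dict[int, float]


def validate_panel(panel: FlowPanel) -> PanelReport:
    """Pure structural summary of a panel (never raises, never mutates)."""
    n, t = panel.n_locations, len(panel.years)
    expected = n * (n - 1) * t
    n_rec = len(panel.data)
    zero_share = float((panel.data["flow"] == 0).mean()) if n_rec else 0.0
    totals = {
        int(y): float(g["flow"].sum()) for y, g in panel.data.groupby("year")
    }
    return PanelReport(
        n_records=n_rec,
        n_locations=n,
        n_years=t,
        expected_records=expected,
        complete=(n_rec == expected and n_rec > 0),
        zero_flow_share=zero_share,
        per_year_totals=totals,
    )
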