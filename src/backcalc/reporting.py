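"""Data loading, rate conversion, goodness-of-fit tables and sensitivity runs.

All tabular I/O is header-bearing delimited text; figures are replaced
by plain tables (observed-vs-expected cohort curves, lag-time
distributions) so everything is testable headless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimate import FitResult, FitSettings, PreObsRule, fit
from .model import (
    CountMatrix,
    ExpectedMatrix,
    ModelError,
    YearGrid,
    poisson_deviance_cells,
)
from .rates import Scenario, build_schedule

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSeries",
    "synthetic_population",
    "LoadResult",
    "load_records",
    "to_rates",
    "gof_cohort_curves",
    "mean_scaled_deviance",
    "lag_distributions",
    "run_sensitivity",
]


@dataclass(frozen=True)
class PopulationSeries:
    """Yearly reference-population counts (the rate denominator)."""

    grid: YearGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (self.grid.n_years,):
            raise ModelError("population series must cover every grid year")
        if np.any(arr <= 0):
            raise ModelError("population counts must be positive")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_frame(cls, grid: YearGrid, frame: pd.DataFrame) -> "PopulationSeries":
        f = frame.set_index("year").reindex(grid.years)
        if f["population"].isna().any():
            missing = grid.years[f["population"].isna().to_numpy()]
            raise ModelError(f"population missing for years {missing.tolist()}")
        return cls(grid, f["population"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.grid.years, "population": self.counts})


def synthetic_population(grid: YearGrid, start: float = 17.5e6, end: float = 21.5e6) -> PopulationSeries:
    """Synthetic smooth denominator series (a stand-in for census counts
    of a 10-44 age band, linear over the grid)."""
    return PopulationSeries(grid, np.linspace(start, end, grid.n_years))


def to_rates(h: Sequence[float], pop: PopulationSeries) -> np.ndarray:
    """Convert yearly person counts to rates per 1,000 population."""
    arr = np.asarray(h, dtype=float)
    if arr.shape != pop.counts.shape:
        raise ModelError("h series and population series differ in length")
    return 1000.0 * arr / pop.counts


@dataclass
class LoadResult:
    records: pd.DataFrame  # filtered individual rows
    counts: CountMatrix  # pooled
    strata: dict  # label -> CountMatrix (rows with missing stratum excluded)
    dropped: dict  # filter name -> rows removed


def load_records(
    path_or_frame,
    grid: YearGrid,
    *,
    sep: str = ",",
    onset_age_range: Optional[tuple[float, float]] = None,
    treatment_age_range: Optional[tuple[float, float]] = None,
) -> LoadResult:
    """Read individual (onset_year, treatment_year[, stratum][, ages]) records.

    Rows violating causality (treatment before onset) or with malformed
    years are rejected with their row numbers.  Window and optional age
    filters drop rows with a per-filter tally.  Rows with a missing
    stratum stay in the pooled matrix but are left out of stratified ones.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep=sep)
    if "onset_year" not in df.columns or "treatment_year" not in df.columns:
        raise ModelError("records need onset_year and treatment_year columns")

    for col in ("onset_year", "treatment_year"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced % 1 != 0)
        if bad.any():
            raise ModelError(f"malformed {col} in rows {df.index[bad][:10].tolist()}")
        df[col] = coerced.astype(int)

    bad = df["treatment_year"] < df["onset_year"]
    if bad.any():
        raise ModelError(
            f"treatment before onset in rows {df.index[bad][:10].tolist()}"
        )

    dropped: dict[str, int] = {}
    n0 = len(df)
    keep = (
        df["onset_year"].between(grid.first_onset_year, grid.last_year)
        & df["treatment_year"].between(grid.first_obs_year, grid.last_year)
    )
    dropped["outside_window"] = int((~keep).sum())
    df = df[keep]

    for name, col, rng_ in (
        ("onset_age", "onset_age", onset_age_range),
        ("treatment_age", "treatment_age", treatment_age_range),
    ):
        if rng_ is not None:
            if col not in df.columns:
                raise ModelError(f"age filter requested but column {col!r} absent")
            ok = df[col].between(*rng_)
            dropped[f"{name}_filter"] = int((~ok).sum())
            df = df[ok]

    if dropped:
        logger.info("load_records dropped rows: %s (of %d)", dropped, n0)

    counts = CountMatrix.from_records(
        grid, df["onset_year"].to_numpy(), df["treatment_year"].to_numpy()
    )
    strata: dict[str, CountMatrix] = {}
    if "stratum" in df.columns:
        labelled = df[df["stratum"].notna() & (df["stratum"].astype(str) != "")]
        for label, sub in labelled.groupby("stratum"):
            strata[str(label)] = CountMatrix.from_records(
                grid, sub["onset_year"].to_numpy(), sub["treatment_year"].to_numpy()
            )
    return LoadResult(records=df.reset_index(drop=True), counts=counts, strata=strata, dropped=dropped)


def gof_cohort_curves(counts: CountMatrix, mu: ExpectedMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs expected counts by onset cohort over the observation window.

    Returns ``(curves, summary)``: cell-level long table and a per-cohort
    summary with totals and Poisson deviance.  Cohorts with zero observed
    and zero expected mass are excluded from the curves.
    """
    grid = counts.grid
    mask = grid.observed_cell_mask()
    dev = poisson_deviance_cells(counts, mu)
    ii, jj = np.nonzero(mask)
    y0 = grid.first_onset_year
    curves = pd.DataFrame(
        {
            "onset_year": ii + y0,
            "treatment_year": jj + y0,
            "observed": counts.counts[ii, jj],
            "expected": mu.mu[ii, jj],
        }
    )
    summary = (
        curves.assign(deviance=dev[ii, jj])
        .groupby("onset_year", as_index=False)
        .agg(
            n_cells=("observed", "size"),
            observed_total=("observed", "sum"),
            expected_total=("expected", "sum"),
            deviance=("deviance", "sum"),
        )
    )
    nonempty = curves.groupby("onset_year")[["observed", "expected"]].sum().sum(axis=1) > 0
    keep_years = nonempty[nonempty].index
    curves = curves[curves["onset_year"].isin(keep_years)].reset_index(drop=True)
    return curves, summary


def mean_scaled_deviance(counts: CountMatrix, mu: ExpectedMatrix, min_expected: float = 5.0) -> float:
    """Mean per-cell Poisson deviance over observed cells with adequate
    expected counts (``mu >= min_expected``; the chi-square calibration
    breaks down for near-empty cells, whose deviance tends to zero under
    the model regardless of fit)."""
    mask = counts.grid.observed_cell_mask() & (mu.mu >= min_expected)
    if not mask.any():
        raise ModelError("no observed cells reach the minimum expected count")
    dev = poisson_deviance_cells(counts, mu)
    return float(dev[mask].mean())


def lag_distributions(
    source: Union[CountMatrix, ExpectedMatrix],
    cutoff_year: Optional[int] = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-cohort distribution of lag d = treatment year - onset year,
    conditional on treatment inside the window and strictly before
    ``cutoff_year`` (defaults to the last grid year, i.e. the final year
    is excluded).

    Returns a long table (onset_year, lag, mass) with masses summing to
    one within each cohort, plus the list of cohorts with no eligible
    cells.
    """
    grid = source.grid
    if cutoff_year is None:
        cutoff_year = grid.last_year
    if not (grid.first_onset_year <= cutoff_year <= grid.last_year):
        raise ModelError("cutoff_year must lie inside the grid")
    vals = source.counts if isinstance(source, CountMatrix) else source.mu
    mask = grid.cell_mask().copy()
    mask[:, : grid.index(grid.first_obs_year)] = False
    mask[:, grid.index(cutoff_year):] = False  # strictly before the cutoff
    rows = []
    empty: list[int] = []
    y0 = grid.first_onset_year
    for i in range(grid.n_years):
        cols = np.nonzero(mask[i])[0]
        if cols.size == 0:
            continue
        m = vals[i, cols].astype(float)
        tot = m.sum()
        if tot <= 0:
            empty.append(i + y0)
            continue
        for j, v in zip(cols, m / tot):
            rows.append((i + y0, int(j - i), v))
    df = pd.DataFrame(rows, columns=["onset_year", "lag", "mass"])
    return df, empty


def run_sensitivity(
    counts: CountMatrix,
    mortality: Sequence[float],
    scenarios: Sequence[Scenario],
    rule: PreObsRule = PreObsRule(),
    settings: Optional[FitSettings] = None,
    pop: Optional[PopulationSeries] = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit every scenario; per-scenario failures are logged, others proceed.

    Returns a long table (scenario, year, h_hat, p_hat, q_used[, rate])
    for overlay plotting plus the dict of FitResults by scenario name.
    """
    grid = counts.grid
    frames = []
    fits: dict[str, FitResult] = {}
    for sc in scenarios:
        try:
            leaving = build_schedule(grid, mortality, sc)
            res = fit(counts, leaving, rule, settings, scenario=sc)
        except ModelError as exc:
            logger.warning("scenario %s failed: %s", sc.name, exc)
            continue
        fits[sc.name] = res
        df = res.to_frame()
        df.insert(0, "scenario", sc.name)
        if pop is not None:
            df["rate"] = to_rates(res.params.h, pop)
        frames.append(df)
    if not frames:
        raise ModelError("every scenario failed")
    return pd.concat(frames, ignore_index=True), fits
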