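"""Core multi-state back-calculation model.

The model describes individual drug-use careers with three states on a
discrete yearly time axis: an *active use* state entered by unobserved
immigration, an absorbing *first treatment* state (the only observed
event), and an absorbing *exit* state (death or permanent cessation
before any treatment).  Writing ``h_t`` for the expected number of new
users in calendar year ``t``, ``p_t`` for the yearly probability that an
active user enters first-ever treatment, and ``q_t`` for the yearly
probability of exiting untreated, the expected number of people with
onset year ``i`` and first-treatment year ``j`` is

    mu_ij = h_i * prod_{k=i}^{j-1} (1 - p_k - q_k) * p_j     for j > i
    mu_ii = 0.5 * h_i * p_i

The same-year cell is half-weighted because people who start use during
year ``i`` are exposed for about half that year on average.  Cell counts
``N_ij`` are independent Poisson with means ``mu_ij``; first treatments
are only observable for ``j`` inside the registration window, so the
log-likelihood sums over those cells only:

    log L = sum_observed ( N_ij * log mu_ij - mu_ij )

(the data-only ``log N_ij!`` constant is dropped; it cannot affect
maximization or likelihood comparisons on fixed data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelError",
    "YearGrid",
    "CountMatrix",
    "LeavingSchedule",
    "ParameterVector",
    "ExpectedMatrix",
    "expected_counts",
    "log_likelihood",
    "poisson_deviance_cells",
]


class ModelError(ValueError):
    """Invalid model inputs (probability mass, grid mismatch, degenerate data)."""


@dataclass(frozen=True)
class YearGrid:
    """Consecutive calendar years with a right-hand observation window.

    Onset years run over the whole grid; first-treatment years are only
    observable in ``[first_obs_year, last_year]``.
    """

    first_onset_year: int
    first_obs_year: int
    last_year: int

    def __post_init__(self) -> None:
        if not (self.first_onset_year <= self.first_obs_year <= self.last_year):
            raise ModelError(
                f"require first_onset_year <= first_obs_year <= last_year, got "
                f"{self.first_onset_year}, {self.first_obs_year}, {self.last_year}"
            )

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_onset_year + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_onset_year, self.last_year + 1)

    @property
    def n_obs_years(self) -> int:
        return self.last_year - self.first_obs_year + 1

    @property
    def obs_years(self) -> np.ndarray:
        return np.arange(self.first_obs_year, self.last_year + 1)

    def index(self, year: int) -> int:
        if not (self.first_onset_year <= year <= self.last_year):
            raise ModelError(f"year {year} outside grid {self.first_onset_year}-{self.last_year}")
        return int(year - self.first_onset_year)

    def cell_mask(self) -> np.ndarray:
        """Boolean (T, T) mask of structurally possible cells (j >= i)."""
        T = self.n_years
        return np.triu(np.ones((T, T), dtype=bool))

    def observed_cell_mask(self) -> np.ndarray:
        """Cells that enter the likelihood: j >= i and j in the observation window."""
        mask = self.cell_mask()
        mask[:, : self.index(self.first_obs_year)] = False
        return mask


def _check_grid(a, b) -> None:
    if a.grid != b.grid:
        raise ModelError("objects are defined on different year grids")


def _as_grid_vector(grid: YearGrid, values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (grid.n_years,):
        raise ModelError(f"{name} must have one value per grid year ({grid.n_years}), got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CountMatrix:
    """Observed counts N_ij over onset year i (rows) x first-treatment year j (cols)."""

    grid: YearGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        T = self.grid.n_years
        if arr.shape != (T, T):
            raise ModelError(f"counts must be ({T}, {T}), got {arr.shape}")
        if np.any(arr < 0):
            raise ModelError("counts must be nonnegative")
        if np.any(arr[~self.grid.cell_mask()] != 0):
            raise ModelError("counts with treatment year before onset year must be zero")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @classmethod
    def from_records(cls, grid: YearGrid, onset_year, treatment_year) -> "CountMatrix":
        """Aggregate paired (onset, first-treatment) years; drops treatment years
        outside the observation window (unobservable cells)."""
        i = np.asarray(onset_year, dtype=int)
        j = np.asarray(treatment_year, dtype=int)
        if i.shape != j.shape:
            raise ModelError("onset and treatment year arrays differ in length")
        if np.any(j < i):
            bad = np.nonzero(j < i)[0]
            raise ModelError(f"treatment before onset in rows {bad[:10].tolist()}")
        T = grid.n_years
        keep = (
            (i >= grid.first_onset_year)
            & (i <= grid.last_year)
            & (j >= grid.first_obs_year)
            & (j <= grid.last_year)
        )
        counts = np.zeros((T, T), dtype=np.int64)
        np.add.at(counts, (i[keep] - grid.first_onset_year, j[keep] - grid.first_onset_year), 1)
        return cls(grid, counts)

    @property
    def observed_total(self) -> int:
        return int(self.counts[self.grid.observed_cell_mask()].sum())

    def to_frame(self) -> pd.DataFrame:
        """Long format: onset_year, treatment_year, count (observable cells only)."""
        mask = self.grid.observed_cell_mask()
        ii, jj = np.nonzero(mask)
        y0 = self.grid.first_onset_year
        return pd.DataFrame(
            {
                "onset_year": ii + y0,
                "treatment_year": jj + y0,
                "count": self.counts[ii, jj],
            }
        )

    @classmethod
    def from_frame(cls, grid: YearGrid, frame: pd.DataFrame) -> "CountMatrix":
        T = grid.n_years
        counts = np.zeros((T, T), dtype=np.int64)
        i = frame["onset_year"].to_numpy(dtype=int) - grid.first_onset_year
        j = frame["treatment_year"].to_numpy(dtype=int) - grid.first_onset_year
        counts[i, j] = frame["count"].to_numpy(dtype=np.int64)
        return cls(grid, counts)


@dataclass(frozen=True)
class LeavingSchedule:
    """Yearly exit probability q_t split into mortality and cessation components."""

    grid: YearGrid
    mortality: np.ndarray
    cessation: np.ndarray

    def __post_init__(self) -> None:
        m = _as_grid_vector(self.grid, self.mortality, "mortality")
        c = _as_grid_vector(self.grid, self.cessation, "cessation")
        if np.any(m < 0) or np.any(c < 0):
            raise ModelError("mortality and cessation rates must be nonnegative")
        if np.any(m + c >= 1.0):
            bad = self.grid.years[m + c >= 1.0]
            raise ModelError(f"q_t = mortality + cessation must be < 1; violated in {bad.tolist()}")
        object.__setattr__(self, "mortality", m)
        object.__setattr__(self, "cessation", c)

    @property
    def q(self) -> np.ndarray:
        return self.mortality + self.cessation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.grid.years,
                "mortality": self.mortality,
                "cessation": self.cessation,
                "q": self.q,
            }
        )

    @classmethod
    def from_frame(cls, grid: YearGrid, frame: pd.DataFrame) -> "LeavingSchedule":
        f = frame.set_index("year").reindex(grid.years)
        if f["mortality"].isna().any() or f["cessation"].isna().any():
            raise ModelError("schedule file does not cover every grid year")
        return cls(grid, f["mortality"].to_numpy(), f["cessation"].to_numpy())


@dataclass(frozen=True)
class ParameterVector:
    """Yearly incidence h_t (persons/year) and registration probability p_t."""

    grid: YearGrid
    h: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        h = _as_grid_vector(self.grid, self.h, "h")
        p = _as_grid_vector(self.grid, self.p, "p")
        if np.any(h < 0):
            raise ModelError("h_t must be nonnegative")
        if np.any((p < 0) | (p >= 1)):
            raise ModelError("p_t must lie in [0, 1)")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "p", p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.grid.years, "h": self.h, "p": self.p})


@dataclass(frozen=True)
class ExpectedMatrix:
    """Expected counts mu_ij on the same cell layout as :class:`CountMatrix`."""

    grid: YearGrid
    mu: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.mu, dtype=float)
        T = self.grid.n_years
        if arr.shape != (T, T):
            raise ModelError(f"mu must be ({T}, {T}), got {arr.shape}")
        if np.any(arr < 0):
            raise ModelError("mu must be nonnegative")
        object.__setattr__(self, "mu", arr)

    def to_frame(self) -> pd.DataFrame:
        mask = self.grid.observed_cell_mask()
        ii, jj = np.nonzero(mask)
        y0 = self.grid.first_onset_year
        return pd.DataFrame(
            {"onset_year": ii + y0, "treatment_year": jj + y0, "mu": self.mu[ii, jj]}
        )


def _survival_factors(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    s = 1.0 - p - q
    if np.any(s < 0):
        bad = np.nonzero(s < 0)[0]
        raise ModelError(
            f"1 - p - q is negative at year index(es) {bad.tolist()}; "
            "p_t + q_t must not exceed 1"
        )
    return s


def _mu_matrix(h: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Dense (T, T) matrix of mu_ij; zero below the diagonal.

    Uses cumulative products: the survival factor from i to j-1 is
    C_j / C_i with C_k = prod_{m<k} (1 - p_m - q_m).
    """
    s = _survival_factors(p, q)
    T = h.shape[0]
    if np.all(s > 0):
        C = np.empty(T + 1)
        C[0] = 1.0
        np.cumprod(s, out=C[1:])
        surv = C[None, :T] / C[:T, None]  # surv[i, j] = prod_{k=i}^{j-1} s_k for j >= i
    else:
        # a year with p + q == 1 zeroes later survival; avoid 0/0 by direct products
        surv = np.zeros((T, T))
        for i in range(T):
            surv[i, i] = 1.0
            surv[i, i + 1 :] = np.cumprod(s[i : T - 1])
    mu = h[:, None] * surv * p[None, :]
    mu[np.tril_indices(T, k=-1)] = 0.0
    mu[np.diag_indices(T)] *= 0.5
    return mu


def expected_counts(params: ParameterVector, leaving: LeavingSchedule) -> ExpectedMatrix:
    """Expected cell counts mu_ij under (h, p) and the exit schedule q.

    Raises :class:`ModelError` if any ``1 - p_k - q_k`` is negative (the
    survival factor would be meaningless); no silent clamping.
    """
    _check_grid(params, leaving)
    mu = _mu_matrix(params.h, params.p, leaving.q)
    return ExpectedMatrix(params.grid, mu)


def log_likelihood(counts: CountMatrix, mu: ExpectedMatrix) -> float:
    """Poisson log-likelihood over observed cells, up to the data-only N! constant.

    Cells with ``N = 0`` and ``mu = 0`` contribute exactly 0 (continuous
    extension of ``N log mu``).  A positive count with zero expectation
    makes the likelihood zero; that is reported as an error naming the cell.
    """
    _check_grid(counts, mu)
    mask = counts.grid.observed_cell_mask()
    N = counts.counts[mask].astype(float)
    m = mu.mu[mask]
    bad = (N > 0) & (m == 0.0)
    if np.any(bad):
        ii, jj = np.nonzero(mask)
        k = np.nonzero(bad)[0][0]
        y0 = counts.grid.first_onset_year
        raise ModelError(
            f"observed count {int(N[k])} in cell (onset {ii[k] + y0}, "
            f"treatment {jj[k] + y0}) has zero expected value; log-likelihood is -inf"
        )
    pos = N > 0
    ll = float(np.sum(N[pos] * np.log(m[pos])) - np.sum(m))
    return ll


def poisson_deviance_cells(counts: CountMatrix, mu: ExpectedMatrix) -> np.ndarray:
    """Per-cell Poisson deviance 2[N log(N/mu) - (N - mu)] over observed cells.

    Returned as a dense (T, T) array, zero outside observed cells.  The
    N = 0 cell contributes ``2 mu``; the saturated fit (mu = N) gives 0.
    """
    _check_grid(counts, mu)
    mask = counts.grid.observed_cell_mask()
    N = counts.counts.astype(float)
    m = mu.mu
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(N > 0, N * np.log(np.where(N > 0, N, 1.0) / np.where(m > 0, m, np.nan)), 0.0)
    dev = 2.0 * (term - (N - m))
    dev = np.where(mask, dev, 0.0)
    if np.any(np.isnan(dev[mask])):
        raise ModelError("positive count with zero expected value; deviance undefined")
    return dev
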