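# Methods

## Model and assumptions

`backcalc` treats a drug-use career as a three-state process on a yearly
calendar grid: *active use* (entered by immigration), *first treatment*
(absorbing; the only observed event), and *exit before treatment*
(absorbing; death or permanent cessation, unobserved). For onset year
`i` and first-treatment year `j`,

    mu_ij = h_i * prod_{k=i}^{j-1} (1 - p_k - q_k) * p_j   for j > i,
    mu_ii = 0.5 * h_i * p_i,

with `h_t` the expected number of new users (persons/year), `p_t` the
yearly probability that an active user enters first-ever treatment
(assumed independent of the onset era), and `q_t` the yearly exit
probability, assumed known. Counts `N_ij` are independent Poisson, so

    log L = sum over observed cells of ( N_ij log mu_ij - mu_ij ),

dropping the data-only `log N_ij!` term; this shifts the log-likelihood
by a constant that cannot affect maximization or likelihood comparisons
on fixed data. "Observed cells" are all pairs with
`first_onset_year <= i <= j` and `j` inside
`[first_obs_year, last_year]`; treatments outside the window are
structurally invisible (right truncation) and — because the observed
cells are independent Poisson thinnings of the onset process — the
observed-cell product *is* the full likelihood of the observable data;
no extra censoring term exists.

Key conventions:

- Years are integral calendar years; the lag is `j - i` whole years.
- The half-weight applies only to the `i = j` cell (about half a year of
  exposure in the onset year), never to survival factors.
- Cells with `N = 0` and `mu = 0` contribute exactly 0 (continuous
  extension); a positive count with zero expectation is an error, not a
  silent `-inf`.

## Identifiability: the exact likelihood ridge

The map `(h, p) -> mu` is not injective. For any feasible scalar
`r0 > 0`, the transformation

    p'_k = p_k / r_k,   h'_k = h_k * r_k,
    r_{k+1} = r_k * (1 - p'_k - q_k) / (1 - p_k - q_k),

run over the observation window with `r = r0` at the first observed
year — together with re-linking the pre-window ramp to the transformed
link value and rescaling pre-window `h` to absorb the changed pre-window
survival — leaves **every** `mu_ij` unchanged, hence the likelihood of
any dataset. (`estimate.ridge_member` constructs members explicitly;
a regression test verifies `mu` agreement to 1e-10, and the Jacobian of
the cell map has exactly one vanishing singular value.)

Consequences:

- Fitted counts, deviances, cohort curves and lag distributions are
  identified and safe to interpret from any fit.
- The split of the data into "incidence" and "registration probability"
  is *not* identified by the data alone. Knowing `p_t` in a single year
  pins the entire family (the recursion above is invertible in both
  directions), so the package exposes `FitSettings(fixed_p={year: value})`
  as the minimal identifying device; the natural choice is the first
  observed year, where external information (survey, clinic capacity) is
  most likely to exist.
- Without an anchor, `fit` still runs (the default mirrors the method as
  usually described) and returns *a* ridge point selected by the
  optimizer path from the documented start — reproducible, but the
  `h`/`p` values carry no information beyond their identified
  functionals, and bootstrap bands for them mix sampling noise with
  drift along the ridge.

## Estimation

The likelihood is maximized by L-BFGS-B on transformed parameters:
`log h_t` for every grid year and a scaled logit of `p_t`
(`p = (1 - q) * sigmoid(b)`) for window years, enforcing `h >= 0` and
`0 <= p <= 1 - q` smoothly. The gradient is analytic (a finite-difference
test verifies it): with `D_ij = N_ij - mu_ij` over observed cells,

    dL/d log h_i = sum_j D_ij,
    dL/d p_m     = (sum_i D_im)/p_m - (sum over cells crossing year m of D_ij)/(1 - p_m - q_m),

with an extra chain-rule term at the link year for the pre-window ramp.

- **Pre-window rule**: `p_t` equals a flat level (default 0.01) through
  `flat_until` (default 1981), then rises linearly to the *current*
  value of `p` at the first observed year. The linkage lives inside the
  objective so the assumption and the estimate stay consistent at every
  iteration; a two-stage variant (fit, freeze the ramp at the fitted
  link value, refit) exists behind `FitSettings(two_stage=True)` for
  comparison.
- **Start**: `h` from observed treatments per cohort inflated by
  `1/p_init` (default `p_init = 0.1`), flat `p_init` for `p`. On
  identified (anchored) problems any start reaches the same optimum
  (tested with 5 random restarts).
- **Convergence**: relative log-likelihood change below `tol`
  (default 1e-9), projected gradient below `gtol` (1e-8), at most
  10,000 iterations; non-convergence is reported with the best point,
  never raised.
- **Weak identification at the grid's end** is intrinsic: the final
  onset year is informed only by its same-year cell, and the last few
  `p_t` enter few cells. The fit flags cohorts with fewer observed
  treatments than `weak_threshold` (default 50) instead of smoothing —
  no penalty is added, matching the method as described. At realistic
  register scale the inverse Fisher information puts the relative
  standard deviation of `h_hat` near 10% already 3 years before the end
  of the window; estimates there should be read with the bootstrap
  bands, not as point values.

## Exit-rate schedules

Mortality among untreated users is known only in fragments: roughly 1%
in the early 1970s rising smoothly to 1.4% by 1984/85, a 6.6% peak in
1995, 1.5% in 1999 and 1% by 2006. The default schedule linearly
interpolates these anchor points (flat outside) — linearity is the
minimal assumption where no functional form is stated — and every fit
records the full schedule used so a better series can be substituted.
The non-injecting stratum uses a constant 1%. Cessation is a constant
yearly rate in 0.02–0.04. The four standard sensitivity scenarios cross
cessation {0.04, 0.02} with a mortality offset {+0, +0.01}; the
(0.04, +0) pair is the primary analysis. Stratified analyses (e.g. by
route of administration) are independent fits on the stratified count
matrices, differing only in the mortality series.

## Bootstrap

Each of `n_resamples` (default 500) replicates: (1) resamples the
individual records with replacement (same total; a multinomial
cell-resampling fallback, logged as a deviation, serves aggregate-only
input), and (2) redraws the flat pre-window `p` level and the constant
cessation rate from gamma distributions moment-matched to their
best-guess means with standard deviation `assumption_sd` (default 0.01;
`shape = mean^2/sd^2`, `scale = sd^2/mean`). The perturbed flat level
re-links the ramp to each replicate's own estimated link value; the
cessation draw applies to all years (it is a single constant); mortality
is not perturbed. Failed or non-converged replicates are counted and
excluded — not retried — keeping the replicate set i.i.d. Bands are
yearly percentile intervals (the minimal reading of bootstrap CIs; no
BCa correction) across converged replicates; rate conversion against a
fixed population denominator commutes with percentile-taking, so bands
may be converted either before or after.

## Synthetic register

`synthetic_epidemic_spec()` emulates a national treatment register at
realistic scale (all values synthetic): a 1971–2006 grid observed from
1991; onsets following an asymmetric Gaussian peaking at 28,000/year in
1987 (standard deviations 5 years rising, 6.5 falling), which against
the synthetic 17.5–21.5 million reference population gives a peak rate
near 1.5 per 1,000 and ~150,000 observed records; registration
probability rising linearly 0.08 to 0.30 over the window and following
the flat-plus-ramp rule before it; exits from the default mortality
schedule plus 0.04 cessation.

The simulator draws Poisson cohort sizes and per-year multinomial
transitions. In the onset year the *matched* convention is used: treated
with probability `0.5 p_i`, surviving with `1 - p_i - q_i`, exiting with
the residual `q_i + 0.5 p_i` — the only assignment whose cell means equal
the expected-count formula exactly (verified against `expected_counts`
at 4 Monte-Carlo standard errors over 5,000 replicates). The alternative
(exit exactly `q_i`) is available behind a flag but is inconsistent with
the product formula for `j > i`. An optional, off-by-default corruption
snaps a fraction of reported onset years to years ending in 0 or 5
(digit preference seen in real registers); the estimator never models it.

What the generator does *not* emulate — and hence what passing tests do
not establish about real registers: reporting error in onset year (other
than the optional digit preference), private-treatment undercoverage,
era-dependent registration probability, within-year timing, relapse and
re-treatment dynamics, age structure.

## Goodness of fit

Observed and expected counts are tabulated per onset cohort over the
window, with per-cohort Poisson deviance
(`2[N log(N/mu) - (N - mu)]`, `2 mu` at `N = 0`; exactly 0 when
saturated). The scalar calibration statistic is the mean per-cell
deviance over cells with fitted expectation at least 5 (default): under
the model it sits near `1 - k/n` (parameters per cell), and near-empty
cells are excluded because their deviance tends to 0 under the model
regardless of fit, which would mask misfit. Lag-time distributions
(mass over `j - i` per cohort, conditional on treatment before a cutoff
that defaults to excluding the final grid year) are computed identically
from observed counts and fitted expectations for overlay.

## Problem sizes used in the tests

Unit tests run on 3–10-year grids; the end-to-end recovery and
goodness-of-fit checks use the full 36-year register-scale generator
(single fits take ~20 ms); the bootstrap coverage study uses a 10-year
toy with 50 outer simulations of 200 replicates each, sizes chosen to
make Monte-Carlo noise small relative to the tolerances being asserted.

## Known limitations

- Incidence and registration probability are jointly identified only up
  to the exact ridge described above; all point estimates of the split
  require an external anchor, and analyses without one should interpret
  only fitted-count functionals.
- Exit rates are assumed known; errors in them propagate directly into
  incidence levels (the sensitivity scenarios bound this, and the
  bootstrap perturbs cessation, but mortality mis-specification is not
  otherwise quantified).
- No age structure, within-year resolution, or relapse states.
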