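# backcalc

Multi-state back-calculation of hidden onset incidence from
first-registration data.

## The problem

Many onset processes — the motivating case is heroin use — are never
observed directly. What a surveillance system sees is a later, single
event per person: the year of *first* treatment, recorded only inside an
observation window (e.g. a national register covering 1991–2006), while
people may have started use decades earlier. People can also leave the
process before ever registering, through death or permanent cessation.
`backcalc` estimates the yearly number of new users ("incidence") from
pairs of (onset year, first-treatment year), under assumed yearly exit
rates, for epidemiologists and public-health analysts working with
treatment-register or similar first-event data.

## The model

A person enters the *active use* state in year `i` (immigration, Poisson
with yearly mean `h_i`), then each year either enters first treatment
(probability `p_t`, assumed common across onset cohorts), exits
untreated (probability `q_t` = mortality + cessation, assumed known), or
stays. The expected count with onset `i` and first treatment `j` is

    mu_ij = h_i * prod_{k=i}^{j-1} (1 - p_k - q_k) * p_j     (j > i)
    mu_ii = 0.5 * h_i * p_i

(the same-year cell is half-weighted: on average half a year of
exposure). Cell counts `N_ij` are independent Poissons and only cells
with `j` inside the observation window enter the log-likelihood
`sum N_ij log mu_ij - mu_ij`. Maximizing it over all yearly `h_t` and
the window-years `p_t` (with pre-window `p_t` fixed by a documented
flat-plus-ramp assumption linked to the first estimated value) is the
back-calculation fit. Bootstrap uncertainty combines record resampling
with gamma-perturbed assumption parameters; sensitivity runs repeat the
fit under four cessation/mortality combinations.

**Identifiability.** The likelihood determines `(h, p)` jointly only up
to an exact one-parameter family (`backcalc.estimate.ridge_member`
constructs it). Fitted counts, deviances and lag distributions are
identified; the `h`/`p` split is not, until the registration probability
is pinned in at least one year from external information
(`FitSettings(fixed_p={year: value})`). See `docs/methods.md`.

## Worked example

```python
import numpy as np
import backcalc as bc

spec = bc.synthetic_epidemic_spec(seed=1)          # 1971-2006 grid, window 1991-2006
table = bc.simulate(spec)                          # individual careers
counts = table.count_matrix()                      # observed N_ij
print(f"observed first-treatment records: {counts.observed_total}")

anchor = {1991: 0.08}                              # external info pins the gauge
res = bc.fit(counts, spec.leaving, bc.PreObsRule(), bc.FitSettings(fixed_p=anchor))
pop = bc.synthetic_population(spec.grid)
rates = bc.to_rates(res.params.h, pop)
k = int(np.argmax(rates))
print(f"log-likelihood {res.loglik:.1f} after {res.n_iterations} iterations")
print(f"peak incidence {rates[k]:.2f} per 1,000 in {spec.grid.years[k]}")
print(f"registration probability {res.params.p[spec.grid.index(1991)]:.2f} (1991) "
      f"-> {res.params.p[-1]:.2f} (2006)")
```

prints

```
observed first-treatment records: 158046
log-likelihood 872155.8 after 74 iterations
peak incidence 1.48 per 1,000 in 1987
registration probability 0.08 (1991) -> 0.21 (2006)
```

The synthetic register emulates a national epidemic that rises through
the late 1970s, peaks in 1987 and declines; the fit recovers the peak
year and level (truth: 28,000 onsets/year ≈ 1.5 per 1,000 of the
reference population) and the rising registration probability from the
first-treatment counts alone.

The same pipeline is available from the shell:

```
backcalc simulate --seed 1 -o records.csv
backcalc fit --records records.csv -o estimates.csv --meta run.txt
backcalc bootstrap --records records.csv --n-resamples 500 -o bands.csv
backcalc sensitivity --records records.csv -o scenarios.csv
backcalc gof --records records.csv --curves curves.csv --lags lags.csv
```

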