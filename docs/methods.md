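# Methods

## The model

`bedbugsim` couples a rental market to a pest-infestation process. The unit
of infection is a rental unit; units are susceptible (S, bug-free) or
infested (I), and renter-occupied (r) or vacant (v). The closed market has
four compartments — Sr, Ir, Sv, Iv — with total N conserved. Tenants move
out of occupied units at rate m (per year), or b·m when the unit is
infested (b ≥ 1, the *vacancy multiplier*); they move into vacant units at
rate n. Infested units complete treatment at rate γ, so 1/γ is the mean
infestation duration. New infestations arise two ways:

* **infectious transmission** — an occupied susceptible unit acquires bugs
  at rate β·Ir/N (visits, shared objects, deliveries);
* **relocation transmission** — a tenant arriving from an infested unit
  seeds the unit they move into with probability k. The fraction of movers
  coming from infested units is f(t) = b·Ir/(Sr + b·Ir) (infested units
  shed tenants b times faster).

The no-disclosure dynamics are

```
dSr/dt = −βSrIr/N + γIr + n(1−k f)Sv − mSr
dIr/dt =  βSrIr/N + k f n Sv + nIv − (γ+bm)Ir
dSv/dt =  mSr + γIv − nSv
dIv/dt =  bmIr − (γ+n)Iv
```

Under a **disclosure policy**, vacant infested units (Iv) are flagged, and a
treated vacant unit enters a fifth class Svp (susceptible-vacant-disclosed)
that keeps the flag for a mean period D (return flow Svp→Sv at rate 1/D).
Renters discount flagged units: move-ins to Iv and Svp occur at rate
(1−s)·n, where s ∈ [0,1] is the *renter selectivity* (s=0: no behavioural
change, and the model reduces exactly to the base model on (Sr, Ir, Sv+Svp,
Iv); s=1: full quarantine). Treated *occupied* units return to Sr unflagged
— disclosure attaches to the vacancy spell, a simplification inherited from
the model structure.

States are continuous occupancies (mean-field). Time is in **years**
everywhere; the 6-month mean infestation duration is γ = 2/year, and the
monthly vacancy cost enters the accounting through an explicit factor 12.

## Calibration

β is not observable. Assuming the observed baseline prevalence p is the
endemic equilibrium of the no-disclosure market, the stationarity conditions
dIv = 0 and dSv = 0, with (Ir+Iv)/N = p and conservation, give the
equilibrium in closed form:

```
Ir* = N p (γ+n)/(bm+γ+n)          Iv* = N p bm/(bm+γ+n)
Sr* = N/(m+n) · [n(1−p) − p m b γ/(bm+γ+n)]
Sv* = N(1−p) − Sr*
```

and dIr = 0 then yields

```
β = N/(Sr* Ir*) · [(γ+bm)Ir* − k f* n Sv* − n Iv*],   f* = bIr*/(Sr*+bIr*).
```

At the defaults (p=5%) β ≈ 2.2573/year. If the bracket is non-positive
(relocation transmission alone more than sustains p — possible only under
extreme mover traffic), a `CalibrationError` is raised rather than returning
a negative β. A numeric root-finder (`calibrate_beta_numeric`) cross-checks
the closed form in the tests to 1e−10. Every analysis that changes a
structural parameter (sensitivity sweeps, migration) recalibrates β to the
same baseline prevalence *after* the change, so comparisons ask "given the
same observed prevalence, how do predictions differ?".

## Reproductive ratio

The next-generation matrix of the disclosure model linearized at the
disease-free market balance (Sr = Nn/(n+m), Sv = Nm/(n+m)) has new
infestations entering Ir only, at rate β·n/(n+m) (infectious route) plus
k·b·m (relocation route) per infested-occupied unit; the transition matrix
couples Ir and Iv through vacancy and return. The spectral radius is

```
R0 = (β·n/(n+m) + k·b·m) · (γ + (1−s)n) / (γ·(γ + bm + (1−s)n)).
```

The second factor is the mean time a unit stays infested (including the
vacancy detour, which selectivity prolongs in quarantine but removes from
circulation); R0 does not depend on D. `r0_ngm_numeric` computes the same
quantity by building F and V explicitly and taking the spectral radius of
F·V⁻¹; the two agree to 1e−8 across the parameter ranges (property test).
One grouping choice in this expression is easy to get wrong — whether
n/(n+m) also multiplies the k·b·m term. The NGM derivation fixes it (it
does not: the relocation route is seeded by the move-in flow n acting on
the vacant share m/(n+m), which cancels to k·b·m). With β calibrated to the
5% baseline, R0 = 1.05 at s = 0 and ≈ 0.86 at s = 1; the alternative
grouping, or rounding the calibrated β first, yields slightly different
full-quarantine values (≈ 0.88 is sometimes quoted), so the s = 1 figure
should not be used as a reference value.

## Cost accounting

Both models run from the calibrated no-disclosure equilibrium (disclosure
run: Svp(0) = 0, the equilibrium Iv units are immediately flagged). Three
event accumulators are integrated as extra ODE components in the same solve
(LSODA, rtol 1e−8, atol 1e−10·N), rather than by post-hoc quadrature:
treatments ∫γ(Ir+Iv)dt/N, turnovers ∫n(Sv+(1−s)(Svp+Iv))dt/N, and vacant
unit-years ∫(Sv+Svp+Iv)dt/N. The comparator (no-disclosure) run uses the
same integrator settings so discretization bias cancels in differences.

Policy year y is the interval [y−1, y] after the policy starts (reports are
1-based; the underlying cost-integral convention indexes the first year as
year 0, and `savings_onset_year` = `break_even_year` − 1 reports that
0-based index, i.e. the whole years elapsed before annual savings begin).
Annual component costs are accumulator increments priced at c_trt = $1,225
per treatment, c_tov = $1,000 per turnover, and 12·c_vac per vacant
unit-year (c_vac = $1,000 is the *monthly* rent), disclosure minus
comparator, per unit. The headline cost curve is the running average
`average_cost_to_date` (cumulative total divided by years elapsed), which
peaks at about $25/unit after two years at the defaults; the annual bars
peak at $26.6 in year 2 and first turn negative (savings) in year 5.
Discounting multiplies year-y entries by (1+r)^(−y) and rebuilds the
cumulative series.

## Migration extension

The open-population variant keeps units closed but lets a fraction i of
incoming tenants originate in external markets with net prevalence e. The
seeding probability of a move-in becomes k·[(1−i)·f(t) + i·e_mover] with
e_mover = b·e/(1−e+b·e) — the external analogue of f: movers out of
infested units are overrepresented by the same factor b. Design choices
here were genuinely open (the coupled formulation is not fully specified by
the main description); two were pinned down as follows and isolated in
`bedbugsim.migration`:

* **mover-weighting of e** (vs. using e raw): an immigrant is by definition
  someone who just vacated an external unit, so the mover-weighted form is
  the consistent reading. The two forms differ modestly (10-year prevalence
  3.67% vs. 3.55% at (i, e) = (0.2, 0.2)).
* **calibration on the open system**: the pre-policy 5% equilibrium belongs
  to the market *with* immigration, so β is calibrated with the mixture
  seeding at s = 0; the comparator run is the open-population system with
  s = 0, which is stationary by construction.

At the corner (i, e) = (0.4, 0.2) — outside the published scan lines —
annual savings do not arrive within 20 years under this formulation.

## Stochastic oracle

`gillespie_run` simulates the exact jump process whose propensities are the
disclosure-model flow terms, with relocation seeding resolved per move-in by
one uniform draw against k·f at the current state (the instantaneous-
probability reading of the mean-field term). The direct method is used;
at the market sizes of interest (N ≤ 10⁶) tau-leaping is unnecessary. Runs
are deterministic in the seed, conserve N exactly on integers, and their
replicate means converge to the ODE prevalence as N grows (tested at
N = 10³…10⁵ with a handful of replicates per size — enough to order the
errors, not to estimate them precisely). Near R0 ≈ 1 small markets show a
real elimination probability that the deterministic model cannot: this is
demographic noise, not a disagreement.

## Synthetic conditions and what the tests do not show

There is no external data: all inputs are the point estimates (p = 5%,
s = 0.5, 1/γ = 6 mo, k = 0.3, b = 1.3, m = 0.5/y, n = 6/y, D = 1 y,
N = 1000, costs $1,225/$1,000/$1,000) and the stated ranges around them.
The model assumes homogeneous units, homogeneous mixing, constant rents (no
price response to disclosure), no seasonality, and exponentially distributed
durations throughout. Passing tests therefore validate the mathematics and
the accounting, not the realism of any particular market; the decomposition
into structured subpopulations (run as independent parameter sets — valid
because per-unit results are provably independent of N) only brackets, and
does not model, real heterogeneity.

## Numerical choices

* LSODA with rtol 1e−8, atol 1e−10·N; reporting grid includes every integer
  year; negative compartments beyond 1e−6·N abort the run.
* `relocation_fraction` is defined as 0 at the empty-market state
  Sr = Ir = 0, keeping the vector field total.
* p = 0 calibrates to β = 0 (disease-free market) instead of erroring, so
  sweep grids can include the axis.
* Threshold classification returns a `boundary` flag within 1e−6 of
  R0 = 1 rather than forcing a side.
* Default sweep resolution (CLI) is 25×25, chosen to keep a full grid under
  a couple of minutes on one CPU; resolution is configurable.

## Known limitations

The treatment-cost channel scales with γ: at a fixed prevalence, slower
treatment means fewer completed treatments per year, so lengthening the
mean infestation duration *reduces* annual treatment savings under this
accounting — the dominant effect in the duration sensitivity. Renter-side
costs, fixed-length (non-exponential) disclosure periods, two-way coupled
markets, and emigration of infested tenants out of the system are out of
scope.
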