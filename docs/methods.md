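# Methods

## Data model

A cohort is a case listing: sex, age and calendar year at diagnosis,
follow-up time in years, and an outcome class (`alive`, `dead_cancer`,
`dead_other`).  Cohort selection uses ICD-O-3 codes (melanoma morphologies
8720–8790 at uveal sites C69.2/C69.3/C69.4).  Follow-up recorded as whole
months is converted to years; a recorded zero is set to half a month, since
zero-length follow-up breaks product-limit estimators (the convention is
flagged in logs).  Background mortality is a period life table m(sex, age,
year) on single-year Lexis cells, read from the Human Mortality Database
Mx_1x1 text dialect or synthesised as Gompertz–Makeham,
m(age) = a + b·e^{c·age}, with an optional geometric secular decline per
calendar year.

Rates are treated as hazards, not annual death probabilities: survival over
a duration d inside one cell is exp(−m·d).  This makes expected-death
integration exact and additive over Lexis splits.  Lookups clamp — ages above
the open "110+" group return the top-group rate, calendar years outside the
table return the nearest boundary year — so follow-ups of four decades
remain computable past the table's edge.

## The five estimators

**Raw proportion.**  o_cancer/(o_cancer + o_other + n_projected), where the
projection assumes everyone still alive dies of other causes.  Simple, but
censoring-naive and COD-dependent.

**1 − MFS.**  Kaplan–Meier with other-cause deaths censored (time to
metastasis proxied by time of cancer death).  Because the injected excess
hazard is shared across subjects, the cause-specific KM consistently
estimates net survival exp(−∫h); 1 − MFS at its late plateau is the net
lifetime risk.  Greenwood variance, 95% CI on the log(−log) scale (via
lifelines).

**Cumulative incidence.**  Aalen–Johansen: CIF_k(t) = Σ_{t_i≤t}
Ŝ(t_i⁻)·d_{k,i}/n_i with Ŝ the all-cause KM.  Implemented directly (ties
grouped, deaths before censorings) so that the conservation identity
CIF₁ + CIF₂ + KM = 1 holds to machine precision even with heavily tied
registry times; lifelines' jittering estimator serves as an independent
cross-check on tie-free data in the tests.  Variance follows the standard
counting-process (Marubini–Valsecchi) form, evaluated with cumulative sums in
O(m); CI on the log(−log(1−F)) scale.

**Relative survival.**  For each case, k = 3 matched controls are walked
through the life table one year at a time; in each step death occurs with
probability 1 − exp(−m), with the death time placed uniformly within the
year, and both age and calendar year advance together.  This yearly-step
scheme is kept deliberately: it is the registry-analysis convention, and its
discretisation bias is characterised exactly in the tests (the step of death
is geometric with p = 1 − e^{−m}, so the mean death time is 1/p − 1/2, and
survival at integer times is exactly e^{−mt}).  A hard age cap of 120 forces
death at the cap; the surviving mass there is negligible but the cap
guarantees termination.  RS(t) = S_obs(t)/S_exp(t); its CI divides the
observed KM bounds by the expected curve, treating the high-k expected arm
as near-deterministic (simulation error enters the null-calibration test as
a separate binomial term).  1 − RS is read at a fixed, configurable plateau
time (default 25 years) rather than by automated plateau detection.

**Excess absolute risk and the trigam model.**  Follow-up is pooled into
intervals with nondecreasing widths (default breaks 0, 0.5, 1, 2, …, 10, 12,
…, 20, 25, 30, 35, 42 years; overridable and recorded in output metadata) —
longer late intervals pool enough deaths for stable late estimates.  Within
an interval each trajectory is split at integer age and year boundaries, and
E accrues as Σ m·duration along the Lexis diagonal, exactly.  O counts
all-cause deaths, so the whole EAR pathway ignores COD labels.  RR = O/E and
EAR = (O − E)/PY carry exact Poisson (Garwood) 95% intervals on O — late
bins are small, and Wald intervals would misbehave there.

The trigam excess hazard is

    h(t) = A · f_Γ(t; k, θ) + H · max(0, 1 − |t − p_c|/w),

an amplitude times a unit-area gamma density plus a symmetric triangle.  The
parameterisation is chosen so the AUC has closed form A + H·w, reduced by
H(w − p_c)²/(2w) when the triangle is truncated at t = 0.  The gamma wave
carries the broad excess-mortality wave after diagnosis; the triangle
captures a concentrated bump of deaths a few years out.  Fitting maximises
the Poisson log-likelihood with per-interval mean λ_i = E_i + h(t̄_i)·PY_i,
where t̄_i is the PY-weighted mean time in the interval — the midpoint
approximation standard in Poisson regression on binned person-years; its
error shrinks with bin width and is covered by the 2% self-consistency
tolerance in the tests.  λ is floored at 10⁻¹⁰; parameters are
box-constrained nonnegative (the model deliberately cannot represent the
statistically-null negative EARs seen in sparse late bins); optimisation is
L-BFGS-B from 5 seeded starts, keeping the best converged solution;
`fix_triangle` drops the triangle for sparse or young-age cohorts where it
is not detectable.  Lifetime risk is 1 − exp(−AUC).

## The synthetic registry

The generator exists so every estimator can be validated by parameter
recovery.  Defaults emulate the study conditions: diagnoses uniform over
1975–2016 with administrative censoring at the end of 2016, age at diagnosis
normal(63, 13) truncated to [3, 99] (median 63, range 3–99), 52.3% male, and
a Gompertz–Makeham background (a = 5·10⁻⁴, b = 3·10⁻⁵, c = 0.09 — roughly
US-adult scale at the cohort's ages).  Each case's time to death is sampled
from the total hazard m(sex, age+t, year+t) + h(t) by exact inversion of the
cumulative hazard: closed form per segment between unit age/year boundaries
and triangle breakpoints, with Brent root-finding inside the segment that
absorbs the exponential draw.  The firing cause is cancer with probability
h/(m+h) at the sampled time, which is distributionally identical to latent
competing times with hazards m and h.  Exact sampling (rather than the
yearly-step scheme of the expected-survival arm) is what gives the oracles
closed forms — with zero background, P(ever dying of the cancer) is exactly
1 − exp(−AUC).

`misreport_frac` relabels each cancer death to `dead_other` with fixed
probability, emulating registry under-ascertainment of metastatic deaths.
Demographics, survival and misreporting draw from independent substreams of
one seed, so matched seeds at different misreporting levels share follow-up
times exactly — which is what lets the tests assert that RS- and EAR-based
estimates are bit-identical under relabelling while the three COD-based
estimates fall monotonically.

What the generator does **not** emulate: registry expansion artifacts
(multi-registry accrual waves), tumour size/stage covariates, age-dependent
excess hazards, interval-censored survival months, or real secular trends in
background mortality beyond a geometric decline.  Passing recovery tests
therefore certify the estimation machinery under the model's own
assumptions, not the epidemiology of any real cohort.

## Numerical choices and degenerate inputs

- KM/CIF tie order: deaths precede censorings at identical times.
- All-censored input: flat S = 1 with degenerate CI and a logged warning; a
  cause with no events yields an identically-zero incidence curve.
- Step curves evaluate right-continuously; evaluation past the last event
  time returns the last value flagged `extrapolated` (35-year read-offs sit
  near the data's edge).
- Expected survival equal to zero at a grid point drops that point from the
  RS ratio with a warning.
- Life-table parsing fills missing ("." ) rates by carrying the last finite
  rate at lower age within the same sex and year; synthetic rates above 10
  per person-year are capped with a warning.
- Problem sizes: recovery tests use 20,000-case cohorts (the scale at which
  binomial noise on a ±0.03 survival tolerance is comfortably resolved),
  null-calibration uses 200 cohorts of 300 cases, and the matched-control
  closed-form checks use k = 50,000 simulants on a single case.

## Known limitations

- The crude/net distinction matters when interpreting the five estimates:
  1 − MFS, 1 − RS and the EAR route target net risk (the world without
  competing mortality), while the cumulative incidence limit and the raw
  proportion target crude risk and sit below it in an elderly cohort.  The
  comparison report records which is which.
- RS confidence intervals ignore expected-arm simulation error by design
  (k = 3 matches the convention; raise k when the expected arm must be
  tight).
- The trigam fit uses interval mean times, not interval integrals of h; with
  very coarse custom breaks the approximation degrades.
- Ederer I/II and Hakulinen analytic expected-survival estimators, Gray's
  test, and regression modelling (Cox, Fine–Gray) are out of scope.
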