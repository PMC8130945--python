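# lifetimerisk

Lifetime risk of death from a cancer, estimated five ways from registry-style
survival data.

## The problem

For cancers with long survival and late metastatic deaths — uveal melanoma is
the motivating case — the question "what fraction of patients will ultimately
die of their cancer?" is surprisingly hard to answer from registry data.
Follow-up thins out after 15–20 years, competing causes of death dominate in
an elderly cohort, and cause-of-death (COD) codes are unreliable precisely for
the late deaths that matter.  Estimators that read COD labels are biased
downward whenever metastatic deaths are recorded as something else; estimators
built on background population mortality avoid COD entirely.

This package implements and compares five estimators of lifetime risk:

1. **Raw proportion** — cancer deaths over all deaths, optionally projecting
   patients still alive to eventual other-cause deaths.
2. **1 − MFS** — Kaplan–Meier metastasis-free survival (other-cause deaths
   censored) read at its late plateau; estimates the *net* risk.
3. **Cumulative incidence** — the Aalen–Johansen cause-specific cumulative
   incidence limit under competing risks; estimates the *crude* risk.
4. **1 − RS** — relative survival RS(t) = S_obs(t)/S_exp(t), with expected
   survival from simulating age/sex/calendar-year matched controls through a
   background life table (three per case, yearly steps), read at its plateau.
5. **Excess absolute risk (EAR)** — person-years pooled into widening
   intervals on the Lexis diagram give observed deaths O, expected deaths E
   and EAR = (O − E)/PY; a parametric excess hazard (the "trigam" model) is
   fit by Poisson likelihood and integrated.

The trigam excess hazard is a gamma-density wave plus a triangle wave,

    h(t) = A · f_Γ(t; k, θ) + H · max(0, 1 − |t − p_c|/w),

so its area under the curve, AUC = A + (triangle area on t ≥ 0), is the
expected number of lifetime excess deaths per person, and lifetime risk is
**1 − exp(−AUC)**.

Estimators 1–3 use COD labels; 4 and 5 do not.  A synthetic-registry
generator with a known injected excess hazard makes all five testable by
parameter recovery, including under deliberate COD misreporting.

## Worked example

```python
import lifetimerisk as lr

table = lr.make_synthetic_lifetable()                    # Gompertz–Makeham background
trigam = lr.TrigamParams(A=0.455, k=2, theta=3, H=0.05, p_c=3, w=2)  # AUC = 0.555
cohort = lr.generate_cohort(lr.GenConfig(n_cases=20_000, seed=1, trigam=trigam), table)

ear = lr.tabulate_ear(cohort, table)
fit = lr.fit_trigam(ear, n_starts=5, seed=1)
print(f"fitted AUC {fit.auc:.3f}, lifetime risk {fit.lifetime_risk:.1%}")
```

prints

```
fitted AUC 0.547, lifetime risk 42.1%
```

against a true injected AUC of 0.555 (risk 1 − e^−0.555 = 42.6%): the full
tabulate-and-fit pipeline recovers the injected lifetime risk to within half a
percentage point at this sample size.  `lr.compare_estimators(cohort, table)`
runs all five estimators and returns the comparison report; the scripts in
`examples/` walk through each stage (life tables, cohort generation, KM/CIF
curves, relative survival, the EAR fit, and the five-way comparison, with and
without misreported causes of death).

A thin CLI wraps the same pipeline for delimited case listings:

```bash
lifetime-risk run --cases cases.csv --lifetable mx.txt --out results/ --age-split 50
```

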