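"""The five-way lifetime-risk comparison, with and without misreported causes.

The point of running five estimators side by side: three read cause-of-death
labels (raw proportion, 1-MFS, cumulative incidence) and are dragged down
when cancer deaths are recorded as other causes; two (1-RS, excess-risk AUC)
ignore the labels entirely and do not move.
"""

import lifetimerisk as lr

table = lr.make_synthetic_lifetable()
trigam = lr.TrigamParams(A=0.455, k=2.0, theta=3.0, H=0.05, p_c=3.0, w=2.0)
true_risk = lr.lifetime_risk_from_auc(trigam.auc)

print(f"true lifetime net risk: {true_risk:.3f}\n")
for frac in (0.0, 0.3):
    cfg = lr.GenConfig(n_cases=10_000, seed=1, trigam=trigam, misreport_frac=frac)
    cohort = lr.generate_cohort(cfg, table)
    rep = lr.compare_estimators(cohort, table, seed=2)
    print(f"misreport_frac = {frac}:")
    for name, value in rep.estimates().items():
        tag = "uses COD" if rep.uses_cod[name] else "COD-free"
        print(f"  {name:20s} {value:.3f}   [{tag}]")
    print()

print("with 30% of cancer deaths relabelled, the three COD-based estimates fall")
print("while 1-RS and the EAR-based estimate are unchanged: the central reason")
print("to prefer them when registry cause-of-death coding is unreliable.")
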