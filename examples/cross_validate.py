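"""The four cross-validation frameworks on the standard fixture.

Global LOOCV ranks each held-out pair against every unknown pair; local
LOOCV only against its own disease's candidates; five-fold CV masks 20% of
the knowns at a time; LODOCV removes a disease's entire label column and is
the most stringent test (nothing is known about the target disease).
AUC = 1 is perfect ranking, 0.5 is chance.
"""

from llcmda import (
    global_loocv,
    kfold_cv,
    local_loocv,
    lodocv,
    standard_fixture,
)

assoc, fms, dss, _ = standard_fixture()
print(f"dataset: {assoc.n_mirnas} miRNAs x {assoc.n_diseases} diseases, "
      f"{assoc.n_known} known associations")

print(f"global LOOCV AUC: {global_loocv(assoc, fms, dss).auc:.4f}")
print(f"local  LOOCV AUC: {local_loocv(assoc, fms, dss).auc:.4f}")
print(f"5-fold x20  AUC: {kfold_cv(assoc, fms, dss, k=5, repeats=20, seed=7).auc:.4f}")
report = lodocv(assoc, fms, dss)
print(f"LODOCV      AUC: {report.auc:.4f}  (hardest: no labels for the target disease)")
worst = min(report.per_unit, key=report.per_unit.get)
print(f"weakest disease under LODOCV: {worst} (AUC {report.per_unit[worst]:.3f})")
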