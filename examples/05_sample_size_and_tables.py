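"""Precision-based sample size and diagnostic metrics from contingency counts.

Two zero-simulation utilities: the per-group sample size needed to pin
sensitivity (or specificity) within a +/- d confidence band, and the percent
metrics implied by a confusion table.
"""

from bldm import ConfusionCounts, confusion_metrics, minimum_sample_size

n = minimum_sample_size(P=0.90, d=0.1, conf=0.95)
print(f"to estimate 90% sensitivity within +/-0.1 at 95% confidence: "
      f"n = {n} per group")

# a validation cohort in which 35/42 malignant and 50/55 benign calls are correct
counts = ConfusionCounts(tp=35, fn=7, tn=50, fp=5)
m = confusion_metrics(counts).rounded()
print(f"\nconfusion table tp=35 fn=7 tn=50 fp=5 (n={counts.total}):")
for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
    print(f"  {k:12s} {m[k]:.2f}%")
print("\nPPV/NPV depend on the cohort's malignancy prevalence; sensitivity and")
print("specificity do not.")
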