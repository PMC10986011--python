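"""Train the diagnostic model end-to-end and evaluate held-out cohorts.

`run_pipeline` chains every stage — block calling on pooled discovery reads,
metrics, the marker funnel, z-scored random-forest training, the Youden-mean
cutoff from 3x5-fold CV — and scores the validation split through the frozen
bundle, reporting the diagnostic battery next to the ultrasonography
comparator (TI-RADS >= 4 positive).
"""

import dataclasses

from bldm import SimConfig, simulate_cohort, run_pipeline

config = dataclasses.replace(
    SimConfig(), n_blocks=40, n_differential=10, delta=0.3,
    n_discovery=(25, 22), n_validation=(18, 15), n_test=(0, 0), seed=5,
)
cohort, truth, sites = simulate_cohort(config)
result = run_pipeline(cohort, sites, seed=5, threshold_reps=1, rfecv_estimators=50,
                      evaluate=("validation",))

print(f"markers: {len(result.marker_set.markers)}   "
      f"cutoff: {result.bundle.threshold:.3f} (mean of {len(result.fold_thresholds)} fold thresholds)")

ev = result.evaluations["validation"]
m = ev.metrics.rounded()
print("\nvalidation cohort (methylation model):")
print(f"  sensitivity {m['sensitivity']}%  specificity {m['specificity']}%  "
      f"accuracy {m['accuracy']}%")
print(f"  AUC {ev.metrics.auc:.3f}  (95% CI {ev.metrics.auc_ci[0]:.3f}-{ev.metrics.auc_ci[1]:.3f})")

c = ev.comparator_metrics.rounded()
print("ultrasonography comparator (TI-RADS >= 4):")
print(f"  sensitivity {c['sensitivity']}%  specificity {c['specificity']}%")

micro = ev.subgroups["micronodule"]
if micro is not None:
    mm = micro.rounded()
    print(f"micronodules (<= 10 mm): accuracy {mm['accuracy']}%  n={micro.counts.total}")
print("\nA higher model specificity at comparable AUC is the clinically relevant")
print("margin: it is what spares benign-nodule patients an unnecessary biopsy.")
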