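"""Run the marker funnel: coverage filter, Mann-Whitney screen, RFECV.

Per block the screen keeps the measurement with the lowest two-sided
Mann-Whitney p-value between malignant and benign discovery samples; blocks
with p < 0.001 become marker candidates, which RFECV (random-forest recursive
feature elimination with 10-fold CV) reduces to the final marker set.
"""

import dataclasses

import pandas as pd

from bldm import SimConfig, simulate_cohort, call_mhbs, build_metric_matrix
from bldm.selection import (
    filter_blocks_by_coverage, screen_markers, impute_missing_knn, rfecv_select,
)

config = dataclasses.replace(
    SimConfig(), n_blocks=40, n_differential=10, delta=0.3,
    n_discovery=(25, 22), n_validation=(0, 0), n_test=(0, 0), seed=5,
)
cohort, truth, sites = simulate_cohort(config)
disc_ids = [m.sample_id for m in cohort.split("discovery")]
labels = pd.Series({m.sample_id: m.label for m in cohort.samples})

pooled = [r for s in disc_ids for r in cohort.haplotypes[s]]
mhbs = call_mhbs(pooled, sites)
matrix = build_metric_matrix(cohort, mhbs, sites)

retained = filter_blocks_by_coverage(matrix)
print(f"coverage filter: {len(retained)}/{len(mhbs)} blocks with 10-500X in >=80% of samples")

screen = screen_markers(matrix.values.loc[:, retained], labels, alpha=0.001)
print(f"screen: {len(screen)} blocks at p < 0.001; first three:")
for r in screen[:3]:
    print(f"  {r.block_id}  metric={r.chosen_metric:6s} p={r.p_two_sided:.2e} direction={r.direction:+d}")

features = matrix.values.loc[:, retained][[(r.block_id, r.chosen_metric) for r in screen]]
completed, _ = impute_missing_knn(features, k=5)
marker_set = rfecv_select(completed, labels.loc[disc_ids], folds=10, seed=5)
print(f"\nRFECV final marker set ({len(marker_set.markers)} markers):")
for block, metric in marker_set.markers[:10]:
    print(f"  {block}:{metric}")
print("Mean CV AUC by candidate size is kept in marker_set.provenance['cv_mean_scores'].")
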