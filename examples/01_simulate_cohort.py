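"""Generate a small synthetic cohort with planted truth and inspect it.

The generator emits read-level methylation haplotypes (mHap-style records),
a clinical sample sheet and a truth table naming the blocks that truly differ
between malignant (MTN) and benign (BTN) nodules.
"""

import dataclasses

from bldm import SimConfig, simulate_cohort

config = dataclasses.replace(
    SimConfig(),           # defaults = three-phase study conditions
    n_blocks=40,           # scaled down so this example runs in seconds
    n_differential=10,
    n_discovery=(20, 18), n_validation=(14, 12), n_test=(0, 0),
    seed=42,
)
cohort, truth, sites = simulate_cohort(config)

print(f"samples: {len(cohort.samples)}  "
      f"(discovery {len(cohort.split('discovery'))}, validation {len(cohort.split('validation'))})")
print(f"reference CpGs: {len(sites)} across {config.n_blocks} blocks")

sid = cohort.samples[0].sample_id
records = cohort.haplotypes[sid]
print(f"\nfirst three haplotype records of {sid}:")
for rec in records[:3]:
    print(f"  {rec.chrom}\t{rec.start}\t{rec.end}\t{rec.pattern}\t{rec.count}")

diff = truth.blocks[truth.blocks.differential]
print(f"\nplanted differential blocks: {len(diff)}")
print(diff[["start", "n_cpgs", "btn_mean", "mtn_mean"]].head(3).to_string())
print("\nEach differential block's MTN group mean is shifted by",
      config.delta, "on the methylation-probability scale.")
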