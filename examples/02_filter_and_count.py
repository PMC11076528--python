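"""Apply the published QC rules and count clock-like passengers.

Sample-level QC (BAF autocorrelation, sex concordance), call-level QC
(minimum size, phased-BAF log-odds, constitutional-duplication and deletion
coverage rules), the single-mCA CHIP-free cohort definition, and per-sample
counting of C>T / T>C passenger mutations.
"""

import mcapacer as m
from mcapacer import mca, passengers

bundle = m.simulate_cohort(m.SimConfig(n_individuals=2000), seed=7)

kept_ids, sample_log = mca.filter_samples(bundle.samples)
samples = bundle.samples[bundle.samples["sample_id"].isin(kept_ids)]
calls, call_log = mca.filter_calls(bundle.mca_calls)
calls = calls[calls["sample_id"].isin(kept_ids)]
print(f"samples: {len(bundle.samples)} -> {len(samples)} after QC")
print("call exclusions by rule:")
print(call_log["reason"].value_counts().to_string())

cohort = mca.define_cohort(calls, samples, chip_carriers=bundle.chip_carriers)
print(f"\ncohort: {len(cohort.assignments)} individuals with exactly one mCA, no CHIP")
print("cohort exclusions:")
print(cohort.exclusions["reason"].value_counts().to_string())

counts = passengers.count_passengers(bundle.variants, sample_ids=cohort.sample_ids)
t = counts["total"]
print(f"\npassenger counts: min {t.min()}, median {t.median():.0f}, max {t.max()}")
# the count proxies how long the pre-driver lineage accrued mutations:
# a later-acquired driver (a faster clone, given its size) carries more.
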