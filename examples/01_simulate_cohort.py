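"""Simulate a synthetic mCA cohort and look at the ground truth.

Generates subjects whose clones grow logistically from one founder stem
cell, retaining those whose clone is large enough to detect at blood draw,
and writes the observable tables (mCA calls, somatic variants, sample
covariates, genotypes) plus a separate ground-truth table.
"""

import mcapacer as m

config = m.SimConfig(n_individuals=2000, seed=7)
bundle = m.simulate_cohort(config)
bundle.write("scratch/example_cohort")

truth = bundle.truth
print(f"simulated {config.n_individuals} subjects, retained {len(truth)} "
      f"with a detectable clone (cell fraction {config.detection_limit_cf}-{config.max_cf})")
print(f"variant table rows: {len(bundle.variants)} "
      f"(clock-like passengers + germline/CHIP contaminants)")
print("\nretained clones by lesion:")
print(
    truth.groupby(["mca_chromosome", "mca_copy_type"])
    .agg(n=("sample_id", "size"), mean_s=("s_true", "mean"), mean_cf=("cf_true", "mean"))
    .round(3)
)
# mean_s is the per-year growth advantage; fitter lesions are detected more
# often and at larger cell fractions.
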