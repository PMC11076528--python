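"""End-to-end pipeline: simulate -> filter -> count -> score -> aggregate
-> associate, with every stage's output written as TSV.

The pipeline consumes only observable tables (the simulator's truth table is
written but never read back), and a fixed config + seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import pandas as pd

from . import aggregate as agg
from . import assoc, mca, passengers, scoring
from .config import SimConfig
from .io import read_genotypes, read_mca_calls, read_samples, read_variants, write_manifest
from .simulate import CohortBundle, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    bundle: CohortBundle
    cohort: mca.CohortDefinition
    counts: pd.DataFrame
    report: scoring.ScoreReport
    fitness: pd.DataFrame
    exclusion: scoring.ExclusionCheck
    scan: pd.DataFrame


def run_pipeline(
    config: SimConfig,
    seed: int,
    outdir,
    include_sex_chromosomes: bool = True,
) -> PipelineResult:
    """Run the whole analysis on a freshly simulated cohort.

    Writes simulate/ (raw tables), filtered call and sample logs, counts,
    scores, the fitness table with fold changes, the association scan, and a
    JSON manifest under ``outdir``.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = simulate_cohort(config, seed=seed)
    simdir = out / "simulate"
    bundle.write(simdir)

    # stages below re-read the written observable tables: the on-disk TSV is
    # the interface, and the truth table stays unread
    samples = read_samples(simdir / "samples.tsv")
    calls = read_mca_calls(simdir / "mca_calls.tsv")
    variants, parse_log = read_variants(simdir / "variants.tsv")
    genotypes = read_genotypes(simdir / "genotypes.tsv")
    chip_ids = [
        s
        for s in (simdir / "chip_carriers.txt").read_text().splitlines()
        if s.strip()
    ]

    kept_ids, sample_log = mca.filter_samples(samples)
    kept_samples = samples[samples["sample_id"].isin(kept_ids)]
    kept_calls, call_log = mca.filter_calls(calls)
    kept_calls = kept_calls[kept_calls["sample_id"].isin(kept_ids)]
    sample_log.to_csv(out / "sample_exclusions.tsv", sep="\t", index=False)
    call_log.to_csv(out / "call_exclusions.tsv", sep="\t", index=False)

    cohort = mca.define_cohort(
        kept_calls,
        kept_samples,
        chip_carriers=chip_ids,
        include_sex_chromosomes=include_sex_chromosomes,
    )
    cohort.assignments.to_csv(out / "cohort.tsv", sep="\t", index=False)
    cohort.exclusions.to_csv(out / "cohort_exclusions.tsv", sep="\t", index=False)

    counts = passengers.count_passengers(
        variants, sample_ids=cohort.sample_ids
    )
    counts.to_csv(out / "passenger_counts.tsv", sep="\t")

    report = scoring.score_cohort(counts, kept_samples, cohort)
    report.results.to_csv(out / "pacer_scores.tsv", sep="\t", index=False)

    exclusion = scoring.chromosome_exclusion_check(
        report, counts, kept_samples, cohort, mode="mca_chrom"
    )
    exclusion.per_sample.to_csv(out / "exclusion_density.tsv", sep="\t", index=False)

    fitness = agg.aggregate_fitness(report.results, cohort, kept_samples)
    try:
        fitness = agg.fold_change(fitness)
    except KeyError:
        pass  # no X-loss reference group in this cohort
    fitness.to_csv(out / "fitness.tsv", sep="\t", index=False)

    scan = assoc.single_variant_scan(
        genotypes, counts, kept_samples, cohort, variant_meta=bundle.variant_meta
    )
    scan.to_csv(out / "association_scan.tsv", sep="\t", index=False)

    write_manifest(
        out / "manifest.json",
        seed=seed,
        config=config.to_dict(),
        n_simulated=config.n_individuals,
        n_retained=len(bundle.samples),
        n_cohort=len(cohort.assignments),
        exclusion_rho=exclusion.rho,
        exclusion_density_p=exclusion.pooled_p,
        variant_parse_log=parse_log,
    )
    return PipelineResult(
        bundle=bundle,
        cohort=cohort,
        counts=counts,
        report=report,
        fitness=fitness,
        exclusion=exclusion,
        scan=scan,
    )
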