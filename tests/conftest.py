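"""Shared fixtures: simulated cohorts run once per session.

The ladder cohort spans five CN-LOH lesions with fitness 0.10-0.30/yr at
default passenger rate and dispersion; it backs the recovery, calibration
and transform-contract tests. The default cohort uses the standard lesion
mix (including X loss and chr9p CN-LOH).
"""

from __future__ import annotations

import pathlib

import pytest

import mcapacer as m
from mcapacer import mca, passengers, scoring

DATA = pathlib.Path(__file__).parent / "data"

LADDER_SEED = 11
DEFAULT_SEED = 3


def run_upstream(config: m.SimConfig, seed: int) -> dict:
    """simulate -> QC filters -> cohort definition -> passenger counts."""
    bundle = m.simulate_cohort(config, seed=seed)
    kept_ids, sample_log = mca.filter_samples(bundle.samples)
    samples = bundle.samples[bundle.samples["sample_id"].isin(kept_ids)]
    calls, call_log = mca.filter_calls(bundle.mca_calls)
    calls = calls[calls["sample_id"].isin(kept_ids)]
    cohort = mca.define_cohort(calls, samples, chip_carriers=bundle.chip_carriers)
    counts = passengers.count_passengers(bundle.variants, sample_ids=cohort.sample_ids)
    return {
        "bundle": bundle,
        "samples": samples,
        "calls": calls,
        "cohort": cohort,
        "counts": counts,
        "sample_log": sample_log,
        "call_log": call_log,
    }


@pytest.fixture(scope="session")
def ladder():
    config = m.SimConfig(
        n_individuals=9800,
        mca_types=m.fitness_ladder_types(),
        n_null_snps=1000,
    )
    data = run_upstream(config, LADDER_SEED)
    data["report"] = scoring.score_cohort(data["counts"], data["samples"], data["cohort"])
    data["config"] = config
    return data


@pytest.fixture(scope="session")
def default_cohort():
    config = m.SimConfig(n_individuals=2500, n_null_snps=10)
    data = run_upstream(config, DEFAULT_SEED)
    data["report"] = scoring.score_cohort(data["counts"], data["samples"], data["cohort"])
    data["config"] = config
    return data


@pytest.fixture(scope="session")
def truth_joined_ladder(ladder):
    truth = ladder["bundle"].truth.set_index("sample_id")
    return ladder["report"].results.set_index("sample_id").join(truth, how="inner")
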