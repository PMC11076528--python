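"""Sample- and call-level QC for MoChA-style mCA call tables.

Implements the published exclusion rules for mosaic chromosomal alteration
calls from phased-BAF callers: contamination and sex-discordance screens at
the sample level; minimum size, phased-BAF log-odds, constitutional
duplication and deletion coverage screens at the call level; and the cohort
definition (exactly one retained mCA, no CHIP driver SNVs). All thresholds
are strict inequalities exactly as published; boundary values pass.

Coordinates are 1-based inclusive; size_mb = (end - start + 1) / 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .genome import arm_of, is_autosome, normalize_chrom

__all__ = [
    "CohortError",
    "CohortDefinition",
    "filter_samples",
    "filter_calls",
    "classify_loss_of_x",
    "define_cohort",
]

# Sample-level thresholds
BAF_AUTOCORR_MAX = 0.05  # excluded when strictly greater

# Call-level thresholds
MIN_SIZE_MB = 2.0
LOD_MIN_AUTOSOME = 20.0  # excluded when strictly below
LOD_MIN_SEX = 5.0
DUP_SMALL_RANGE_MB = (2.0, 10.0)  # rel cov strictly > 2.25 excluded
DUP_SMALL_COV = 2.25
DUP_LARGE_RANGE_MB = (50.0, 250.0)  # rel cov strictly > 2.5 excluded
DUP_LARGE_COV = 2.5
DEL_COV_MIN = 0.5  # excluded when strictly below

# Mosaic loss-of-X definition
XLOSS_MIN_MB = 100.0
XLOSS_MAX_COV = 2.5


class CohortError(RuntimeError):
    """Raised when cohort definition produces no eligible individuals."""


def size_mb(start, end) -> float:
    """Interval size in megabases, 1-based inclusive coordinates."""
    return (end - start + 1) / 1e6


def filter_samples(samples: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Sample-level QC: phased-BAF autocorrelation and sex concordance.

    Returns (retained sample_ids, exclusion log). Missing QC fields are
    treated as passing and logged with reason 'missing_qc_field'.
    """
    log: list[dict] = []
    retained: list[str] = []
    for row in samples.itertuples(index=False):
        sid = row.sample_id
        reasons = []
        baf = getattr(row, "baf_autocorrelation", None)
        if baf is None or pd.isna(baf):
            log.append({"sample_id": sid, "reason": "missing_qc_field", "excluded": False})
        elif baf > BAF_AUTOCORR_MAX:
            reasons.append("baf_autocorrelation")
        conc = getattr(row, "reported_sex_concordant", None)
        if conc is None or pd.isna(conc):
            log.append({"sample_id": sid, "reason": "missing_qc_field", "excluded": False})
        elif not conc:
            reasons.append("sex_discordance")
        if reasons:
            for r in reasons:
                log.append({"sample_id": sid, "reason": r, "excluded": True})
        else:
            retained.append(sid)
    log_df = pd.DataFrame(log, columns=["sample_id", "reason", "excluded"])
    return retained, log_df


def _call_failures(chrom: str, start, end, copy_type, lod, rel_cov) -> list[str]:
    reasons = []
    sz = size_mb(start, end)
    if sz < MIN_SIZE_MB:
        reasons.append("min_size")
    lod_min = LOD_MIN_AUTOSOME if is_autosome(chrom) else LOD_MIN_SEX
    if lod < lod_min:
        reasons.append("lod_baf_phase")
    small = DUP_SMALL_RANGE_MB[0] <= sz <= DUP_SMALL_RANGE_MB[1] and rel_cov > DUP_SMALL_COV
    large = DUP_LARGE_RANGE_MB[0] <= sz <= DUP_LARGE_RANGE_MB[1] and rel_cov > DUP_LARGE_COV
    if small or large:
        reasons.append("constitutional_duplication")
    if rel_cov < DEL_COV_MIN:
        reasons.append("deletion_coverage")
    return reasons


def filter_calls(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call-level QC. Returns (retained calls, exclusion log).

    The log records every failed rule for every dropped call. Unknown
    chromosome labels raise UnknownChromosomeError.
    """
    keep_idx: list[int] = []
    log: list[dict] = []
    for idx, row in calls.iterrows():
        chrom = normalize_chrom(row["chromosome"])
        reasons = _call_failures(
            chrom,
            row["start"],
            row["end"],
            row.get("copy_type", "undetermined"),
            row["lod_baf_phase"],
            row["relative_coverage"],
        )
        if reasons:
            for r in reasons:
                log.append(
                    {
                        "sample_id": row["sample_id"],
                        "chromosome": chrom,
                        "start": row["start"],
                        "end": row["end"],
                        "reason": r,
                    }
                )
        else:
            keep_idx.append(idx)
    retained = calls.loc[keep_idx].copy()
    if len(retained):
        retained["chromosome"] = [normalize_chrom(c) for c in retained["chromosome"]]
        retained["size_mb"] = size_mb(retained["start"], retained["end"])
    else:
        retained = retained.assign(size_mb=pd.Series(dtype=float))
    log_df = pd.DataFrame(
        log, columns=["sample_id", "chromosome", "start", "end", "reason"]
    )
    return retained, log_df


def classify_loss_of_x(chromosome, start, end, copy_type, relative_coverage) -> bool:
    """True for mosaic loss of X: a loss on chromosome X spanning more than
    100 Mb with relative coverage below 2.5."""
    if normalize_chrom(chromosome) != "X":
        return False
    return (
        copy_type == "loss"
        and size_mb(start, end) > XLOSS_MIN_MB
        and relative_coverage < XLOSS_MAX_COV
    )


@dataclass
class CohortDefinition:
    """Analysis cohort: one retained mCA per included individual.

    assignments has one row per included sample with the mCA's chromosome,
    arm ('p'/'q'/'whole'), copy type and clonal fraction; exclusions logs
    every dropped sample with a reason.
    """

    assignments: pd.DataFrame
    exclusions: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments["sample_id"])


def define_cohort(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    chip_carriers: Iterable[str] = (),
    include_sex_chromosomes: bool = True,
) -> CohortDefinition:
    """Define the single-mCA, CHIP-free analysis cohort.

    Expects quality-filtered calls and samples (filter_calls /
    filter_samples already applied). With include_sex_chromosomes=False,
    sex-chromosome calls are ignored entirely: individuals whose only mCA is
    on X or Y drop out, mirroring autosome-restricted analyses.
    """
    chip = set(chip_carriers)
    use = calls
    log: list[dict] = []
    if not include_sex_chromosomes:
        use = calls[[is_autosome(c) for c in calls["chromosome"]]]
    per_sample = use.groupby("sample_id")

    rows: list[dict] = []
    sample_ids = list(samples["sample_id"])
    counts = per_sample.size()
    for sid in sample_ids:
        n = int(counts.get(sid, 0))
        if sid in chip:
            log.append({"sample_id": sid, "reason": "chip_carrier"})
            continue
        if n == 0:
            log.append({"sample_id": sid, "reason": "no_mca"})
            continue
        if n > 1:
            log.append({"sample_id": sid, "reason": "multiple_mca"})
            continue
        call = per_sample.get_group(sid).iloc[0]
        chrom = normalize_chrom(call["chromosome"])
        rows.append(
            {
                "sample_id": sid,
                "chromosome": chrom,
                "arm": arm_of(chrom, call["start"], call["end"]),
                "copy_type": call["copy_type"],
                "clonal_fraction": call["clonal_fraction"],
                "is_loss_of_x": classify_loss_of_x(
                    chrom,
                    call["start"],
                    call["end"],
                    call["copy_type"],
                    call["relative_coverage"],
                ),
            }
        )
    if not rows:
        raise CohortError(
            "cohort definition retained no individuals (all excluded as "
            "multi-mCA, CHIP carriers, or without a retained mCA)"
        )
    return CohortDefinition(
        assignments=pd.DataFrame(rows),
        exclusions=pd.DataFrame(log, columns=["sample_id", "reason"]),
    )
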