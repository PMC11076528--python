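"""TSV (and minimal VCF) readers/writers for the pipeline's tables.

Column schemas
--------------
mCA calls (MoChA-like): sample_id, chromosome, start, end, copy_type,
    clonal_fraction, lod_baf_phase, relative_coverage. Coordinates are
    1-based inclusive.
samples: sample_id, age_at_draw, sex, study, blood-count columns,
    reported_sex_concordant, baf_autocorrelation.
variants: sample_id, chromosome, position, ref, alt, depth, vaf, gene.
    Indels and multi-nucleotide records are rejected at parse time and
    counted in the returned log.
genotypes: sample_id index column, one column of 0/1/2 allele counts per
    variant id.
"""

from __future__ import annotations

import json
import pathlib

import pandas as pd

__all__ = [
    "read_mca_calls",
    "read_samples",
    "read_variants",
    "read_genotypes",
    "write_manifest",
]

_BASES = frozenset("ACGT")


def read_mca_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {
        "sample_id",
        "chromosome",
        "start",
        "end",
        "copy_type",
        "clonal_fraction",
        "lod_baf_phase",
        "relative_coverage",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mCA call table missing columns: {sorted(missing)}")
    return df


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample table missing sample_id column")
    return df


def _reject_non_snv(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    ref = df["ref"].astype(str).str.upper()
    alt = df["alt"].astype(str).str.upper()
    snv = ref.isin(_BASES) & alt.isin(_BASES) & (ref != alt)
    return df[snv].reset_index(drop=True), int((~snv).sum())


def read_variants(path) -> tuple[pd.DataFrame, dict]:
    """Read a somatic variant table (TSV, or minimal VCF if the filename
    ends in .vcf). Returns (table, parse log); non-SNV records are dropped
    and counted in the log."""
    path = pathlib.Path(path)
    if path.suffix == ".vcf":
        df = _read_minimal_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene": str})
        required = {"sample_id", "chromosome", "position", "ref", "alt", "depth", "vaf"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if "gene" not in df.columns:
        df["gene"] = ""
    df["gene"] = df["gene"].fillna("")
    df, n_rejected = _reject_non_snv(df)
    return df, {"n_rejected_non_snv": n_rejected, "n_records": len(df)}


def _read_minimal_vcf(path) -> pd.DataFrame:
    """Minimal multi-sample VCF dialect, parsed with cyvcf2: per-sample
    FORMAT DP and AD (or INFO AF as a fallback); an INFO GENE tag carries
    the gene annotation. Samples with missing/zero DP at a record are taken
    not to carry that variant."""
    import numpy as np
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    rows = []
    for rec in vcf:
        gene = rec.INFO.get("GENE") or ""
        alt = rec.ALT[0] if rec.ALT else ""
        dp = rec.format("DP")
        ad = rec.format("AD")
        info_af = rec.INFO.get("AF")
        for i, name in enumerate(names):
            depth = int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else 0
            if depth <= 0:
                continue
            if ad is not None and ad.shape[1] > 1 and ad[i][1] >= 0:
                vaf = float(ad[i][1]) / depth
            elif info_af is not None:
                vaf = float(np.atleast_1d(info_af)[0])
            else:
                vaf = 0.0
            rows.append(
                {
                    "sample_id": name,
                    "chromosome": rec.CHROM,
                    "position": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "depth": depth,
                    "vaf": vaf,
                    "gene": gene,
                }
            )
    return pd.DataFrame(rows)


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_manifest(path, **entries) -> None:
    """JSON run manifest (inputs, seed, package version)."""
    from . import __version__

    payload = {"mcapacer_version": __version__, **entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
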