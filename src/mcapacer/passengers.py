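"""Clock-like passenger mutation identification and per-sample counting.

A passenger here is a somatic single-nucleotide variant whose substitution,
after normalizing to the pyrimidine-reference representation standard for
mutational-signature work, is C>T or T>C (so G>A and A>G qualify), with
sequencing depth in [25, 100], variant allele fraction at most 0.35, and no
CHIP driver gene annotation. Depth and VAF bounds follow the published
wording literally ("below 25 or above 100", "exceeding 35%"), so the
boundary values themselves pass. The count of such variants per individual
proxies the age at which the individual's driver lesion was acquired.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genome import normalize_chrom

__all__ = [
    "DuplicateVariantError",
    "load_chip_genes",
    "is_clocklike",
    "passes_quality",
    "count_passengers",
    "total_excluding",
]

DEPTH_MIN = 25
DEPTH_MAX = 100
VAF_MAX = 0.35

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = frozenset("ACGT")


class DuplicateVariantError(ValueError):
    """A (sample, chromosome, position, ref, alt) key appeared twice."""


def load_chip_genes() -> frozenset[str]:
    """CHIP driver gene list from the bundled configuration file."""
    text = resources.files("mcapacer.data").joinpath("chip_genes.txt").read_text()
    genes = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(genes)


def is_clocklike(ref: str, alt: str, literal_strand: bool = False) -> bool:
    """True if ref>alt is a clock-like C>T / T>C substitution.

    By default the substitution is first normalized to its
    pyrimidine-reference representation (the convention of the clock-like
    signatures SBS1/SBS5), so G>A and A>G also qualify. With
    ``literal_strand=True`` only literal C>T and T>C count (sensitivity
    switch).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in ("G", "A") and not literal_strand:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return (ref, alt) in (("C", "T"), ("T", "C"))


def passes_quality(depth, vaf, gene="", chip_genes: frozenset[str] | None = None) -> bool:
    """Depth/VAF/CHIP-gene quality predicate for a candidate passenger."""
    if chip_genes is None:
        chip_genes = load_chip_genes()
    gene = "" if gene is None or (isinstance(gene, float) and np.isnan(gene)) else gene
    return DEPTH_MIN <= depth <= DEPTH_MAX and vaf <= VAF_MAX and gene not in chip_genes


def _passing_mask(
    variants: pd.DataFrame,
    chip_genes: frozenset[str],
    literal_strand: bool,
) -> np.ndarray:
    ref = variants["ref"].str.upper()
    alt = variants["alt"].str.upper()
    clock = np.array(
        [is_clocklike(r, a, literal_strand=literal_strand) for r, a in zip(ref, alt)]
    )
    gene = variants.get("gene", pd.Series("", index=variants.index)).fillna("")
    return (
        clock
        & (variants["depth"] >= DEPTH_MIN)
        & (variants["depth"] <= DEPTH_MAX)
        & (variants["vaf"] <= VAF_MAX)
        & ~gene.isin(chip_genes)
    ).to_numpy()


def count_passengers(
    variants: pd.DataFrame,
    chip_genes: frozenset[str] | None = None,
    sample_ids: list[str] | None = None,
    literal_strand: bool = False,
) -> pd.DataFrame:
    """Per-sample passenger counts: one row per sample, one column per
    chromosome with at least one passing variant anywhere, plus 'total'.

    ``sample_ids`` optionally fixes the output rows (samples with zero
    passing variants get an all-zero row rather than being dropped).
    Duplicate variant records raise DuplicateVariantError.
    """
    if chip_genes is None:
        chip_genes = load_chip_genes()
    key_cols = ["sample_id", "chromosome", "position", "ref", "alt"]
    if len(variants) and variants.duplicated(subset=key_cols).any():
        dup = variants[variants.duplicated(subset=key_cols, keep=False)]
        raise DuplicateVariantError(
            f"duplicate variant record(s), first at {dup.iloc[0][key_cols].tolist()}"
        )
    if len(variants) == 0:
        idx = pd.Index(sample_ids or [], name="sample_id")
        out = pd.DataFrame(index=idx)
        out["total"] = 0
        return out

    v = variants.copy()
    v["chromosome"] = [normalize_chrom(c) for c in v["chromosome"]]
    v["_pass"] = _passing_mask(v, chip_genes, literal_strand)
    passing = v[v["_pass"]]
    wide = (
        passing.groupby(["sample_id", "chromosome"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    if sample_ids is not None:
        wide = wide.reindex(pd.Index(sample_ids, name="sample_id"), fill_value=0)
    else:
        wide = wide.reindex(
            pd.Index(sorted(v["sample_id"].unique()), name="sample_id"), fill_value=0
        )
    wide = wide.astype(int)
    wide["total"] = wide.sum(axis=1)
    return wide


def total_excluding(counts: pd.DataFrame, chrom) -> pd.Series:
    """Total passenger count per sample excluding one chromosome.

    ``chrom`` may be a single label or a per-sample Series aligned to the
    counts index (the per-individual mCA chromosome). Chromosomes absent
    from the table contribute zero.
    """
    if isinstance(chrom, pd.Series):
        chrom = chrom.reindex(counts.index).map(
            lambda x: normalize_chrom(x) if pd.notna(x) else x
        )
        sub = pd.Series(0, index=counts.index, dtype=int)
        for c in chrom.dropna().unique():
            if c in counts.columns:
                mask = chrom == c
                sub[mask] = counts.loc[mask, c]
        return counts["total"] - sub
    c = normalize_chrom(chrom)
    if c in counts.columns:
        return counts["total"] - counts[c]
    return counts["total"].copy()
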