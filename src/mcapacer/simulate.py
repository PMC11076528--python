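"""Synthetic clonal-expansion cohort generator.

Generative story: each subject acquires a single mCA driver lesion at a
uniformly distributed age t_driver; the mutant clone then grows
logistically with per-year fitness s inside an effective stem-cell pool of
size N_HSC. Clock-like passenger mutations accrue along the pre-driver
lineage at rate mu per year with Gamma-Poisson overdispersion, so a clone
that reached the same size in less time (higher s) carries more "ancestral"
passengers — the signal the scoring stage extracts. Observables are emitted
in the shapes a real pipeline consumes (MoChA-like mCA calls, a somatic
variant table with WGS depth/VAF sampling, sample covariates and blood
counts, a 0/1/2 genotype matrix); the per-subject ground truth is kept in a
separate table that no downstream stage reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig, MCAType, STRONG_ERY_COUPLING  # noqa: F401
from .genome import (
    CENTROMERE_MID,
    CHROM_LENGTHS,
    PASSENGER_CHROMOSOMES,
    chrom_weights,
)

__all__ = [
    "EmptyCohortError",
    "CohortBundle",
    "SimulatedIndividual",
    "clone_cell_fraction",
    "simulate_individual",
    "simulate_cohort",
]

CLOCKLIKE_SUBS = (("C", "T"), ("T", "C"), ("G", "A"), ("A", "G"))
NONCLOCK_SUBS = (
    ("C", "A"), ("C", "G"), ("T", "A"), ("T", "G"),
    ("G", "T"), ("G", "C"), ("A", "T"), ("A", "C"),
)
ALL_SUBS = CLOCKLIKE_SUBS + NONCLOCK_SUBS

# CHIP driver genes used for contaminating annotated variants; mirrors the
# bundled configuration list in data/chip_genes.txt.
_CHIP_GENES = ("DNMT3A", "ASXL1", "TET2", "JAK2")

# Fraction of emitted mCA calls given a deliberately failing lod_baf_phase,
# so the call-level quality filter has true rejections to perform.
_FRAC_LOW_LOD = 0.04

# LD tag SNP for the germline modifier: per-haplotype flip probability.
# Haplotype correlation ~ (1 - 2*eps), i.e. r^2 ~ 0.81 at eps = 0.05.
_TAG_FLIP_PROB = 0.05


class EmptyCohortError(RuntimeError):
    """No simulated clone fell inside the mosaic detection window."""


def clone_cell_fraction(s: float, dt: float, n_hsc: float) -> float:
    """Cell fraction of a clone with fitness ``s`` after ``dt`` years.

    Deterministic logistic growth of a single founder cell inside an
    effective stem-cell pool of fixed size::

        cf = e^(s*dt) / (n_hsc + e^(s*dt) - 1)

    strictly increasing in both ``s`` and ``dt``, equal to ``1/n_hsc`` at
    ``dt = 0`` and saturating at 1. Evaluated in the numerically stable form
    ``1 / (1 + (n_hsc - 1) * e^(-s*dt))``.
    """
    if s < 0 or dt < 0:
        raise ValueError("fitness s and elapsed time dt must be >= 0")
    if n_hsc < 1:
        raise ValueError("n_hsc must be >= 1")
    return 1.0 / (1.0 + (n_hsc - 1.0) * np.exp(-float(s) * float(dt)))


@dataclass
class SimulatedIndividual:
    """One retained subject: ground truth plus all observable records."""

    truth: dict
    sample: dict
    mca_calls: list[dict]
    variants: dict  # column -> np.ndarray, one entry per variant row
    genotypes: dict  # variant id -> allele count
    chip_carrier: bool


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _passes_inline(ref, alt, depth, vaf, gene) -> np.ndarray:
    """Generator-side detectability predicate (kept deliberately independent
    of the passenger_counter module so end-to-end agreement is a real test):
    clock-like substitution after pyrimidine normalization, depth in
    [25, 100], VAF <= 0.35, not in a CHIP gene."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    clock = np.array(
        [
            (r, a) in (("C", "T"), ("T", "C"))
            or (comp[r], comp[a]) in (("C", "T"), ("T", "C"))
            for r, a in zip(ref, alt)
        ]
    )
    ok_gene = np.array([g not in _CHIP_GENES for g in gene])
    return clock & (depth >= 25) & (depth <= 100) & (vaf <= 0.35) & ok_gene


def _mca_call_record(rng, sample_id, mtype: MCAType, cf: float) -> dict:
    chrom = mtype.chromosome
    length = CHROM_LENGTHS[chrom]
    cen = CENTROMERE_MID[chrom]
    if mtype.arm == "whole":
        start, end = 1, length
    elif mtype.arm == "p":
        start = 1
        end = int(cen * (1.0 - 0.08 * rng.random()))
    else:  # q
        start = int(cen * (1.0 + 0.08 * rng.random()))
        end = length
    if mtype.copy_type == "gain":
        rel_cov = 2.0 + cf * (1.0 + rng.normal(0.0, 0.05))
    elif mtype.copy_type == "loss":
        rel_cov = 2.0 - cf * (1.0 + rng.normal(0.0, 0.05))
    else:  # cnloh
        rel_cov = 2.0 + rng.normal(0.0, 0.03)
    rel_cov = float(np.clip(rel_cov, 0.55, 3.2))
    sex_chrom = chrom in ("X", "Y")
    if rng.random() < _FRAC_LOW_LOD:
        lod = rng.uniform(0.5, 4.5) if sex_chrom else rng.uniform(2.0, 19.0)
    else:
        lod = (5.0 if sex_chrom else 20.0) + rng.exponential(80.0)
    return {
        "sample_id": sample_id,
        "chromosome": chrom,
        "start": start,
        "end": end,
        "copy_type": mtype.copy_type,
        "clonal_fraction": round(float(cf), 6),
        "lod_baf_phase": round(float(lod), 3),
        "relative_coverage": round(rel_cov, 4),
    }


def _emit_variants(rng, config: SimConfig, sample_id, mtype, cf, t_driver):
    """All somatic-table rows for one subject; returns (columns, n_anc,
    per-chrom ancestral allocation, intended detectable count)."""
    weights = chrom_weights()
    chroms = list(weights)
    w = np.array([weights[c] for c in chroms])
    if config.mca_chrom_enrichment is not None and mtype.chromosome in weights:
        f = config.mca_chrom_enrichment
        idx = chroms.index(mtype.chromosome)
        rest = w.copy()
        rest[idx] = 0.0
        w = (1.0 - f) * rest / rest.sum()
        w[idx] = f

    mu_t = config.passenger_rate_mu * t_driver
    if config.frailty == "gamma":
        k = config.overdispersion_k
        lam = rng.gamma(k, mu_t / k) if mu_t > 0 else 0.0
    else:
        lam = mu_t * np.exp(rng.normal(0.0, config.frailty_sd))
    n_anc = int(rng.poisson(lam))
    alloc = rng.multinomial(n_anc, w / w.sum())

    rows_chrom, rows_ref, rows_alt, rows_gene, rows_p = [], [], [], [], []

    def add(chrom_arr, sub_idx, sub_table, p_alt, gene=""):
        rows_chrom.extend(chrom_arr)
        rows_ref.extend(sub_table[i][0] for i in sub_idx)
        rows_alt.extend(sub_table[i][1] for i in sub_idx)
        rows_gene.extend([gene] * len(chrom_arr))
        rows_p.extend(p_alt)

    # ancestral clock-like passengers, carried at the clone's cell fraction
    anc_chroms = np.repeat(chroms, alloc)
    add(
        anc_chroms,
        rng.integers(0, len(CLOCKLIKE_SUBS), size=n_anc),
        CLOCKLIKE_SUBS,
        np.full(n_anc, cf / 2.0),
    )
    # non-clock-like somatic mutations on the same lineage
    n_nc = rng.poisson(config.nonclock_frac * mu_t)
    nc_chroms = np.array(chroms)[rng.choice(len(chroms), size=n_nc, p=w / w.sum())]
    add(
        nc_chroms,
        rng.integers(0, len(NONCLOCK_SUBS), size=n_nc),
        NONCLOCK_SUBS,
        np.full(n_nc, cf / 2.0),
    )
    # contaminating germline heterozygous variants (VAF ~ 0.5)
    n_g = rng.poisson(config.germline_rate)
    g_chroms = np.array(chroms)[rng.choice(len(chroms), size=n_g, p=w / w.sum())]
    add(
        g_chroms,
        rng.integers(0, len(ALL_SUBS), size=n_g),
        ALL_SUBS,
        np.full(n_g, 0.5),
    )
    # CHIP-gene-annotated variants (clock-like-looking, must be rejected by
    # the gene filter)
    n_chip = rng.poisson(config.chip_variant_rate)
    chip_chroms = np.array(chroms)[rng.choice(len(chroms), size=n_chip, p=w / w.sum())]
    chip_genes = [
        _CHIP_GENES[i] for i in rng.integers(0, len(_CHIP_GENES), size=n_chip)
    ]
    rows_chrom.extend(chip_chroms)
    idx = rng.integers(0, len(CLOCKLIKE_SUBS), size=n_chip)
    rows_ref.extend(CLOCKLIKE_SUBS[i][0] for i in idx)
    rows_alt.extend(CLOCKLIKE_SUBS[i][1] for i in idx)
    rows_gene.extend(chip_genes)
    rows_p.extend(rng.uniform(0.05, 0.3, size=n_chip))

    m = len(rows_chrom)
    chrom_arr = np.array(rows_chrom, dtype=object)
    depth = rng.poisson(config.mean_depth, size=m)
    p_alt = np.asarray(rows_p, dtype=float)
    alt_reads = rng.binomial(np.maximum(depth, 0), np.clip(p_alt, 0.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt_reads / np.maximum(depth, 1), 0.0)

    pos = rng.integers(1, 2**31, size=m)
    # guarantee (chrom, pos) uniqueness within the sample
    seen: set[tuple[str, int]] = set()
    for i in range(m):
        key = (chrom_arr[i], int(pos[i]))
        while key in seen:
            pos[i] += 1
            key = (chrom_arr[i], int(pos[i]))
        seen.add(key)

    ref_arr = np.array(rows_ref, dtype=object)
    alt_arr = np.array(rows_alt, dtype=object)
    gene_arr = np.array(rows_gene, dtype=object)
    intended = int(_passes_inline(ref_arr, alt_arr, depth, vaf, gene_arr).sum())
    columns = {
        "sample_id": np.full(m, sample_id, dtype=object),
        "chromosome": chrom_arr,
        "position": pos,
        "ref": ref_arr,
        "alt": alt_arr,
        "depth": depth,
        "vaf": np.round(vaf, 6),
        "gene": gene_arr,
    }
    return columns, n_anc, dict(zip(chroms, alloc)), intended


def _log_fitness_sd(config: SimConfig) -> float:
    """Approximate SD of log individual fitness implied by the config
    (lognormal heterogeneity plus the germline modifier)."""
    p = config.modifier_maf
    per_allele = np.log(max(1.0 + config.modifier_effect, 1e-6))
    var_mod = per_allele**2 * 2.0 * p * (1.0 - p)
    return float(max(np.sqrt(config.fitness_sd**2 + var_mod), 0.05))


def _blood_counts(rng, config: SimConfig, coupled: bool, z_fitness: float) -> dict:
    bc = config.blood_counts
    out = {
        "erythrocytes": rng.normal(bc.erythrocytes_mean, bc.erythrocytes_sd),
        "lymphocytes": rng.normal(bc.lymphocytes_mean, bc.lymphocytes_sd),
        "neutrophils": rng.normal(bc.neutrophils_mean, bc.neutrophils_sd),
        "basophils": rng.normal(bc.basophils_mean, bc.basophils_sd),
        "eosinophils": rng.normal(bc.eosinophils_mean, bc.eosinophils_sd),
        "monocytes": rng.normal(bc.monocytes_mean, bc.monocytes_sd),
        "platelets": rng.normal(bc.platelets_mean, bc.platelets_sd),
    }
    if coupled:
        out["erythrocytes"] += bc.ery_coupling_9p * z_fitness
    return {k: round(max(v, 0.0), 4) for k, v in out.items()}


def simulate_individual(
    config: SimConfig, rng: np.random.Generator, index: int = 0
) -> SimulatedIndividual | None:
    """Simulate one subject; returns None if the clone's cell fraction at
    blood draw falls outside the mosaic detection window."""
    sample_id = f"S{index:05d}"
    age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_min, config.age_max)
    w = config.type_weights()
    mtype = config.mca_types[rng.choice(len(config.mca_types), p=w)]
    sex = "female" if rng.random() < config.frac_female else "male"
    if mtype.chromosome == "X" and mtype.copy_type == "loss":
        sex = "female"  # mosaic X loss is a lesion of the female X

    # germline modifier haplotypes (tag SNP in LD with the causal allele)
    hap_mod = rng.random(2) < config.modifier_maf
    flips = rng.random(2) < _TAG_FLIP_PROB
    g_mod = int(hap_mod.sum())
    g_tag = int((hap_mod ^ flips).sum())

    s_true = (
        mtype.fitness
        * (1.0 + config.modifier_effect) ** g_mod
        * float(np.exp(rng.normal(0.0, config.fitness_sd)))
    )
    t_driver = float(rng.uniform(0.0, age))
    cf = clone_cell_fraction(s_true, age - t_driver, config.n_hsc)
    if not (config.detection_limit_cf <= cf <= config.max_cf):
        return None

    variants, n_anc, alloc, intended = _emit_variants(
        rng, config, sample_id, mtype, cf, t_driver
    )
    calls = [_mca_call_record(rng, sample_id, mtype, cf)]
    if rng.random() < config.frac_second_mca:
        others = [
            c for c in PASSENGER_CHROMOSOMES if c != mtype.chromosome and c != "X"
        ]
        c2 = others[rng.integers(0, len(others))]
        start = CENTROMERE_MID[c2] + int(rng.uniform(1e6, 5e6))
        size = int(rng.uniform(5e6, 2e7))
        calls.append(
            {
                "sample_id": sample_id,
                "chromosome": c2,
                "start": start,
                "end": min(start + size, CHROM_LENGTHS[c2]),
                "copy_type": "cnloh",
                "clonal_fraction": round(float(rng.uniform(0.05, 0.3)), 6),
                "lod_baf_phase": round(20.0 + rng.exponential(60.0), 3),
                "relative_coverage": round(2.0 + rng.normal(0.0, 0.03), 4),
            }
        )

    chip_carrier = rng.random() < config.frac_chip_carrier
    if chip_carrier:
        # the carrier's flagged driver SNV (JAK2 V617F-like)
        for col, val in {
            "sample_id": sample_id,
            "chromosome": "9",
            "position": 5_073_770,
            "ref": "G",
            "alt": "T",
            "depth": int(rng.poisson(config.mean_depth)),
            "vaf": round(float(rng.uniform(0.05, 0.3)), 6),
            "gene": "JAK2",
        }.items():
            variants[col] = np.append(variants[col], val)

    coupled = (
        mtype.chromosome == "9"
        and mtype.arm == "p"
        and mtype.copy_type in ("cnloh", "loss")
    ) or chip_carrier
    z_fit = float(np.log(max(s_true, 1e-12)) - np.log(mtype.fitness)) / _log_fitness_sd(config)
    bc = _blood_counts(rng, config, coupled, z_fit)

    baf_ac = (
        round(float(rng.uniform(0.055, 0.1)), 4)
        if rng.random() < config.frac_baf_fail
        else round(float(rng.uniform(0.005, 0.045)), 4)
    )
    sample = {
        "sample_id": sample_id,
        "age_at_draw": round(age, 2),
        "sex": sex,
        "study": config.study_labels[rng.integers(0, len(config.study_labels))],
        **bc,
        "reported_sex_concordant": not (rng.random() < config.frac_sex_discordant),
        "baf_autocorrelation": baf_ac,
        "jak2_chip": chip_carrier,
    }
    truth = {
        "sample_id": sample_id,
        "mca_chromosome": mtype.chromosome,
        "mca_arm": mtype.arm,
        "mca_copy_type": mtype.copy_type,
        "s_type": mtype.fitness,
        "s_true": round(s_true, 8),
        "modifier_genotype": g_mod,
        "t_driver": round(t_driver, 4),
        "cf_true": round(cf, 6),
        "n_ancestral_passengers": n_anc,
        "n_expected_passengers": intended,
    }
    genotypes = {"rs_mod": g_mod, "rs_mod_tag": g_tag}
    return SimulatedIndividual(truth, sample, calls, variants, genotypes, chip_carrier)


@dataclass
class CohortBundle:
    """All tables for one simulated cohort, keyed by sample_id.

    ``truth`` is ground truth for evaluation only; every analysis stage
    consumes exclusively the observable tables.
    """

    samples: pd.DataFrame
    mca_calls: pd.DataFrame
    variants: pd.DataFrame
    genotypes: pd.DataFrame  # index sample_id, one column per variant id
    variant_meta: pd.DataFrame
    truth: pd.DataFrame
    chip_carriers: tuple[str, ...]
    config: SimConfig

    def write(self, outdir) -> None:
        """Write all tables as TSV; truth goes to its own file so pipeline
        stages cannot accidentally consume it."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.mca_calls.to_csv(out / "mca_calls.tsv", sep="\t", index=False)
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.genotypes.to_csv(out / "genotypes.tsv", sep="\t")
        self.variant_meta.to_csv(out / "variant_meta.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "chip_carriers.txt").write_text(
            "".join(f"{s}\n" for s in self.chip_carriers)
        )


def simulate_cohort(config: SimConfig, seed: int | None = None) -> CohortBundle:
    """Simulate ``config.n_individuals`` subjects and retain those whose
    clone is inside the mosaic detection window.

    Raises
    ------
    EmptyCohortError
        If no subject is retained; lower ``detection_limit_cf``, raise the
        fitness values, or simulate more individuals.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    retained: list[SimulatedIndividual] = []
    for i in range(config.n_individuals):
        ind = simulate_individual(config, rng, index=i)
        if ind is not None:
            retained.append(ind)
    if not retained:
        raise EmptyCohortError(
            "no simulated clone fell inside the detection window "
            f"[{config.detection_limit_cf}, {config.max_cf}]; lower "
            "detection_limit_cf, raise mCA fitness values, or increase "
            "n_individuals"
        )

    samples = pd.DataFrame([ind.sample for ind in retained])
    calls = pd.DataFrame([c for ind in retained for c in ind.mca_calls])
    variants = pd.concat(
        [pd.DataFrame(ind.variants) for ind in retained], ignore_index=True
    )
    truth = pd.DataFrame([ind.truth for ind in retained])
    chip = tuple(ind.sample["sample_id"] for ind in retained if ind.chip_carrier)

    # genotype matrix: causal modifier, its LD tag, and null SNPs
    ids = [ind.sample["sample_id"] for ind in retained]
    geno = {
        "rs_mod": [ind.genotypes["rs_mod"] for ind in retained],
        "rs_mod_tag": [ind.genotypes["rs_mod_tag"] for ind in retained],
    }
    meta_rows = [
        {"variant_id": "rs_mod", "chromosome": "14", "position": 95_000_000},
        {"variant_id": "rs_mod_tag", "chromosome": "14", "position": 95_010_000},
    ]
    n = len(retained)
    lo, hi = config.null_snp_maf_range
    for j in range(config.n_null_snps):
        maf = rng.uniform(lo, hi)
        vid = f"null_{j + 1:04d}"
        geno[vid] = rng.binomial(2, maf, size=n)
        chrom = PASSENGER_CHROMOSOMES[rng.integers(0, len(PASSENGER_CHROMOSOMES))]
        meta_rows.append(
            {
                "variant_id": vid,
                "chromosome": chrom,
                "position": int(rng.integers(1, CHROM_LENGTHS[chrom])),
            }
        )
    genotypes = pd.DataFrame(geno, index=pd.Index(ids, name="sample_id"))
    meta = pd.DataFrame(meta_rows)
    meta["alt_freq"] = [genotypes[v].mean() / 2.0 for v in meta["variant_id"]]

    return CohortBundle(
        samples=samples,
        mca_calls=calls,
        variants=variants,
        genotypes=genotypes,
        variant_meta=meta,
        truth=truth,
        chip_carriers=chip,
        config=dataclasses.replace(config),
    )
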