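"""Simulation configuration for the synthetic clonal-expansion cohort.

The defaults encode the study conditions the analysis assumes: a late-life
cohort (median age ~67, 57% female), clock-like passenger accrual at a roughly
constant per-year rate, exponential-then-saturating clone growth within a
fixed effective stem-cell pool, 38x whole-genome sequencing, and a common
germline variant that modifies clonal fitness multiplicatively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class MCAType:
    """One simulated mosaic chromosomal alteration category.

    fitness is the per-year growth advantage s of the clone; weight is the
    relative prevalence of this lesion among simulated driver events.
    """

    chromosome: str
    arm: str  # 'p', 'q' or 'whole'
    copy_type: str  # 'gain', 'loss' or 'cnloh'
    fitness: float
    weight: float = 1.0


@dataclass(frozen=True)
class BloodCountParams:
    """Baseline blood-count distributions and the chr9p erythrocyte coupling.

    Means/SDs are typical adult values: erythrocytes in 10^12 cells/L, the
    leukocyte subsets in 10^9 cells/L, platelets in 10^9/L.
    ery_coupling_9p is the erythrocyte shift (10^12 cells/L) per standard
    deviation of log clonal fitness, applied to carriers of chr9p CN-LOH or
    loss (the JAK2-locus lesions of polycythemia vera).
    """

    erythrocytes_mean: float = 4.6
    erythrocytes_sd: float = 0.45
    lymphocytes_mean: float = 1.9
    lymphocytes_sd: float = 0.5
    neutrophils_mean: float = 3.8
    neutrophils_sd: float = 1.2
    basophils_mean: float = 0.05
    basophils_sd: float = 0.03
    eosinophils_mean: float = 0.15
    eosinophils_sd: float = 0.1
    monocytes_mean: float = 0.5
    monocytes_sd: float = 0.15
    platelets_mean: float = 250.0
    platelets_sd: float = 60.0
    ery_coupling_9p: float = 0.3


#: Erythrocyte coupling preset mimicking the dramatic erythrocytosis of
#: JAK2-driven clones (real chr9p cohorts show blood-count models with
#: R^2 ~ 0.9 at n ~ 10, i.e. coupling dominating baseline variation).
STRONG_ERY_COUPLING = 1.3

#: Multiplicative per-allele fitness effect preset for the germline modifier
#: ("strong" protective allele).
STRONG_MODIFIER_EFFECT = -0.4


def default_mca_types() -> tuple[MCAType, ...]:
    """Default lesion mix: common CN-LOH events, a gain, arm losses, and
    mosaic loss of X as the low-fitness reference lesion."""
    return (
        MCAType("9", "p", "cnloh", 0.28, 0.14),
        MCAType("14", "q", "cnloh", 0.25, 0.14),
        MCAType("11", "q", "cnloh", 0.16, 0.14),
        MCAType("12", "whole", "gain", 0.22, 0.12),
        MCAType("20", "q", "loss", 0.20, 0.14),
        MCAType("13", "q", "loss", 0.18, 0.12),
        MCAType("X", "whole", "loss", 0.13, 0.20),
    )


def fitness_ladder_types(
    fitness_levels: Sequence[float] = (0.10, 0.15, 0.20, 0.25, 0.30),
) -> tuple[MCAType, ...]:
    """Five equally weighted CN-LOH lesions spanning a fitness ladder.

    Used for parameter-recovery experiments: CN-LOH events have neutral
    relative coverage, so the lesion mix interacts minimally with the
    coverage-based call filters and group composition stays interpretable.
    """
    chroms = ("4", "7", "11", "14", "2")
    return tuple(
        MCAType(c, "q", "cnloh", s, 1.0) for c, s in zip(chroms, fitness_levels)
    )


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator.

    n_individuals is the number of simulated subjects (attempts); only clones
    whose cell fraction at blood draw falls inside the mosaic detection window
    [detection_limit_cf, max_cf] enter the observable cohort.
    """

    n_individuals: int = 4000
    age_mean: float = 67.0
    age_sd: float = 9.0
    age_min: float = 40.0
    age_max: float = 97.0
    frac_female: float = 0.57
    mca_types: tuple[MCAType, ...] = field(default_factory=default_mca_types)
    # Clock-like passenger accrual: expected detectable passengers per year of
    # pre-driver lineage, with Gamma-Poisson (negative binomial) dispersion.
    # ~4/yr: HSCs accrue ~10-12 clock-like substitutions per year genome-wide,
    # of which roughly a third are detectable at 38x WGS; puts the simulated
    # per-cohort count scale (median a few tens) on the scale real passenger
    # burdens show.
    passenger_rate_mu: float = 4.0
    overdispersion_k: float = 3.0
    frailty: str = "gamma"  # 'gamma' (NB, correctly specified) or 'lognormal'
    frailty_sd: float = 0.5  # log-scale SD when frailty='lognormal'
    n_hsc: float = 2.0e4
    detection_limit_cf: float = 0.05
    max_cf: float = 0.95
    mean_depth: float = 38.0
    # Per-individual lognormal heterogeneity of clonal fitness (log-scale SD).
    fitness_sd: float = 0.3
    # Germline modifier SNP: per-allele multiplicative effect on s.
    modifier_maf: float = 0.21
    modifier_effect: float = -0.15
    n_null_snps: int = 50
    null_snp_maf_range: tuple[float, float] = (0.05, 0.5)
    blood_counts: BloodCountParams = field(default_factory=BloodCountParams)
    study_labels: tuple[str, ...] = ("SYNTH",)
    # Nuisance structure exercising the QC filters downstream.
    frac_chip_carrier: float = 0.05
    frac_second_mca: float = 0.03
    frac_baf_fail: float = 0.02
    frac_sex_discordant: float = 0.01
    germline_rate: float = 8.0  # mean contaminating germline variants/sample
    nonclock_frac: float = 0.5  # non-clock-like somatic rate as fraction of mu
    chip_variant_rate: float = 0.2  # mean CHIP-gene-annotated variants/sample
    # Adversarial switch: fraction of passengers forced onto the mCA
    # chromosome (None = length-proportional allocation, the null).
    mca_chrom_enrichment: float | None = None
    seed: int | None = None

    def validate(self) -> "SimConfig":
        if self.n_individuals < 0:
            raise ConfigError("n_individuals must be >= 0")
        if not 0.0 <= self.frac_female <= 1.0:
            raise ConfigError("frac_female must be in [0, 1]")
        if not 0.0 < self.detection_limit_cf <= 1.0:
            raise ConfigError("detection_limit_cf must be in (0, 1]")
        if not self.detection_limit_cf <= self.max_cf <= 1.0:
            raise ConfigError("max_cf must be in [detection_limit_cf, 1]")
        for name in (
            "passenger_rate_mu",
            "overdispersion_k",
            "mean_depth",
            "germline_rate",
            "nonclock_frac",
            "chip_variant_rate",
            "fitness_sd",
            "frailty_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_hsc < 1:
            raise ConfigError("n_hsc must be >= 1")
        if not self.mca_types:
            raise ConfigError("mca_types must be non-empty")
        if any(t.weight < 0 for t in self.mca_types):
            raise ConfigError("mca type weights must be >= 0")
        if sum(t.weight for t in self.mca_types) <= 0:
            raise ConfigError("mca type weights must sum to > 0")
        if any(t.fitness < 0 for t in self.mca_types):
            raise ConfigError("mca type fitness must be >= 0")
        if not 0.0 <= self.modifier_maf <= 0.5:
            raise ConfigError("modifier_maf must be in [0, 0.5]")
        if self.frailty not in ("gamma", "lognormal"):
            raise ConfigError("frailty must be 'gamma' or 'lognormal'")
        if self.mca_chrom_enrichment is not None and not (
            0.0 <= self.mca_chrom_enrichment <= 1.0
        ):
            raise ConfigError("mca_chrom_enrichment must be in [0, 1]")
        if not (0 < self.age_min <= self.age_mean <= self.age_max):
            raise ConfigError("age bounds must satisfy 0 < min <= mean <= max")
        return self

    def type_weights(self) -> tuple[float, ...]:
        total = sum(t.weight for t in self.mca_types)
        return tuple(t.weight / total for t in self.mca_types)

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mca_types"] = [dataclasses.asdict(t) for t in self.mca_types]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "mca_types" in d:
            d["mca_types"] = tuple(MCAType(**t) for t in d["mca_types"])
        if "blood_counts" in d and isinstance(d["blood_counts"], dict):
            d["blood_counts"] = BloodCountParams(**d["blood_counts"])
        for key in ("null_snp_maf_range", "study_labels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
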