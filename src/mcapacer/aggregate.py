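"""Per-mCA fitness estimates from individual expansion-rate scores.

An mCA's fitness is estimated as the median score of all individuals
carrying that lesion (keyed by chromosome, arm, copy type), with fold
changes reported relative to mosaic loss of the X chromosome — the
slow-growing reference lesion. Because scores live on a standard-normal
scale, a ratio of medians can be negative or unstable near zero; the table
therefore carries a machine-readable sign warning and a difference-of-
medians column as a stable alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "MalignancyClassSpec",
    "DEFAULT_CLASSES",
    "XLOSS_KEY",
    "aggregate_fitness",
    "fold_change",
    "compare_external",
    "classify_mca",
    "class_membership",
    "class_contrast",
    "ExternalComparison",
    "ContrastResult",
]

#: Group key of the fold-change reference lesion (mosaic X loss spans the
#: centromere, so its arm resolves to 'whole').
XLOSS_KEY = ("X", "whole", "loss")


@dataclass(frozen=True)
class MalignancyClassSpec:
    """Curated mCA sets linked to lineage-specific hematologic malignancy.

    Entries are (chromosome, arm, copy_type); arm None means the entry is
    chromosome-level and matches a call on any arm. The lymphoid and myeloid
    sets both contain CN-LOH of 9q, so single-label classification applies
    the precedence pv > lymphoid > myeloid.
    """

    lymphoid: frozenset
    myeloid: frozenset
    pv: frozenset


DEFAULT_CLASSES = MalignancyClassSpec(
    lymphoid=frozenset(
        {
            ("12", None, "gain"),
            ("10", "q", "loss"),
            ("13", "q", "loss"),
            ("8", "q", "cnloh"),
            ("9", "q", "cnloh"),
            ("13", "q", "cnloh"),
        }
    ),
    myeloid=frozenset(
        {
            ("20", "q", "loss"),
            ("5", "q", "loss"),
            ("8", None, "gain"),
            ("9", "q", "cnloh"),
            ("14", "q", "cnloh"),
            ("22", "q", "cnloh"),
        }
    ),
    pv=frozenset({("9", "p", "cnloh"), ("9", "p", "loss")}),
)


def _matches(mca: tuple, entry: tuple) -> bool:
    chrom, arm, copy_type = mca
    e_chrom, e_arm, e_copy = entry
    if str(chrom) != e_chrom or copy_type != e_copy:
        return False
    if e_arm is None:  # chromosome-level entry: any arm qualifies
        return True
    # an arm-level entry is matched by that arm or by a whole-chromosome call
    return arm == e_arm or arm == "whole"


def class_membership(mca: tuple, spec: MalignancyClassSpec = DEFAULT_CLASSES) -> frozenset[str]:
    """All malignancy classes an mCA belongs to (possibly several)."""
    out = set()
    for name in ("lymphoid", "myeloid", "pv"):
        if any(_matches(mca, e) for e in getattr(spec, name)):
            out.add(name)
    return frozenset(out)


def classify_mca(mca: tuple, spec: MalignancyClassSpec = DEFAULT_CLASSES) -> str:
    """Single malignancy-class label: 'pv', 'lymphoid', 'myeloid' or
    'neither' (precedence pv > lymphoid > myeloid where sets overlap)."""
    member = class_membership(mca, spec)
    for name in ("pv", "lymphoid", "myeloid"):
        if name in member:
            return name
    return "neither"


def aggregate_fitness(
    results: pd.DataFrame,
    cohort,
    samples: pd.DataFrame | None = None,
    collapse_arms: bool = False,
) -> pd.DataFrame:
    """Median score per (chromosome, arm, copy_type) group.

    With ``collapse_arms=True`` groups are keyed by chromosome and copy type
    only (arm reported as 'whole'), reproducing chromosome-level summaries.
    Output is sorted by fitness descending; ties broken by group key for
    determinism.
    """
    assignments = getattr(cohort, "assignments", cohort)
    merged = results.merge(assignments, on="sample_id", how="inner", validate="1:1")
    if samples is not None:
        merged = merged.merge(
            samples[["sample_id", "age_at_draw"]], on="sample_id", how="left"
        )
    else:
        merged["age_at_draw"] = np.nan
    if collapse_arms:
        merged = merged.assign(arm="whole")
    grouped = merged.groupby(["chromosome", "arm", "copy_type"], sort=True)
    table = grouped.agg(
        n_individuals=("sample_id", "size"),
        fitness=("score", "median"),
        median_age=("age_at_draw", "median"),
        median_cf=("clonal_fraction", "median"),
    ).reset_index()
    return table.sort_values(
        ["fitness", "chromosome", "arm", "copy_type"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)


def fold_change(table: pd.DataFrame, reference: tuple = XLOSS_KEY) -> pd.DataFrame:
    """Fold change of each group's fitness relative to the reference lesion.

    Adds fold_change_vs_ref (reference row exactly 1), fitness_diff_vs_ref,
    and sign_warning (True on every row when the reference fitness is <= 0,
    where a ratio of scores loses its meaning).
    """
    chrom, arm, copy_type = reference
    mask = (
        (table["chromosome"].astype(str) == str(chrom))
        & (table["arm"] == arm)
        & (table["copy_type"] == copy_type)
    )
    if not mask.any():
        raise KeyError(
            f"reference group {reference} absent from fitness table; cannot "
            "compute fold changes"
        )
    ref_fitness = float(table.loc[mask, "fitness"].iloc[0])
    out = table.copy()
    out["fold_change_vs_ref"] = out["fitness"] / ref_fitness
    out.loc[mask, "fold_change_vs_ref"] = 1.0
    out["fitness_diff_vs_ref"] = out["fitness"] - ref_fitness
    out["sign_warning"] = ref_fitness <= 0
    return out


@dataclass
class ExternalComparison:
    """OLS comparison of per-mCA fitness against an external estimate."""

    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    r2_full: float
    r2_age_only: float
    r2_score_only: float
    n_groups: int


def compare_external(
    table: pd.DataFrame, external: pd.DataFrame, min_n: int = 25
) -> ExternalComparison:
    """Regress an external per-mCA fitness estimate on the score-derived one.

    ``external`` needs columns chromosome, arm, copy_type, fitness. Groups
    with more than ``min_n`` individuals (strictly) enter an OLS of external
    fitness on (score fitness, median age, median clonal fraction); R^2 is
    reported for the full model and for age-only / score-only reductions.
    """
    key = ["chromosome", "arm", "copy_type"]
    ext = external.rename(columns={"fitness": "external_fitness"})
    merged = table[table["n_individuals"] > min_n].merge(ext, on=key, how="inner")
    merged = merged.dropna(subset=["external_fitness", "fitness", "median_age", "median_cf"])
    if len(merged) < 5:
        raise ValueError(
            f"insufficient overlapping groups ({len(merged)} after min_n filter); need >= 5"
        )
    y = merged["external_fitness"].to_numpy()

    def _ols_r2(cols):
        X = sm.add_constant(merged[cols].to_numpy())
        return sm.OLS(y, X).fit()

    full = _ols_r2(["fitness", "median_age", "median_cf"])
    names = ["const", "fitness", "median_age", "median_cf"]
    return ExternalComparison(
        params=pd.Series(full.params, index=names),
        conf_int=pd.DataFrame(full.conf_int(), index=names, columns=["lo", "hi"]),
        pvalues=pd.Series(full.pvalues, index=names),
        r2_full=float(full.rsquared),
        r2_age_only=float(_ols_r2(["median_age"]).rsquared),
        r2_score_only=float(_ols_r2(["fitness"]).rsquared),
        n_groups=len(merged),
    )


@dataclass
class ContrastResult:
    f_stat: float
    p_value: float
    group_stats: pd.DataFrame


def class_contrast(
    results: pd.DataFrame,
    cohort,
    spec: MalignancyClassSpec = DEFAULT_CLASSES,
) -> ContrastResult:
    """One-way ANOVA of scores across lymphoid / myeloid / neither classes.

    pv-class individuals are folded into the class precedence of
    classify_mca; groups with fewer than 2 members are dropped, and at least
    two groups must remain.
    """
    assignments = getattr(cohort, "assignments", cohort)
    merged = results.merge(assignments, on="sample_id", how="inner", validate="1:1")
    labels = [
        classify_mca((r.chromosome, r.arm, r.copy_type), spec)
        for r in merged.itertuples()
    ]
    merged = merged.assign(mca_class=labels)
    merged = merged[merged["mca_class"].isin(["lymphoid", "myeloid", "neither"])]
    groups = [
        g["score"].to_numpy()
        for _, g in merged.groupby("mca_class")
        if len(g) >= 2
    ]
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 members each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every class")
    f, p = st.f_oneway(*groups)
    stats = (
        merged.groupby("mca_class")["score"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
    return ContrastResult(f_stat=float(f), p_value=float(p), group_stats=stats)
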