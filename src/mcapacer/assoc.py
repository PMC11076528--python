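"""Downstream association analyses on expansion-rate scores.

Blood-count regressions for curated mCA classes, covariate-adjusted
single-variant association of germline genotypes with inverse-normal
transformed passenger counts, and conditional analysis of a lead SNP
against a correlated SNP. Genotypes are assumed unrelated, so plain
fixed-effects least squares replaces the kinship-adjusted mixed models used
on biobank-scale data (see README); ancestry principal components are
accepted as extra covariate columns when supplied, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .aggregate import DEFAULT_CLASSES, MalignancyClassSpec, classify_mca
from .scoring import rank_inverse_normal

__all__ = [
    "GENOME_WIDE_P",
    "AssociationResult",
    "BloodCountResult",
    "myeloid_sum",
    "blood_count_model",
    "single_variant_scan",
    "conditional_test",
    "ld_r2",
]

GENOME_WIDE_P = 5e-8

MYELOID_COMPONENTS = ("neutrophils", "basophils", "eosinophils", "monocytes")


def myeloid_sum(samples: pd.DataFrame) -> pd.Series:
    """Myeloid cell count: neutrophils + basophils + eosinophils + monocytes
    (10^9 cells/L); missing if any component is missing."""
    missing = [c for c in MYELOID_COMPONENTS if c not in samples.columns]
    if missing:
        raise KeyError(f"missing myeloid component columns: {missing}")
    parts = samples[list(MYELOID_COMPONENTS)].astype(float)
    out = parts.sum(axis=1, skipna=False)
    out.name = "myeloid_count"
    return out


_CLASS_OUTCOME_DEFAULTS = {
    "lymphoid": "lymphocytes",
    "myeloid": "myeloid_count",
    "pv": "erythrocytes",
    "jak2_chip": "erythrocytes",
}


@dataclass
class BloodCountResult:
    mca_class: str
    outcome: str
    beta_score: float
    ci_score: tuple[float, float]
    p_score: float
    r2_full: float
    r2_without_score: float
    n: int
    covariates: tuple[str, ...]


def blood_count_model(
    samples: pd.DataFrame,
    results: pd.DataFrame,
    cohort,
    mca_class: str,
    outcome: str | None = None,
    spec: MalignancyClassSpec = DEFAULT_CLASSES,
    exclude_lymphocyte_outliers: bool = False,
    min_cases: int | None = None,
) -> BloodCountResult:
    """OLS of a blood count on age, sex, clonal fraction and the score,
    within one curated mCA class.

    For the pv class (chr9p lesions) the clonal-fraction covariate is
    omitted, matching the published 9p erythrocyte model. mca_class
    'jak2_chip' selects samples whose ``jak2_chip`` flag is set instead of
    an mCA class. ``exclude_lymphocyte_outliers`` drops outcomes above
    10 x 10^9 cells/L (lymphocyte sensitivity analysis).
    """
    if outcome is None:
        outcome = _CLASS_OUTCOME_DEFAULTS[mca_class]
    if samples["sample_id"].duplicated().any():
        raise ValueError("non-unique sample_id in sample table")
    assignments = getattr(cohort, "assignments", cohort)
    merged = results.merge(assignments, on="sample_id", how="inner").merge(
        samples, on="sample_id", how="inner", validate="1:1"
    )
    if mca_class == "jak2_chip":
        if "jak2_chip" not in merged.columns:
            raise KeyError("sample table lacks a 'jak2_chip' flag column")
        sel = merged[merged["jak2_chip"].astype(bool)]
    else:
        labels = [
            classify_mca((r.chromosome, r.arm, r.copy_type), spec)
            for r in merged.itertuples()
        ]
        sel = merged[np.asarray(labels) == mca_class]
    if outcome == "myeloid_count" and "myeloid_count" not in sel.columns:
        sel = sel.assign(myeloid_count=myeloid_sum(sel).to_numpy())
    if outcome not in sel.columns:
        raise KeyError(f"outcome column {outcome!r} not present")
    if exclude_lymphocyte_outliers and outcome == "lymphocytes":
        sel = sel[sel[outcome] <= 10.0]

    covs = ["age_at_draw", "sex_female", "clonal_fraction", "score"]
    if mca_class == "pv":
        covs.remove("clonal_fraction")
    sel = sel.assign(sex_female=sel["sex"].map({"female": 1.0, "male": 0.0}))
    cols = covs + [outcome]
    sel = sel.dropna(subset=cols)
    n = len(sel)
    needed = max(len(covs) + 4, min_cases if min_cases is not None else 8)
    if n < needed:
        raise ValueError(f"too few complete cases ({n}) for class {mca_class!r}")

    y = sel[outcome].to_numpy(dtype=float)
    X_full = sm.add_constant(sel[covs].to_numpy(dtype=float))
    fit = sm.OLS(y, X_full).fit()
    reduced_covs = [c for c in covs if c != "score"]
    X_red = sm.add_constant(sel[reduced_covs].to_numpy(dtype=float))
    fit_red = sm.OLS(y, X_red).fit()
    j = covs.index("score") + 1  # offset for the constant
    ci = fit.conf_int()[j]
    return BloodCountResult(
        mca_class=mca_class,
        outcome=outcome,
        beta_score=float(fit.params[j]),
        ci_score=(float(ci[0]), float(ci[1])),
        p_score=float(fit.pvalues[j]),
        r2_full=float(fit.rsquared),
        r2_without_score=float(fit_red.rsquared),
        n=n,
        covariates=tuple(covs),
    )


def _assoc_design(
    samples: pd.DataFrame,
    cohort,
    covariates=("age", "sex", "cf", "study"),
    extra_covariate_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    from .scoring import build_design

    assignments = getattr(cohort, "assignments", cohort)
    design, _ = build_design(samples, assignments, covariates)
    if extra_covariate_cols:
        extra = samples.set_index("sample_id")[list(extra_covariate_cols)]
        design = design.join(extra.reindex(design.index))
    return design


def single_variant_scan(
    genotypes: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cohort,
    variant_meta: pd.DataFrame | None = None,
    covariates=("age", "sex", "cf", "study"),
    extra_covariate_cols: tuple[str, ...] = (),
    maf_min: float = 0.01,
    max_missing: float = 0.10,
) -> pd.DataFrame:
    """Per-variant linear association with inverse-normal passenger counts.

    The outcome is the rank-based inverse-normal transform (Blom offsets) of
    total passenger counts; each variant's allele count enters a fixed-
    effects OLS with the stated covariates (computed via residualization,
    which is algebraically identical to the joint OLS). Variants with minor
    allele frequency <= maf_min, missingness >= max_missing, or constant
    genotype are skipped. The significance flag applies the genome-wide
    threshold 5e-8.
    """
    design = _assoc_design(samples, cohort, covariates, extra_covariate_cols)
    ids = design.index.intersection(genotypes.index).intersection(counts.index)
    design = design.loc[ids]
    y = rank_inverse_normal(counts.loc[ids, "total"].to_numpy(dtype=float))

    X = np.column_stack([np.ones(len(ids)), design.to_numpy(dtype=float)])
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    p_cov = X.shape[1]
    dof = len(ids) - p_cov - 1

    meta = (
        variant_meta.set_index("variant_id")
        if variant_meta is not None
        else pd.DataFrame()
    )
    rows = []
    skipped = []
    for vid in genotypes.columns:
        g = genotypes.loc[ids, vid].to_numpy(dtype=float)
        miss = np.isnan(g)
        if miss.mean() >= max_missing:
            skipped.append((vid, "missingness"))
            continue
        if miss.any():
            g = np.where(miss, np.nanmean(g), g)
        af = g.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf <= maf_min:
            skipped.append((vid, "maf"))
            continue
        if np.ptp(g) == 0:
            skipped.append((vid, "constant"))
            continue
        g_res = g - Q @ (Q.T @ g)
        gg = float(g_res @ g_res)
        if gg <= 1e-12:
            skipped.append((vid, "collinear_with_covariates"))
            continue
        beta = float(g_res @ y_res) / gg
        rss = float(y_res @ y_res) - beta**2 * gg
        se = float(np.sqrt(max(rss, 0.0) / dof / gg))
        tstat = beta / se if se > 0 else np.nan
        p = float(2.0 * st.t.sf(abs(tstat), dof))
        row = {
            "variant_id": vid,
            "af": af,
            "beta": beta,
            "se": se,
            "p": p,
            "n": len(ids),
            "significant": p < GENOME_WIDE_P,
        }
        if vid in meta.index:
            row["chromosome"] = meta.at[vid, "chromosome"]
            row["position"] = meta.at[vid, "position"]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    out.attrs["covariates"] = tuple(covariates) + tuple(extra_covariate_cols)
    return out


@dataclass
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple[str, ...]
    collinear: bool = False


def _single_ols(y, g, X, vid, covariates) -> AssociationResult:
    M = np.column_stack([X, g])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        return AssociationResult(vid, np.nan, np.nan, np.nan, len(y), covariates, collinear=True)
    fit = sm.OLS(y, M).fit()
    return AssociationResult(
        vid,
        float(fit.params[-1]),
        float(fit.bse[-1]),
        float(fit.pvalues[-1]),
        len(y),
        covariates,
    )


def conditional_test(
    lead: str,
    conditioned: str,
    genotypes: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cohort,
    covariates=("age", "sex", "cf", "study"),
    extra_covariate_cols: tuple[str, ...] = (),
) -> tuple[AssociationResult, AssociationResult]:
    """Marginal and conditional association for a lead variant.

    The conditional model adds the conditioned variant's allele count to the
    lead variant's regression; if lead and conditioned genotypes are exactly
    collinear the conditional result is flagged instead of fitted.
    """
    for vid in (lead, conditioned):
        if vid not in genotypes.columns:
            raise KeyError(f"variant {vid!r} not in genotype matrix")
    design = _assoc_design(samples, cohort, covariates, extra_covariate_cols)
    ids = design.index.intersection(genotypes.index).intersection(counts.index)
    design = design.loc[ids]
    y = rank_inverse_normal(counts.loc[ids, "total"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(ids)), design.to_numpy(dtype=float)])
    g_lead = genotypes.loc[ids, lead].to_numpy(dtype=float)
    g_cond = genotypes.loc[ids, conditioned].to_numpy(dtype=float)
    covs = tuple(covariates) + tuple(extra_covariate_cols)

    marginal = _single_ols(y, g_lead, X, lead, covs)
    if np.ptp(g_cond) == 0:
        # a constant conditioned covariate is absorbed by the intercept: the
        # conditional model equals the marginal model exactly
        conditional = AssociationResult(
            lead, marginal.beta, marginal.se, marginal.p, marginal.n,
            covs + (conditioned,),
        )
    else:
        conditional = _single_ols(
            y, g_lead, np.column_stack([X, g_cond]), lead, covs + (conditioned,)
        )
    return marginal, conditional


def ld_r2(genotypes: pd.DataFrame, a: str, b: str) -> float:
    """Composite linkage disequilibrium: squared Pearson correlation of
    allele counts (no phasing needed)."""
    ga = genotypes[a].to_numpy(dtype=float)
    gb = genotypes[b].to_numpy(dtype=float)
    ok = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[ok], gb[ok]
    if np.ptp(ga) == 0 or np.ptp(gb) == 0:
        raise ValueError("constant genotype column; LD undefined")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r**2)
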