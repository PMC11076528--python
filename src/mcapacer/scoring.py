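"""Covariate-adjusted clonal-expansion scores from passenger counts.

The score for an individual is the residual of their clock-like passenger
count from an NB2 negative-binomial regression on age, sex, clonal fraction
(and study indicators when several studies are present), passed through a
Yeo-Johnson power transform (lambda by maximum likelihood) and standardized
to mean 0, variance 1. Because the transform is monotone, the score is a
rank-preserving, approximately Gaussian re-expression of "more passengers
than expected given age, sex and clone size" — the proxy for a faster
expanding clone.

A companion score computed on counts excluding the individual's mCA
chromosome supports the confounding check that the lesion itself does not
drive the count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .genome import chrom_weights, normalize_chrom
from .passengers import total_excluding

__all__ = [
    "FitError",
    "DegenerateResidualsError",
    "NBModelFit",
    "ScoreReport",
    "ExclusionCheck",
    "fit_nb",
    "pacer_transform",
    "rank_inverse_normal",
    "score_cohort",
    "chromosome_exclusion_check",
]


class FitError(RuntimeError):
    """Negative-binomial fit could not be computed or did not converge."""


class DegenerateResidualsError(ValueError):
    """Residual vector is constant or too short to transform."""


@dataclass
class NBModelFit:
    """NB2 maximum-likelihood fit (log link; variance mu + alpha * mu^2)."""

    coefficients: pd.Series
    stderr: pd.Series
    alpha: float  # NB2 overdispersion (variance mu + alpha mu^2)
    fitted: pd.Series  # mean per sample
    llf: float
    converged: bool
    iterations: int
    gradient_norm: float

    @property
    def dispersion(self) -> float:
        """NB shape parameter k = 1/alpha (Poisson limit as k -> inf)."""
        return np.inf if self.alpha <= 0 else 1.0 / self.alpha


def fit_nb(counts, design: pd.DataFrame, add_intercept: bool = True) -> NBModelFit:
    """Fit an NB2 negative-binomial regression of counts on the design table.

    Parameters
    ----------
    counts : array-like of nonnegative integers, length n.
    design : numeric DataFrame (n rows); an intercept column is added unless
        ``add_intercept=False`` or a constant column is already present.

    Raises
    ------
    FitError
        For all-zero counts, a rank-deficient design, too few observations
        (n < 10 per covariate), or an optimizer that fails outright.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1:
        raise FitError("counts must be one-dimensional")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise FitError("counts must be nonnegative integers")
    if np.all(y == 0):
        raise FitError("all counts are zero; nothing to fit")
    X = design.astype(float).copy()
    if add_intercept:
        # constant covariates are absorbed by the intercept: an all-constant
        # design legitimately reduces to the intercept-only model
        X = X.drop(columns=[c for c in X.columns if X[c].nunique() == 1])
        X.insert(0, "const", 1.0)
    n, p = X.shape
    if n < 10 * max(p - 1, 1):
        raise FitError(f"need >= {10 * max(p - 1, 1)} observations for {p - 1} covariates, got {n}")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise FitError("design matrix is rank deficient (collinear covariates)")

    # standardize covariate columns internally: the optimizer then sees the
    # same numerical problem under any affine rescaling of a covariate, so
    # fitted means (and scores downstream) are exactly rescaling-invariant
    Xs = X.to_numpy().copy()
    shifts = np.zeros(p)
    scales = np.ones(p)
    for j, col in enumerate(X.columns):
        if col == "const":
            continue
        sd = Xs[:, j].std()
        if sd > 0:
            shifts[j] = Xs[:, j].mean()
            scales[j] = sd
            Xs[:, j] = (Xs[:, j] - shifts[j]) / sd

    model = NegativeBinomial(y, Xs, loglike_method="nb2")
    # warm start: Poisson coefficients + moment estimate of alpha
    pois = sm.GLM(y, Xs, family=sm.families.Poisson()).fit()
    mu0 = pois.fittedvalues
    alpha0 = max(((y - mu0) ** 2 - mu0).sum() / (mu0**2).sum(), 1e-4)
    start = np.append(pois.params, alpha0)

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method, kwargs in (
            ("bfgs", {"gtol": 1e-10}),
            ("nm", {"xtol": 1e-10, "ftol": 1e-12, "maxfun": 20000}),
        ):
            try:
                cand = model.fit(
                    start_params=start, method=method, maxiter=2000, disp=0, **kwargs
                )
            except Exception:
                continue
            if res is None or cand.llf > res.llf:
                res = cand
            if cand.mle_retvals.get("converged", False):
                res = cand
                break
    if res is None:
        raise FitError("negative binomial optimization failed")

    # Newton polish to machine-precision optimum (quadratic convergence from
    # the line-search solution); makes the fit reproducible to ~1e-12 for
    # numerically equivalent inputs
    theta = np.asarray(res.params, dtype=float).copy()
    theta[-1] = max(theta[-1], 1e-8)
    ll_cur = model.loglike(theta)
    n_newton = 0
    for _ in range(50):
        g = model.score(theta)
        if np.linalg.norm(g) < 1e-9:
            break
        try:
            H = model.hessian(theta)
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        improved = False
        damp = 1.0
        for _ in range(30):
            cand = theta - damp * step
            if cand[-1] > 0:
                ll_new = model.loglike(cand)
                if np.isfinite(ll_new) and ll_new >= ll_cur - 1e-12:
                    theta, ll_cur, improved = cand, ll_new, True
                    break
            damp *= 0.5
        n_newton += 1
        if not improved:
            break
    final_params = theta
    final_llf = float(ll_cur)
    final_grad = model.score(theta)

    # back-transform coefficients (and their SEs) to the original scale
    beta_s = final_params[:-1]
    beta = beta_s / scales
    if "const" in X.columns:
        j0 = list(X.columns).index("const")
        beta[j0] = beta_s[j0] - np.sum(beta_s * shifts / scales)
    params = pd.Series(beta, index=list(X.columns))
    try:
        # observed-information covariance at the polished optimum,
        # delta-method transformed to the original covariate scale
        cov_full = np.linalg.inv(-model.hessian(final_params))
        A = np.diag(1.0 / scales)
        if "const" in X.columns:
            A[j0, :] = -shifts / scales
            A[j0, j0] = 1.0
        cov_s = cov_full[:p, :p]
        bse = np.sqrt(np.clip(np.diag(A @ cov_s @ A.T), 0.0, None))
        stderr = pd.Series(bse, index=list(X.columns))
    except Exception:
        stderr = pd.Series(np.nan, index=list(X.columns))
    alpha = float(max(final_params[-1], 0.0))
    fitted = pd.Series(np.exp(Xs @ beta_s), index=design.index)
    gnorm = float(np.linalg.norm(final_grad))
    return NBModelFit(
        coefficients=params,
        stderr=stderr,
        alpha=alpha,
        fitted=fitted,
        llf=final_llf,
        converged=bool(res.mle_retvals.get("converged", False)) or gnorm < 1e-5,
        iterations=int(res.mle_retvals.get("iterations", -1)) + n_newton,
        gradient_norm=gnorm,
    )


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets."""
    x = np.asarray(values, dtype=float)
    ranks = st.rankdata(x)
    return st.norm.ppf((ranks - offset) / (len(x) + 1.0 - 2.0 * offset))


def pacer_transform(residuals, method: str = "yeo-johnson") -> np.ndarray:
    """Yeo-Johnson inverse-normal transform of model residuals.

    Fits the Yeo-Johnson power parameter by maximum likelihood, applies the
    (strictly monotone) transform, and standardizes to mean 0, variance 1.
    ``method='rank'`` substitutes the rank-based inverse-normal transform
    (Blom offsets) instead.
    """
    x = np.asarray(residuals, dtype=float)
    if len(x) < 20:
        raise DegenerateResidualsError(f"need >= 20 residuals, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise DegenerateResidualsError("residuals contain non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateResidualsError("degenerate residuals: constant vector")
    if method == "rank":
        z = rank_inverse_normal(x)
    elif method == "yeo-johnson":
        # solve the MLE power parameter to tight tolerance so that scores are
        # reproducible to ~1e-8 under numerically equivalent inputs
        from scipy import optimize

        lam = optimize.brent(
            lambda l: -st.yeojohnson_llf(l, x), brack=(-2.0, 2.0), tol=1e-12
        )
        z = st.yeojohnson(x, lmbda=float(lam))
    else:
        raise ValueError(f"unknown transform method {method!r}")
    return (z - z.mean()) / z.std(ddof=0)


def _residuals(y: np.ndarray, mu: np.ndarray, alpha: float, kind: str) -> np.ndarray:
    if kind == "raw":
        return y - mu
    if kind == "pearson":
        return (y - mu) / np.sqrt(mu + alpha * mu**2)
    if kind == "deviance":
        # NB2 deviance residuals, signed
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            a = max(alpha, 1e-12)
            t2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
        d2 = np.maximum(2.0 * (t1 - t2), 0.0)
        return np.sign(y - mu) * np.sqrt(d2)
    raise ValueError(f"unknown residual type {kind!r}")


def build_design(
    samples: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates=("age", "sex", "cf", "study"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scoring design matrix for the cohort, aligned on sample_id.

    Returns (design indexed by sample_id, drop log). Samples with a missing
    clonal fraction or missing sex are dropped and logged.
    """
    if samples["sample_id"].duplicated().any():
        raise ValueError("non-unique sample_id in sample table")
    merged = assignments.merge(samples, on="sample_id", how="inner", validate="1:1")
    cols = {}
    drop = pd.Series(False, index=merged.index)
    reasons = pd.Series("", index=merged.index)
    if "age" in covariates:
        cols["age"] = merged["age_at_draw"].astype(float)
    if "sex" in covariates:
        sex = merged["sex"].map({"female": 1.0, "male": 0.0})
        missing = sex.isna()
        drop |= missing
        reasons[missing] += "missing_sex;"
        cols["sex_female"] = sex
    if "cf" in covariates:
        cf = pd.to_numeric(merged["clonal_fraction"], errors="coerce")
        missing = cf.isna()
        drop |= missing
        reasons[missing] += "missing_clonal_fraction;"
        cols["clonal_fraction"] = cf
    design = pd.DataFrame(
        {k: v.to_numpy() for k, v in cols.items()},
        index=pd.Index(merged["sample_id"], name="sample_id"),
    )
    if "study" in covariates and "study" in merged.columns:
        studies = sorted(merged["study"].astype(str).unique())
        for s in studies[1:]:  # first study is the reference level
            design[f"study_{s}"] = (merged["study"].astype(str) == s).astype(float).to_numpy()
    log = pd.DataFrame(
        {
            "sample_id": merged.loc[drop, "sample_id"],
            "reason": reasons[drop].str.rstrip(";"),
        }
    )
    return design[~drop.to_numpy()], log


@dataclass
class ScoreReport:
    """Scored cohort plus the two NB fits behind the scores."""

    results: pd.DataFrame
    fit_total: NBModelFit
    fit_excluding: NBModelFit | None
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)


def score_cohort(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cohort,
    covariates=("age", "sex", "cf", "study"),
    residual_type: str = "raw",
    transform: str = "yeo-johnson",
) -> ScoreReport:
    """Compute per-individual expansion-rate scores for a defined cohort.

    Runs the full pipeline (NB fit -> residuals -> Yeo-Johnson
    inverse-normal) twice: on total passenger counts, and on totals
    excluding each individual's mCA chromosome.

    ``cohort`` is a CohortDefinition or its assignments DataFrame.
    """
    assignments = getattr(cohort, "assignments", cohort)
    design, dropped = build_design(samples, assignments, covariates)
    ids = design.index
    totals = counts.loc[ids, "total"]

    fit_t = fit_nb(totals.to_numpy(), design)
    resid_t = _residuals(totals.to_numpy(dtype=float), fit_t.fitted.to_numpy(), fit_t.alpha, residual_type)
    score_t = pacer_transform(resid_t, method=transform)

    chrom_series = assignments.set_index("sample_id")["chromosome"].reindex(ids)
    totals_ex = total_excluding(counts.loc[ids], chrom_series)
    fit_e = fit_nb(totals_ex.to_numpy(), design)
    resid_e = _residuals(totals_ex.to_numpy(dtype=float), fit_e.fitted.to_numpy(), fit_e.alpha, residual_type)
    score_e = pacer_transform(resid_e, method=transform)

    results = pd.DataFrame(
        {
            "sample_id": ids,
            "raw_count": totals.to_numpy(dtype=int),
            "residual": resid_t,
            "score": score_t,
            "raw_count_excluding": totals_ex.to_numpy(dtype=int),
            "score_excluding_mca_chrom": score_e,
        }
    ).reset_index(drop=True)
    return ScoreReport(results=results, fit_total=fit_t, fit_excluding=fit_e, dropped=dropped)


@dataclass
class ExclusionCheck:
    """Chromosome-exclusion sensitivity analysis output."""

    mode: str
    rho: float
    rho_p: float
    pooled_z: float
    pooled_p: float
    per_sample: pd.DataFrame


def chromosome_exclusion_check(
    report: ScoreReport,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cohort,
    mode: str = "mca_chrom",
    seed: int | None = None,
    covariates=("age", "sex", "cf", "study"),
) -> ExclusionCheck:
    """Check that the mCA chromosome does not drive the score.

    Returns the Spearman correlation between the score and the score
    recomputed without the (mCA or random) chromosome, plus a pooled
    rate test of whether passenger density on that chromosome departs from
    its genome-length share (per-sample counts are binomial with
    length-proportional success probability under the uniform-accrual null;
    the pooled z aggregates over samples).
    """
    assignments = getattr(cohort, "assignments", cohort)
    res = report.results
    if len(res) < 10:
        raise ValueError("need at least 10 scored individuals")
    ids = res["sample_id"]
    chrom = (
        assignments.set_index("sample_id")["chromosome"]
        .reindex(ids)
        .map(normalize_chrom)
    )
    weights = chrom_weights()
    if mode == "mca_chrom":
        test_chrom = chrom
        score_ex = res["score_excluding_mca_chrom"].to_numpy()
    elif mode == "random_chrom":
        rng = np.random.default_rng(seed)
        pool = list(weights)
        picks = []
        for m in chrom:
            alternatives = [c for c in pool if c != m]
            picks.append(alternatives[rng.integers(0, len(alternatives))])
        test_chrom = pd.Series(picks, index=chrom.index)
        totals_ex = total_excluding(counts.loc[ids], test_chrom)
        design, _ = build_design(samples, assignments, covariates)
        design = design.loc[ids]
        fit = fit_nb(totals_ex.to_numpy(), design)
        resid = totals_ex.to_numpy(dtype=float) - fit.fitted.to_numpy()
        score_ex = pacer_transform(resid)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rho, rho_p = st.spearmanr(res["score"], score_ex)

    # density rate test: on-chromosome count ~ Binomial(total, length share)
    x = np.array(
        [
            counts.at[s, c] if c in counts.columns else 0
            for s, c in zip(ids, test_chrom)
        ],
        dtype=float,
    )
    n = counts.loc[ids, "total"].to_numpy(dtype=float)
    p0 = np.array([weights.get(c, 0.0) for c in test_chrom])
    expected = n * p0
    var = n * p0 * (1.0 - p0)
    pooled_z = float((x.sum() - expected.sum()) / np.sqrt(var.sum()))
    pooled_p = float(2.0 * st.norm.sf(abs(pooled_z)))
    per_sample = pd.DataFrame(
        {
            "sample_id": ids.to_numpy(),
            "chromosome": test_chrom.to_numpy(),
            "on_chrom": x.astype(int),
            "total": n.astype(int),
            "length_share": p0,
            "expected": expected,
        }
    )
    return ExclusionCheck(
        mode=mode,
        rho=float(rho),
        rho_p=float(rho_p),
        pooled_z=pooled_z,
        pooled_p=pooled_p,
        per_sample=per_sample,
    )
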