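"""NB regression, residual transform, cohort scoring, exclusion check."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import mcapacer as m
from mcapacer import scoring


def nb_loglik(y, X, beta, alpha):
    """Independent NB2 log-likelihood (oracle; no statsmodels)."""
    from scipy.special import gammaln

    mu = np.exp(X @ beta)
    k = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + k)
            - gammaln(k)
            - gammaln(y + 1)
            + k * np.log(k / (k + mu))
            + y * np.log(mu / (k + mu))
        )
    )


class TestFitNB:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(22)
        n = 5000
        age_dec = rng.uniform(4, 9, n)  # age in decades
        beta_true = np.array([1.0, np.log(0.8)])  # per-decade effect
        mu = np.exp(beta_true[0] + beta_true[1] * age_dec)
        k = 3.0
        y = rng.negative_binomial(k, k / (k + mu))
        design = pd.DataFrame({"age_dec": age_dec})
        fit = m.fit_nb(y, design)
        se = fit.stderr
        for name, truth in zip(["const", "age_dec"], beta_true):
            assert abs(fit.coefficients[name] - truth) < 2 * se[name]
        assert fit.converged

    def test_intercept_only_mean_equals_sample_mean(self):
        rng = np.random.default_rng(3)
        y = rng.negative_binomial(2, 0.1, size=200)
        design = pd.DataFrame({"z": np.ones(200)})  # constant covariate
        fit = m.fit_nb(y, design)
        assert fit.fitted.iloc[0] == pytest.approx(y.mean(), rel=1e-6)
        assert (fit.fitted.nunique()) == 1

    def test_poisson_limit(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.normal(size=n)
        mu = np.exp(2.0 + 0.3 * x)
        y = rng.poisson(mu)
        design = pd.DataFrame({"x": x})
        fit = m.fit_nb(y, design)
        X = np.column_stack([np.ones(n), x])
        import statsmodels.api as sm

        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.llf >= pois.llf - 0.1

    def test_all_zero_counts_rejected(self):
        with pytest.raises(scoring.FitError):
            m.fit_nb(np.zeros(100), pd.DataFrame({"x": np.arange(100.0)}))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        design = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(scoring.FitError):
            m.fit_nb(rng.poisson(5, 200), design)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(6)
        design = pd.DataFrame({"a": rng.normal(size=15), "b": rng.normal(size=15)})
        with pytest.raises(scoring.FitError):
            m.fit_nb(rng.poisson(5, 15), design)


class TestPacerTransform:
    def test_normal_input_is_close_to_zscore(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10_000)
        out = m.pacer_transform(x)
        z = (x - x.mean()) / x.std()
        assert np.max(np.abs(out - z)) < 0.05

    def test_rank_preservation(self):
        rng = np.random.default_rng(8)
        x = rng.gamma(2, 5, size=500) - 8
        out = m.pacer_transform(x)
        rho, _ = st.spearmanr(x, out)
        assert rho == 1.0

    def test_symmetric_input_symmetric_output(self):
        x = np.tile([-1.0, 0.0, 1.0], 7)
        out = m.pacer_transform(x)
        assert np.allclose(np.sort(out), -np.sort(-out)[::-1])
        assert out[x == 0].mean() == pytest.approx(0.0, abs=1e-6)

    def test_standardized_output(self):
        rng = np.random.default_rng(9)
        out = m.pacer_transform(rng.exponential(size=1000))
        assert abs(out.mean()) < 1e-8
        assert out.std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(scoring.DegenerateResidualsError):
            m.pacer_transform(np.ones(50))
        with pytest.raises(scoring.DegenerateResidualsError):
            m.pacer_transform(np.arange(10.0))

    def test_rank_variant(self):
        rng = np.random.default_rng(10)
        x = rng.exponential(size=200)
        out = m.pacer_transform(x, method="rank")
        assert st.spearmanr(x, out)[0] == 1.0
        assert abs(out.mean()) < 1e-8


def _tiny_cohort(counts_by_sample, age=60.0, sex="female", cf=0.2):
    n = len(counts_by_sample)
    ids = [f"T{i:03d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "age_at_draw": age,
            "sex": sex,
            "study": "A",
        }
    )
    assignments = pd.DataFrame(
        {
            "sample_id": ids,
            "chromosome": "7",
            "arm": "q",
            "copy_type": "cnloh",
            "clonal_fraction": cf,
        }
    )
    counts = pd.DataFrame(
        {"7": 0, "total": list(counts_by_sample)},
        index=pd.Index(ids, name="sample_id"),
    )
    counts["1"] = counts["total"]
    counts["7"] = 0
    return counts[["1", "7", "total"]], samples, assignments


class TestScoreCohort:
    def test_monotone_in_count_at_fixed_covariates(self):
        rng = np.random.default_rng(11)
        base = rng.poisson(40, size=40)
        base[0], base[1] = 80, 20
        counts, samples, assignments = _tiny_cohort(base)
        rep = m.score_cohort(counts, samples, assignments)
        res = rep.results.set_index("sample_id")
        assert res.loc["T000", "score"] > res.loc["T001", "score"]

    def test_row_order_invariance(self, ladder):
        rep = ladder["report"]
        counts = ladder["counts"]
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(counts))
        shuffled = counts.iloc[perm]
        assign_shuffled = ladder["cohort"].assignments.sample(
            frac=1.0, random_state=1
        )
        rep2 = m.score_cohort(
            shuffled, ladder["samples"], assign_shuffled
        )
        a = rep.results.set_index("sample_id")["score"]
        b = rep2.results.set_index("sample_id")["score"]
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-6)

    def test_affine_covariate_rescaling_invariance(self, ladder):
        samples2 = ladder["samples"].copy()
        samples2["age_at_draw"] = samples2["age_at_draw"] * 10.0 + 7.0
        rep2 = m.score_cohort(ladder["counts"], samples2, ladder["cohort"])
        a = ladder["report"].results.set_index("sample_id")["score"]
        b = rep2.results.set_index("sample_id")["score"]
        assert np.max(np.abs(a.sort_index() - b.sort_index())) < 1e-6

    def test_score_distribution_near_normal_when_well_specified(self, ladder):
        # counts drawn from the NB model itself (correctly specified): the
        # transformed scores should be close to standard normal
        rng = np.random.default_rng(20)
        design, _ = scoring.build_design(ladder["samples"], ladder["cohort"].assignments)
        n = len(design)
        X = np.column_stack([np.ones(n), design.to_numpy()])
        beta = np.array([2.5, 0.015, -0.1, -1.0, ][: X.shape[1]])
        if len(beta) < X.shape[1]:
            beta = np.append(beta, np.zeros(X.shape[1] - len(beta)))
        mu = np.exp(X @ beta)
        k = 3.0
        y = rng.negative_binomial(k, k / (k + mu))
        counts = pd.DataFrame({"total": y, "1": y}, index=design.index)[["1", "total"]]
        fit = m.fit_nb(y, design)
        resid = y - fit.fitted.to_numpy()
        score = m.pacer_transform(resid)
        ks = st.kstest(score, "norm").statistic
        assert ks < 0.05

    def test_missing_clonal_fraction_dropped_with_log(self, ladder):
        samples = ladder["samples"]
        assignments = ladder["cohort"].assignments.copy()
        victim = assignments.iloc[0]["sample_id"]
        assignments.loc[assignments["sample_id"] == victim, "clonal_fraction"] = np.nan
        rep = m.score_cohort(ladder["counts"], samples, assignments)
        assert victim not in set(rep.results["sample_id"])
        assert victim in set(rep.dropped["sample_id"])

    def test_nb_optimum_beats_brute_force_grid(self):
        # oracle equivalence on a tiny dataset: the fitted NB2 likelihood is
        # at least the best over a dense grid around the optimum
        rng = np.random.default_rng(13)
        n = 30
        x1 = rng.normal(size=n)
        x2 = rng.uniform(size=n)
        mu = np.exp(2.0 + 0.4 * x1 - 0.5 * x2)
        k = 2.0
        y = rng.negative_binomial(k, k / (k + mu))
        design = pd.DataFrame({"x1": x1, "x2": x2})
        fit = m.fit_nb(y, design)
        X = np.column_stack([np.ones(n), x1, x2])
        b0 = fit.coefficients.to_numpy()
        grid = [np.linspace(b - 2, b + 2, 13) for b in b0]
        alphas = np.concatenate([np.linspace(0.02, 2, 25), np.linspace(2.2, 10, 10)])
        best = -np.inf
        for g0 in grid[0]:
            for g1 in grid[1]:
                for g2 in grid[2]:
                    beta = np.array([g0, g1, g2])
                    for a in alphas:
                        best = max(best, nb_loglik(y, X, beta, a))
        assert fit.llf >= best - 1e-6


class TestExclusionCheck:
    def test_rho_one_when_mca_chromosome_empty(self):
        rng = np.random.default_rng(14)
        counts, samples, assignments = _tiny_cohort(rng.poisson(40, size=60))
        # chromosome 7 (the assigned mCA chromosome) carries zero passengers
        rep = m.score_cohort(counts, samples, assignments)
        chk = m.chromosome_exclusion_check(rep, counts, samples, assignments)
        assert chk.rho == pytest.approx(1.0)

    def test_null_rho_high_and_density_centered(self, ladder):
        rep = ladder["report"]
        chk = m.chromosome_exclusion_check(
            rep, ladder["counts"], ladder["samples"], ladder["cohort"]
        )
        assert chk.rho >= 0.8
        assert abs(chk.pooled_z) < 4

    def test_random_chromosome_mode(self, ladder):
        chk = m.chromosome_exclusion_check(
            ladder["report"],
            ladder["counts"],
            ladder["samples"],
            ladder["cohort"],
            mode="random_chrom",
            seed=5,
        )
        assert chk.rho >= 0.8
        assert (
            chk.per_sample["chromosome"].to_numpy()
            != ladder["cohort"].assignments.set_index("sample_id")
            .loc[chk.per_sample["sample_id"], "chromosome"]
            .to_numpy()
        ).all()

    def test_adversarial_enrichment_detected(self):
        cfg = m.SimConfig(
            n_individuals=1500,
            mca_types=m.fitness_ladder_types(),
            mca_chrom_enrichment=0.5,
            n_null_snps=0,
        )
        from conftest import run_upstream

        data = run_upstream(cfg, 17)
        rep = m.score_cohort(data["counts"], data["samples"], data["cohort"])
        chk = m.chromosome_exclusion_check(
            rep, data["counts"], data["samples"], data["cohort"]
        )
        assert chk.pooled_p < 1e-6  # density test flags the enrichment

        # matched null run: same size and seed, no enrichment; removing the
        # mCA chromosome must disturb the ranking more under enrichment
        null_cfg = m.SimConfig(
            n_individuals=1500, mca_types=m.fitness_ladder_types(), n_null_snps=0
        )
        null_data = run_upstream(null_cfg, 17)
        null_rep = m.score_cohort(
            null_data["counts"], null_data["samples"], null_data["cohort"]
        )
        null_chk = m.chromosome_exclusion_check(
            null_rep, null_data["counts"], null_data["samples"], null_data["cohort"]
        )
        assert chk.rho < null_chk.rho

    def test_too_small_cohort_rejected(self):
        rng = np.random.default_rng(15)
        counts, samples, assignments = _tiny_cohort(rng.poisson(40, size=5))
        rep_results = pd.DataFrame(
            {"sample_id": counts.index, "score": 0.0, "score_excluding_mca_chrom": 0.0}
        )
        fake = scoring.ScoreReport(rep_results, None, None)
        with pytest.raises(ValueError):
            m.chromosome_exclusion_check(fake, counts, samples, assignments)
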