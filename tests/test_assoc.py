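"""Blood-count regressions, variant scan, conditional analysis, LD."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import mcapacer as m
from mcapacer import assoc
from conftest import run_upstream


class TestMyeloidSum:
    def test_addition(self):
        samples = pd.DataFrame(
            {"neutrophils": [3.0], "basophils": [0.1], "eosinophils": [0.2], "monocytes": [0.5]}
        )
        assert assoc.myeloid_sum(samples).iloc[0] == pytest.approx(3.8)

    def test_missing_component_propagates(self):
        samples = pd.DataFrame(
            {"neutrophils": [3.0, np.nan], "basophils": [0.1, 0.1], "eosinophils": [0.2, 0.2], "monocytes": [0.5, 0.5]}
        )
        out = assoc.myeloid_sum(samples)
        assert out.iloc[0] == pytest.approx(3.8)
        assert np.isnan(out.iloc[1])

    def test_all_zero(self):
        samples = pd.DataFrame(
            {"neutrophils": [0.0], "basophils": [0.0], "eosinophils": [0.0], "monocytes": [0.0]}
        )
        assert assoc.myeloid_sum(samples).iloc[0] == 0.0

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            assoc.myeloid_sum(pd.DataFrame({"neutrophils": [1.0]}))


def synthetic_class_cohort(rng, n=200, beta=0.0, outcome_sd=0.5):
    """Hand-built lymphoid-mCA cohort with a controllable score effect."""
    ids = [f"B{i:04d}" for i in range(n)]
    score = rng.normal(size=n)
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "age_at_draw": rng.uniform(50, 85, n),
            "sex": rng.choice(["female", "male"], n),
            "lymphocytes": 1.9 + beta * score + rng.normal(0, outcome_sd, n),
            "neutrophils": 3.8,
            "basophils": 0.05,
            "eosinophils": 0.15,
            "monocytes": 0.5,
            "erythrocytes": 4.6,
        }
    )
    results = pd.DataFrame({"sample_id": ids, "score": score})
    assignments = pd.DataFrame(
        {
            "sample_id": ids,
            "chromosome": "12",
            "arm": "whole",
            "copy_type": "gain",
            "clonal_fraction": rng.uniform(0.05, 0.5, n),
        }
    )
    return samples, results, assignments


class TestBloodCountModel:
    def test_null_outcome_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        covered = 0
        reps = 30
        for _ in range(reps):
            samples, results, assignments = synthetic_class_cohort(rng, beta=0.0)
            r = m.blood_count_model(samples, results, assignments, "lymphoid")
            lo, hi = r.ci_score
            covered += lo <= 0 <= hi
        assert covered >= 0.9 * reps

    def test_chr9p_erythrocyte_coupling_power_at_strong_preset(self):
        bc = dataclasses.replace(m.BloodCountParams(), ery_coupling_9p=m.STRONG_ERY_COUPLING)
        types = (m.MCAType("9", "p", "cnloh", 0.25, 1.0),)
        hits = 0
        reps = 12
        for seed in range(reps):
            cfg = m.SimConfig(
                n_individuals=230, mca_types=types, blood_counts=bc, n_null_snps=0
            )
            data = run_upstream(cfg, 100 + seed)
            rep = m.score_cohort(data["counts"], data["samples"], data["cohort"])
            r = m.blood_count_model(data["samples"], rep.results, data["cohort"], "pv")
            hits += (r.beta_score > 0) and (r.p_score < 0.05)
        assert hits >= 0.8 * reps

    def test_pv_model_omits_clonal_fraction(self):
        rng = np.random.default_rng(1)
        samples, results, assignments = synthetic_class_cohort(rng)
        assignments = assignments.assign(chromosome="9", arm="p", copy_type="cnloh")
        r = m.blood_count_model(samples, results, assignments, "pv", outcome="erythrocytes")
        assert "clonal_fraction" not in r.covariates

    def test_lymphocyte_outlier_exclusion(self):
        rng = np.random.default_rng(2)
        samples, results, assignments = synthetic_class_cohort(rng, n=60)
        samples.loc[:2, "lymphocytes"] = 25.0
        r_all = m.blood_count_model(samples, results, assignments, "lymphoid")
        r_trim = m.blood_count_model(
            samples, results, assignments, "lymphoid", exclude_lymphocyte_outliers=True
        )
        assert r_trim.n == r_all.n - 3

    def test_duplicate_sample_rows_rejected(self):
        rng = np.random.default_rng(3)
        samples, results, assignments = synthetic_class_cohort(rng, n=30)
        dup = pd.concat([samples, samples.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            m.blood_count_model(dup, results, assignments, "lymphoid")

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(4)
        samples, results, assignments = synthetic_class_cohort(rng, n=5)
        with pytest.raises(ValueError):
            m.blood_count_model(samples, results, assignments, "lymphoid")


class TestSingleVariantScan:
    def test_null_snp_type_one_error_and_uniform_p(self, ladder):
        scan = m.single_variant_scan(
            ladder["bundle"].genotypes,
            ladder["counts"],
            ladder["samples"],
            ladder["cohort"],
        )
        nulls = scan[scan["variant_id"].str.startswith("null_")]
        assert len(nulls) > 900
        rate = (nulls["p"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065
        ks = st.kstest(nulls["p"], "uniform").statistic
        assert ks < 0.05

    def test_modifier_beta_negative(self, ladder):
        scan = m.single_variant_scan(
            ladder["bundle"].genotypes,
            ladder["counts"],
            ladder["samples"],
            ladder["cohort"],
        )
        row = scan[scan["variant_id"] == "rs_mod"].iloc[0]
        assert row["beta"] < 0

    def test_allele_coding_swap_flips_beta_sign(self, default_cohort):
        geno = default_cohort["bundle"].genotypes[["rs_mod"]]
        flipped = 2 - geno
        kw = dict(
            counts=default_cohort["counts"],
            samples=default_cohort["samples"],
            cohort=default_cohort["cohort"],
        )
        a = m.single_variant_scan(geno, **kw).iloc[0]
        b = m.single_variant_scan(flipped, **kw).iloc[0]
        assert a["beta"] == pytest.approx(-b["beta"], rel=1e-9)
        assert a["p"] == pytest.approx(b["p"], rel=1e-9)

    def test_rare_variant_filtered(self, default_cohort):
        n = len(default_cohort["bundle"].genotypes)
        rng = np.random.default_rng(5)
        geno = pd.DataFrame(
            {"rare": rng.binomial(2, 0.003, n), "common": rng.binomial(2, 0.3, n)},
            index=default_cohort["bundle"].genotypes.index,
        )
        scan = m.single_variant_scan(
            geno,
            default_cohort["counts"],
            default_cohort["samples"],
            default_cohort["cohort"],
            maf_min=0.01,
        )
        assert "rare" not in set(scan["variant_id"])
        assert "common" in set(scan["variant_id"])

    def test_constant_genotype_skipped(self, default_cohort):
        geno = pd.DataFrame(
            {"const_snp": 1},
            index=default_cohort["bundle"].genotypes.index,
        )
        scan = m.single_variant_scan(
            geno,
            default_cohort["counts"],
            default_cohort["samples"],
            default_cohort["cohort"],
        )
        assert scan.empty
        assert ("const_snp", "maf") in scan.attrs["skipped"] or (
            "const_snp",
            "constant",
        ) in scan.attrs["skipped"]


class TestConditional:
    def test_zero_conditioned_column_equals_marginal(self, default_cohort):
        geno = default_cohort["bundle"].genotypes[["rs_mod"]].copy()
        geno["zero"] = 0
        marg, cond = m.conditional_test(
            "rs_mod",
            "zero",
            geno,
            default_cohort["counts"],
            default_cohort["samples"],
            default_cohort["cohort"],
        )
        assert not cond.collinear
        assert cond.beta == marg.beta
        assert cond.p == marg.p

    def test_exact_collinearity_flagged(self, default_cohort):
        geno = default_cohort["bundle"].genotypes[["rs_mod"]].copy()
        geno["copy"] = geno["rs_mod"]
        marg, cond = m.conditional_test(
            "rs_mod",
            "copy",
            geno,
            default_cohort["counts"],
            default_cohort["samples"],
            default_cohort["cohort"],
        )
        assert not marg.collinear
        assert cond.collinear

    def test_independent_conditioned_leaves_beta(self, default_cohort):
        rng = np.random.default_rng(6)
        geno = default_cohort["bundle"].genotypes[["rs_mod"]].copy()
        geno["indep"] = rng.binomial(2, 0.3, len(geno))
        marg, cond = m.conditional_test(
            "rs_mod",
            "indep",
            geno,
            default_cohort["counts"],
            default_cohort["samples"],
            default_cohort["cohort"],
        )
        assert abs(cond.beta - marg.beta) < 2 * marg.se

    def test_signal_mediated_by_conditioned_variant_attenuates(self):
        # causal variant in LD (r^2 ~ 0.8) with the lead: conditioning on the
        # causal variant should attenuate the lead's significance
        rng = np.random.default_rng(7)
        attenuated = 0
        reps = 10
        for _ in range(reps):
            n = 1500
            h = rng.random((n, 2)) < 0.25
            flips = rng.random((n, 2)) < 0.055
            g_causal = h.sum(axis=1)
            g_lead = (h ^ flips).sum(axis=1)
            y = -0.25 * g_causal + rng.normal(size=n)
            ids = [f"L{i}" for i in range(n)]
            geno = pd.DataFrame(
                {"lead": g_lead, "causal": g_causal}, index=pd.Index(ids, name="sample_id")
            )
            counts = pd.DataFrame(
                {"total": np.round(50 + 10 * y).astype(int).clip(0)},
                index=pd.Index(ids, name="sample_id"),
            )
            samples = pd.DataFrame(
                {
                    "sample_id": ids,
                    "age_at_draw": 65.0 + rng.normal(size=n),
                    "sex": rng.choice(["female", "male"], n),
                    "study": "A",
                }
            )
            assignments = pd.DataFrame(
                {
                    "sample_id": ids,
                    "chromosome": "14",
                    "arm": "q",
                    "copy_type": "cnloh",
                    "clonal_fraction": rng.uniform(0.05, 0.5, n),
                }
            )
            marg, cond = m.conditional_test(
                "lead", "causal", geno, counts, samples, assignments
            )
            attenuated += cond.p > marg.p
        assert attenuated >= 9


class TestLD:
    def test_identical_columns_r2_one(self):
        g = pd.DataFrame({"a": [0, 1, 2, 1, 0, 2], "b": [0, 1, 2, 1, 0, 2]})
        assert m.ld_r2(g, "a", "b") == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        g = pd.DataFrame(
            {"a": rng.binomial(2, 0.3, 10_000), "b": rng.binomial(2, 0.3, 10_000)}
        )
        assert m.ld_r2(g, "a", "b") < 0.01

    def test_constant_column_rejected(self):
        g = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 1, 2, 1]})
        with pytest.raises(ValueError):
            m.ld_r2(g, "a", "b")
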