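"""Stepwise conditional eQTL mapping, signal isolation, replication, pi1."""

import numpy as np
import pytest
from scipy import stats

from condcoloc import (
    ExpressionMatrix,
    SimScenario,
    all_but_one,
    beta_for_variance_explained,
    bh_threshold,
    estimate_pi1,
    fit_snp_gene,
    marginal_scan,
    replicate_models,
    simulate_expression,
    simulate_genotypes,
    stepwise_conditional,
)

from oracles import bh_cutoff_enumeration

WIDE_WINDOW = ("1", 1, 2_000_000_000)


def _expr_for(geno, planted, noise_sd, rng, gene="g1"):
    return simulate_expression(geno, {gene: planted}, noise_sd, rng)[0]


class TestFitSnpGene:
    def test_perfect_fit(self):
        dosage = np.array([0.0, 1.0, 1.0, 2.0, 0.0, 2.0])
        beta, se, p = fit_snp_gene(2.0 * dosage, dosage)
        assert beta == pytest.approx(2.0, abs=1e-12)
        assert p < 1e-12

    def test_hand_computed_ols_slope(self):
        # dosage (0,1,1,2), expr (0,1,2,3): slope = Sxy/Sxx = 3/2
        beta, _, _ = fit_snp_gene(np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 1, 2]))
        assert beta == pytest.approx(1.5, abs=1e-12)

    def test_matches_full_model_ols(self, rng, small_geno):
        """FWL-residualized scan equals statsmodels full-model OLS exactly."""
        import statsmodels.api as sm

        n = len(small_geno.sample_ids)
        covar = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        x = small_geno.dosages[:, 7]
        beta, se, p = fit_snp_gene(y, x, covar)
        fit = sm.OLS(y, np.column_stack([np.ones(n), covar, x])).fit()
        assert beta == pytest.approx(fit.params[-1], abs=1e-10)
        assert se == pytest.approx(fit.bse[-1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        n = 200
        pvals = []
        for _ in range(1000):
            x = rng.binomial(2, 0.3, size=n).astype(float)
            y = rng.standard_normal(n)
            pvals.append(fit_snp_gene(y, x)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_flagged(self):
        beta, se, p = fit_snp_gene(np.arange(5.0), np.ones(5))
        assert beta == 0.0 and p == 1.0


class TestReadVcf:
    VCF_TEXT = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT:DS\t0/1:0.9\t1/1:2.0\t0/0:0.1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t./.\t1/1\n"
    )

    def test_ds_preferred_gt_fallback_and_missing(self, tmp_path):
        from condcoloc.eqtl import read_vcf_dosages

        path = tmp_path / "t.vcf"
        path.write_text(self.VCF_TEXT)
        geno = read_vcf_dosages(path)
        assert geno.sample_ids == ["S1", "S2", "S3"]
        assert geno.variant_ids == ["rs1", "rs2"]
        np.testing.assert_allclose(geno.dosages[:, 0], [0.9, 2.0, 0.1], atol=1e-6)
        assert geno.dosages[0, 1] == 1.0 and np.isnan(geno.dosages[1, 1])
        geno.mean_impute()
        assert geno.dosages[1, 1] == pytest.approx(1.5)  # mean of 1 and 2


class TestBhThreshold:
    @pytest.mark.parametrize(
        "pvals,fdr,expected",
        [
            ([0.01, 0.02, 0.03, 0.5], 0.05, 0.03),
            ([1.0, 1.0, 1.0], 0.05, 0.0),
            ([0.04], 0.05, 0.04),
        ],
    )
    def test_examples(self, pvals, fdr, expected):
        assert bh_threshold(pvals, fdr) == pytest.approx(expected)

    def test_matches_enumeration_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200)) ** rng.uniform(1, 3)
            fdr = rng.uniform(0.01, 0.2)
            assert bh_threshold(p, fdr) == pytest.approx(bh_cutoff_enumeration(p, fdr))

    def test_agrees_with_statsmodels_rejections(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=300) ** 2
        cutoff = bh_threshold(p, 0.05)
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(p <= cutoff, reject)


class TestStepwise:
    def test_single_huge_signal_gives_model_of_one(self, rng):
        scenario = SimScenario(seed=21, n_variants=50, n_samples=300)
        geno = simulate_genotypes(scenario)
        expr = _expr_for(geno, [(25, 2.0)], 0.5, rng)
        model = stepwise_conditional("g1", geno, expr, None, 1e-5, WIDE_WINDOW)
        assert len(model) == 1
        assert model.steps[0].esnp_id == geno.variant_ids[25]

    def test_two_planted_signals_recovered(self, rng):
        """Two uncorrelated signals at the default per-signal variance
        explained (10%, n=500) are both found (allowing near-perfect LD
        proxies) in >= 19/20 replicates."""
        hits = 0
        for rep in range(20):
            scenario = SimScenario(seed=100 + rep, n_variants=100, n_samples=500, block_size=10)
            geno = simulate_genotypes(scenario)
            i1, i2 = 5, 75  # different LD blocks: population r2 ~ 0
            ve = scenario.eqtl_var_explained
            planted = [
                (i, beta_for_variance_explained(geno.dosages[:, i], ve, 1.0 / (1 - 2 * ve)))
                for i in (i1, i2)
            ]
            expr = _expr_for(geno, planted, 1.0, rng)
            model = stepwise_conditional("g1", geno, expr, None, 1e-5, WIDE_WINDOW)
            found = 0
            for i in (i1, i2):
                for vid in model.esnp_ids:
                    j = geno.variant_ids.index(vid)
                    r = np.corrcoef(geno.dosages[:, i], geno.dosages[:, j])[0, 1]
                    if r * r > 0.95:
                        found += 1
                        break
            hits += found == 2
        assert hits >= 19

    def test_null_gene_gives_empty_model(self, rng):
        empties = 0
        for rep in range(20):
            scenario = SimScenario(seed=300 + rep, n_variants=100, n_samples=300)
            geno = simulate_genotypes(scenario)
            expr = _expr_for(geno, [], 1.0, rng)
            model = stepwise_conditional("g1", geno, expr, None, 1e-5, WIDE_WINDOW)
            empties += len(model) == 0
        assert empties >= 19

    def test_each_step_reduces_rss(self, rng):
        scenario = SimScenario(seed=31, n_variants=60, n_samples=400)
        geno = simulate_genotypes(scenario)
        planted = [
            (i, beta_for_variance_explained(geno.dosages[:, i], 0.1, 1.0 / 0.8))
            for i in (3, 43)
        ]
        expr = _expr_for(geno, planted, 1.0, rng)
        model = stepwise_conditional("g1", geno, expr, None, 1e-4, WIDE_WINDOW)
        assert len(model) >= 2
        y = expr.gene("g1")
        prev_rss = np.inf
        for k in range(1, len(model) + 1):
            cols = [geno.variant_ids.index(v) for v in model.esnp_ids[:k]]
            X = np.column_stack([np.ones(len(y)), geno.dosages[:, cols]])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            rss = float(resid @ resid)
            assert rss <= prev_rss
            prev_rss = rss

    def test_selected_p_is_scan_minimum(self, rng):
        scenario = SimScenario(seed=41, n_variants=50, n_samples=300)
        geno = simulate_genotypes(scenario)
        expr = _expr_for(geno, [(10, 0.5)], 1.0, rng)
        model = stepwise_conditional("g1", geno, expr, None, 1e-5, WIDE_WINDOW)
        assert len(model) >= 1
        _, _, p = marginal_scan(expr.gene("g1"), geno.dosages)
        assert model.steps[0].p == pytest.approx(p.min())

    def test_deterministic_rerun(self, rng):
        scenario = SimScenario(seed=51, n_variants=50, n_samples=300)
        geno = simulate_genotypes(scenario)
        expr = _expr_for(geno, [(10, 0.4)], 1.0, rng)
        m1 = stepwise_conditional("g1", geno, expr, None, 1e-4, WIDE_WINDOW, gene_tss=1_000_000)
        m2 = stepwise_conditional("g1", geno, expr, None, 1e-4, WIDE_WINDOW, gene_tss=1_000_000)
        assert m1.esnp_ids == m2.esnp_ids


class TestAllButOne:
    @pytest.fixture
    def fitted(self, rng):
        scenario = SimScenario(seed=61, n_variants=60, n_samples=400, block_size=10)
        geno = simulate_genotypes(scenario)
        planted = [
            (i, beta_for_variance_explained(geno.dosages[:, i], 0.08, 1.0 / 0.76))
            for i in (5, 25, 45)
        ]
        expr = _expr_for(geno, planted, 1.0, rng)
        model = stepwise_conditional("g1", geno, expr, None, 1e-4, WIDE_WINDOW)
        assert len(model) >= 2
        return geno, expr, model

    def test_size_one_model_equals_marginal_scan(self, rng):
        scenario = SimScenario(seed=71, n_variants=40, n_samples=300)
        geno = simulate_genotypes(scenario)
        expr = _expr_for(geno, [(20, 1.0)], 1.0, rng)
        model = stepwise_conditional("g1", geno, expr, None, 1e-5, WIDE_WINDOW)
        assert len(model) == 1
        iso = all_but_one("g1", model, geno, expr, None, 1)
        beta, se, p = marginal_scan(expr.gene("g1"), geno.dosages)
        np.testing.assert_allclose(iso.beta, beta, atol=1e-12)
        np.testing.assert_allclose(iso.p, p, atol=1e-12)

    def test_focal_esnp_equals_joint_regression_coefficient(self, fitted):
        """At the focal eSNP the isolated scan IS the joint model: exact."""
        geno, expr, model = fitted
        y = expr.gene("g1")
        cols = [geno.variant_ids.index(v) for v in model.esnp_ids]
        X = np.column_stack([np.ones(len(y)), geno.dosages[:, cols]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = len(y) - X.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        for focal in range(1, len(model) + 1):
            iso = all_but_one("g1", model, geno, expr, None, focal)
            j = iso.variant_ids.index(model.steps[focal - 1].esnp_id)
            assert iso.beta[j] == pytest.approx(coef[focal], abs=1e-10)
            assert iso.se[j] == pytest.approx(np.sqrt(cov[focal, focal]), abs=1e-10)

    def test_focal_order_out_of_range(self, fitted):
        geno, expr, model = fitted
        with pytest.raises(ValueError, match="out of range"):
            all_but_one("g1", model, geno, expr, None, len(model) + 1)

    def test_model_size_yields_that_many_scans(self, fitted):
        geno, expr, model = fitted
        scans = [all_but_one("g1", model, geno, expr, None, k) for k in range(1, len(model) + 1)]
        assert len(scans) == len(model)
        for k, iso in enumerate(scans, 1):
            assert iso.conditioned_on == [v for i, v in enumerate(model.esnp_ids) if i != k - 1]


class TestReplication:
    @pytest.fixture
    def discovery(self, rng):
        scenario = SimScenario(seed=81, n_variants=60, n_samples=400, block_size=10)
        geno = simulate_genotypes(scenario)
        planted = {
            "g1": [(5, beta_for_variance_explained(geno.dosages[:, 5], 0.15, 1.0 / 0.85))],
            "g2": [(35, beta_for_variance_explained(geno.dosages[:, 35], 0.15, 1.0 / 0.85))],
        }
        expr, _ = simulate_expression(geno, planted, 1.0, rng)
        models = [
            stepwise_conditional(g, geno, expr, None, 1e-5, WIDE_WINDOW) for g in ("g1", "g2")
        ]
        assert all(len(m) >= 1 for m in models)
        return geno, expr, models

    def test_self_replication(self, discovery):
        geno, expr, models = discovery
        res, omitted = replicate_models(models, geno, expr, None)
        assert omitted == []
        for model in models:
            for _, _, p in res[model.gene_id]:
                assert p < 1e-5

    def test_permuted_expression_gives_null_pvalues(self, discovery, rng):
        geno, expr, models = discovery
        perm = rng.permutation(len(expr.sample_ids))
        expr_perm = ExpressionMatrix(expr.gene_ids, expr.sample_ids, expr.values[:, perm])
        res, _ = replicate_models(models, geno, expr_perm, None)
        ps = [p for steps in res.values() for _, _, p in steps]
        assert min(ps) > 1e-4  # no signal survives permutation at these sizes

    def test_missing_marker_omits_whole_gene(self, discovery):
        geno, expr, models = discovery
        from condcoloc import GenotypeMatrix

        drop = geno.variant_ids.index(models[0].steps[0].esnp_id)
        keep = [i for i in range(len(geno.variant_ids)) if i != drop]
        geno2 = GenotypeMatrix(
            geno.sample_ids, [geno.variant_ids[i] for i in keep],
            geno.chrom[keep], geno.pos[keep], geno.dosages[:, keep],
        )
        res, omitted = replicate_models(models, geno2, expr, None)
        assert models[0].gene_id in omitted
        assert models[0].gene_id not in res
        assert models[1].gene_id in res


class TestPi1:
    def test_uniform_null_near_zero(self, rng):
        p = rng.uniform(size=10_000)
        assert abs(estimate_pi1(p)) <= 0.03

    def test_mixture_recovers_thirty_percent(self, rng):
        m = 10_000
        alt = rng.beta(0.1, 8.0, size=int(0.3 * m))  # dense near zero
        null = rng.uniform(size=m - alt.size)
        p = np.concatenate([alt, null])
        assert estimate_pi1(p) == pytest.approx(0.30, abs=0.05)

    def test_saturated_alternative(self):
        assert estimate_pi1([1e-10] * 100) == 1.0

    def test_invariant_to_input_order(self, rng):
        p = rng.uniform(size=500) ** 2
        assert estimate_pi1(p) == pytest.approx(estimate_pi1(p[::-1]))
        assert estimate_pi1(p) == pytest.approx(estimate_pi1(rng.permutation(p)))

    def test_too_few_pvalues(self):
        with pytest.raises(ValueError):
            estimate_pi1([0.5] * 10)
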