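import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichescape.evo_inference import (
    FitError,
    aicc,
    compare_models,
    fit_evomodel,
    fit_lambda,
    holm_adjust,
    lambda_lrt,
    profiled_loglik,
    select_model,
    summarise_across_trees,
)
from nichescape.phylo_core import correlation_structure, model_covariance
from nichescape.synthetic_data import simulate_continuous_trait, simulate_tree


@pytest.fixture(scope="module")
def medium_tree():
    return simulate_tree(80, seed=21)


class TestProfiledLoglik:
    def test_matches_mvn_density_oracle(self, medium_tree):
        # at the profiled optimum, the plain MVN density must agree
        x = simulate_continuous_trait(
            medium_tree, "BM", {"sigma2": 2.0, "z0": 1.0}, seed=1
        ).to_numpy()
        V = medium_tree.shared_path_matrix()
        logL, z0, s2 = profiled_loglik(x, V)
        direct = stats.multivariate_normal.logpdf(
            x, mean=np.full(len(x), z0), cov=s2 * V, allow_singular=False
        )
        assert logL == pytest.approx(direct, abs=1e-8)

    def test_profiling_never_beaten_by_other_parameters(self, medium_tree):
        x = simulate_continuous_trait(medium_tree, "BM", {"sigma2": 1.0}, seed=2)
        V = medium_tree.shared_path_matrix()
        logL, z0, s2 = profiled_loglik(x.to_numpy(), V)
        rng = np.random.default_rng(3)
        for _ in range(10):
            other = stats.multivariate_normal.logpdf(
                x.to_numpy(),
                mean=np.full(len(x), z0 + rng.normal(0, 0.5)),
                cov=s2 * np.exp(rng.normal(0, 0.3)) * V,
            )
            assert other <= logL + 1e-10


class TestFitLambda:
    def test_matches_fine_grid_oracle(self, medium_tree):
        rng_seeds = range(10)
        grid = np.linspace(0.0, 1.0, 1001)
        S = medium_tree.shared_path_matrix()
        T = medium_tree.height
        for seed in rng_seeds:
            lam_true = [0.0, 0.5, 1.0][seed % 3]
            x = simulate_continuous_trait(
                medium_tree, "LAMBDA", {"lambda": lam_true}, seed=100 + seed
            )
            est = fit_lambda(x, medium_tree)
            xs = x.loc[medium_tree.tip_labels].to_numpy()
            lls = [
                profiled_loglik(
                    xs, correlation_structure(S, T, "LAMBDA", {"lambda": g})
                )[0]
                for g in grid
            ]
            lam_grid = grid[int(np.argmax(lls))]
            assert abs(est.lambda_hat - lam_grid) <= 0.001 + 1e-9
            assert est.logL_hat >= max(lls) - 1e-6

    def test_loglik_at_hat_dominates_boundaries(self, medium_tree):
        x = simulate_continuous_trait(medium_tree, "LAMBDA",
                                      {"lambda": 0.6}, seed=5)
        est = fit_lambda(x, medium_tree)
        assert est.logL_hat >= max(est.logL_lambda0, est.logL_lambda1) - 1e-8

    def test_constant_trait_errors(self, medium_tree):
        x = pd.Series(1.0, index=medium_tree.tip_labels)
        with pytest.raises(FitError):
            fit_lambda(x, medium_tree)

    def test_bm_simulation_recovers_high_lambda(self, medium_tree):
        hats = []
        for seed in range(20):
            x = simulate_continuous_trait(medium_tree, "BM",
                                          {"sigma2": 1.0}, seed=200 + seed)
            hats.append(fit_lambda(x, medium_tree).lambda_hat)
        assert np.median(hats) >= 0.9

    def test_iid_noise_recovers_low_lambda(self, medium_tree):
        rng = np.random.default_rng(6)
        hats = []
        for _ in range(20):
            x = pd.Series(rng.standard_normal(medium_tree.n_tips),
                          index=medium_tree.tip_labels)
            hats.append(fit_lambda(x, medium_tree).lambda_hat)
        assert np.median(hats) < 0.1


class TestLambdaLrt:
    def test_lambda_at_one_gives_p_one(self, medium_tree):
        # BM-simulated data usually lands at the lambda = 1 boundary
        for seed in range(5):
            x = simulate_continuous_trait(medium_tree, "BM", {"sigma2": 1.0},
                                          seed=300 + seed)
            est = fit_lambda(x, medium_tree)
            if est.lambda_hat == 1.0:
                assert est.p_vs_1 == pytest.approx(1.0)
                break
        else:
            pytest.fail("no boundary estimate in 5 BM replicates")

    def test_holm_enumeration(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_dimension_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.02]), [0.02])

    def test_families_adjusted_separately(self, medium_tree):
        ests = []
        for seed in range(3):
            x = simulate_continuous_trait(medium_tree, "LAMBDA",
                                          {"lambda": 0.5}, seed=400 + seed)
            ests.append(fit_lambda(x, medium_tree))
        lambda_lrt(ests)
        raw0 = [e.p_vs_0 for e in ests]
        exp0 = holm_adjust(raw0)
        for e, p in zip(ests, exp0):
            assert e.p_vs_0_adj == pytest.approx(p)
            assert e.p_vs_0_adj >= e.p_vs_0 - 1e-15


class TestFitEvomodel:
    def test_degenerate_data_flagged(self, toy_tree):
        x = pd.Series(0.0, index=["A", "B", "C"])
        with pytest.raises(FitError):
            fit_evomodel(x, toy_tree, "BM")

    def test_ou_loglik_matches_density_oracle(self, medium_tree):
        x = simulate_continuous_trait(medium_tree, "OU",
                                      {"sigma2": 1.0, "alpha": 3.0}, seed=7)
        fit = fit_evomodel(x, medium_tree, "OU")
        C = model_covariance(
            medium_tree, "OU",
            {"alpha": fit.params["alpha"], "sigma2": fit.params["sigma2"]},
        ).matrix
        direct = stats.multivariate_normal.logpdf(
            x.loc[medium_tree.tip_labels],
            mean=np.full(medium_tree.n_tips, fit.params["z0"]),
            cov=C,
        )
        assert fit.logLik == pytest.approx(direct, abs=1e-8)

    def test_ou_and_eb_never_below_bm(self, medium_tree):
        # both models include BM as a boundary case
        for seed in range(5):
            x = simulate_continuous_trait(medium_tree, "BM", {"sigma2": 1.0},
                                          seed=500 + seed)
            bm = fit_evomodel(x, medium_tree, "BM").logLik
            assert fit_evomodel(x, medium_tree, "OU").logLik >= bm - 1e-5
            assert fit_evomodel(x, medium_tree, "EB").logLik >= bm - 1e-5

    def test_strong_ou_alpha_recovered_within_factor_two(self):
        tree = simulate_tree(150, seed=22)
        alpha_true = 5.0 / tree.height
        hats = []
        for seed in range(10):
            x = simulate_continuous_trait(
                tree, "OU", {"sigma2": 1.0, "alpha": alpha_true},
                seed=600 + seed,
            )
            hats.append(fit_evomodel(x, tree, "OU").params["alpha"])
        med = np.median(hats)
        assert alpha_true / 2 <= med <= alpha_true * 2

    def test_non_ultrametric_rejected_for_ou(self):
        from nichescape.phylo_core import parse_tree

        tree = parse_tree("((A:1,B:1):1,C:5);")
        x = pd.Series([0.0, 1.0, 2.0, 3.0], index=["A", "B", "C", "D"])
        with pytest.raises(FitError):
            fit_evomodel(x.loc[["A", "B", "C"]], tree, "OU")


class TestCompareModels:
    def test_aicc_formula(self):
        assert aicc(-10.0, 2, 50) == pytest.approx(24.0 + 12.0 / 47.0)

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(FitError):
            aicc(-10.0, 3, 4)

    def test_equal_aicc_gives_equal_weights(self, medium_tree):
        from nichescape.evo_inference import EvoFit

        fits = [
            EvoFit(model="BM", params={}, logLik=-10.0, k=2, n=50),
            EvoFit(model="OU", params={}, logLik=-10.0, k=2, n=50),
        ]
        compare_models(fits)
        assert fits[0].akaike_weight == pytest.approx(0.5)
        assert fits[1].akaike_weight == pytest.approx(0.5)

    def test_weights_sum_to_one_and_best_has_delta_zero(self, medium_tree):
        x = simulate_continuous_trait(medium_tree, "BM", {"sigma2": 1.0},
                                      seed=8)
        _, fits = select_model(x, medium_tree)
        assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0)
        assert min(f.delta_AICc for f in fits) == 0.0


class TestSummarise:
    def test_unanimous_selection_is_100_percent(self):
        df = pd.DataFrame(
            {
                "tree_id": [0, 1, 2],
                "dimension": ["Dim1"] * 3,
                "lambda_hat": [0.9, 1.0, 0.95],
                "selected_model": ["BM", "BM", "BM"],
            }
        )
        out = summarise_across_trees(df)
        assert out.loc["Dim1", "pct_BM"] == 100.0
        assert out.loc["Dim1", "median_lambda"] == pytest.approx(0.95)

    def test_bm_majority_across_simulated_trees(self):
        from nichescape.synthetic_data import simulate_tree_set

        trees = simulate_tree_set(60, 10, seed=23)
        x = simulate_continuous_trait(trees[0], "BM", {"sigma2": 1.0}, seed=9)
        selected = [select_model(x, t)[0] for t in trees]
        assert sum(m == "BM" for m in selected) > len(trees) / 2
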