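import numpy as np
import pandas as pd
import pytest

from cophylochem.association_models import (TERM_NAMES, KronTerm,
                                            TermCovariances, VarpartSpec,
                                            aicc, build_term_covariances,
                                            compare_model_variants,
                                            fit_occurrence_model,
                                            nearest_psd_correlation,
                                            occurrence_frame,
                                            run_variance_partition,
                                            run_variance_partition_batch)
from cophylochem.synthetic_data import (sim_bd_tree, sim_incidence,
                                        star_species_tree)


def irls_binomial(X, y, n, n_iter=200, tol=1e-12):
    """Independent iteratively-reweighted least-squares logistic oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = n * mu * (1 - mu)
        z = eta + (y - n * mu) / w
        new = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


class TestOccurrenceModel:
    def _frame(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        return pd.DataFrame({
            "y": [3, 5, 1, 0, 7, 2], "n": [20] * 6, "x": x,
        })

    def test_intercept_only_closed_form(self):
        df = self._frame()
        res = fit_occurrence_model(df, [])
        p_hat = df["y"].sum() / df["n"].sum()
        assert res.beta[0] == pytest.approx(np.log(p_hat / (1 - p_hat)),
                                            abs=1e-6)
        assert res.odds[0] == pytest.approx(p_hat / (1 - p_hat), rel=1e-5)

    def test_matches_irls_oracle(self):
        df = self._frame()
        res = fit_occurrence_model(df, ["x"])
        X = np.column_stack([np.ones(6), df["x"]])
        oracle = irls_binomial(X, df["y"].to_numpy(float),
                               df["n"].to_numpy(float))
        np.testing.assert_allclose(res.beta, oracle, atol=1e-6)

    def test_zero_slope_gives_unit_odds(self):
        df = self._frame()
        df["flat"] = 1.0  # collinear with intercept -> dropped effect size
        res = fit_occurrence_model(df, [])
        assert res.odds.shape == (1,)

    def test_deviance_never_increases_with_added_predictor(self):
        rng = np.random.default_rng(1)
        df = self._frame()
        df["x2"] = rng.normal(size=6)
        l0 = fit_occurrence_model(df, []).loglik
        l1 = fit_occurrence_model(df, ["x"]).loglik
        l2 = fit_occurrence_model(df, ["x", "x2"]).loglik
        assert l1 >= l0 - 1e-9 and l2 >= l1 - 1e-9

    def test_separation_triggers_firth_refit(self):
        df = pd.DataFrame({
            "y": [0, 0, 0, 10, 10, 10], "n": [10] * 6,
            "x": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0],
        })
        with pytest.warns(UserWarning, match="separation"):
            res = fit_occurrence_model(df, ["x"])
        assert res.separation
        assert np.isfinite(res.beta).all() and np.isfinite(res.se).all()

    def test_occurrence_frame_counts_richness(self, block_chem_similarity):
        saw = sim_bd_tree(20, seed=1)
        host = sim_bd_tree(20, seed=2)
        sim = sim_incidence(saw, host, block_chem_similarity,
                            {"host_main": 1.0}, seed=3)
        df = occurrence_frame(sim.table)
        mat = sim.table.binary_matrix()
        assert (df["y"] == mat.sum(axis=1)).all()
        assert (df["n"] == len(sim.table.motus)).all()
        assert "effort" in df.columns


class TestAICc:
    def test_worked_example(self):
        # -2(-5) + 2(1) + 2*1*2/(10-2) = 12.5
        assert aicc(-5.0, 1, 10) == pytest.approx(12.5)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-5.0) + 2 * 3
        assert aicc(-5.0, 3, 10 ** 7) == pytest.approx(aic, abs=1e-5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 9, 10)

    def test_ranking_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "y": rng.integers(0, 10, 12), "n": [15] * 12,
            "a": rng.normal(size=12), "b": rng.normal(size=12),
        })
        candidates = [[], ["a"], ["b"], ["a", "b"]]
        results = [fit_occurrence_model(df, c) for c in candidates]
        ranks = np.argsort([r.aicc for r in results])
        brute = np.argsort([aicc(r.loglik, r.k, r.n) for r in results])
        np.testing.assert_array_equal(ranks, brute)


class TestTermCovariances:
    def _cov(self, block_chem):
        saw = sim_bd_tree(20, seed=1)
        host = sim_bd_tree(20, seed=2)
        return build_term_covariances(saw, host, block_chem, ["R1", "R2"])

    def test_twelve_named_terms(self, block_chem_similarity):
        cov = self._cov(block_chem_similarity)
        assert set(cov.terms) == set(TERM_NAMES)

    def test_star_trees_and_identity_chemistry_collapse(self):
        saw = star_species_tree(4, 1.0)
        host = star_species_tree(4, 1.0)
        chem = pd.DataFrame(np.eye(4), index=host.tip_labels,
                            columns=host.tip_labels)
        cov = build_term_covariances(saw, host, chem, ["R1"])
        # every structured factor degenerates to the identity
        for name in ("coevolution", "defense_tracking", "interaction"):
            np.testing.assert_allclose(cov.terms[name].full(), np.eye(16),
                                       atol=1e-12)
        np.testing.assert_allclose(cov.terms["sawfly_main"].full(),
                                   np.kron(np.eye(4), np.ones((4, 4))))

    def test_kronecker_entries_are_products(self, block_chem_similarity):
        cov = self._cov(block_chem_similarity)
        term = cov.terms["coevolution"]
        full = term.full()
        n_h = cov.n_h
        rng = np.random.default_rng(3)
        for _ in range(10):
            s1, s2 = rng.integers(cov.n_s, size=2)
            h1, h2 = rng.integers(n_h, size=2)
            assert full[s1 * n_h + h1, s2 * n_h + h2] == pytest.approx(
                term.factor_s[s1, s2] * term.factor_h[h1, h2])

    def test_all_factors_psd(self, block_chem_similarity):
        cov = self._cov(block_chem_similarity)
        for term in cov.terms.values():
            assert np.linalg.eigvalsh(term.factor_s).min() >= -1e-8
            assert np.linalg.eigvalsh(term.factor_h).min() >= -1e-8

    def test_nearest_psd_projection_repairs_indefinite_similarity(self):
        S = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        # this matrix is indefinite; projection must fix it
        assert np.linalg.eigvalsh(S).min() < 0
        R = nearest_psd_correlation(S)
        assert np.linalg.eigvalsh(R).min() >= -1e-10
        np.testing.assert_allclose(np.diag(R), 1.0)


def _iid_cov(n_s, n_h, regions=("R1", "R2")):
    return TermCovariances(
        [f"s{i}" for i in range(n_s)], [f"h{j}" for j in range(n_h)],
        list(regions),
        {"interaction": KronTerm("interaction", np.eye(n_s), np.eye(n_h))})


class TestVariancePartition:
    def _toy_y(self, seed, n=10, sigma2=2.0):
        rng = np.random.default_rng(seed)
        u = np.sqrt(sigma2) * rng.standard_normal((n, n))
        eta = -0.3 + u[None] + rng.standard_normal((2, n, n))
        return (eta > 0).astype(int)

    def test_proportions_sum_to_one_per_draw(self, block_chem_similarity):
        saw = sim_bd_tree(20, seed=1)
        host = sim_bd_tree(20, seed=2)
        sim = sim_incidence(saw, host, block_chem_similarity,
                            {"defense_tracking": 1.0}, seed=5)
        spec = VarpartSpec(n_iter=600, burn_in=100, thin=5)
        res = run_variance_partition(sim.y, sim.cov, spec, seed=0)
        sig2 = np.stack([res.sigma2_samples[t] for t in res.terms])
        props = sig2 / sig2.sum(axis=0)
        np.testing.assert_allclose(props.sum(axis=0), 1.0, atol=1e-12)

    def test_identical_seed_identical_results(self):
        y = self._toy_y(0)
        cov = _iid_cov(10, 10)
        spec = VarpartSpec(terms=["interaction"], include_region=False,
                           control_effort=False, n_iter=500, burn_in=100,
                           thin=2)
        a = run_variance_partition(y, cov, spec, seed=7)
        b = run_variance_partition(y, cov, spec, seed=7)
        np.testing.assert_array_equal(a.sigma2_samples["interaction"],
                                      b.sigma2_samples["interaction"])

    def test_posterior_matches_long_reference_chain(self):
        # short chain vs a 10x reference on a well-identified fixture
        y = self._toy_y(1)
        cov = _iid_cov(10, 10)
        short = VarpartSpec(terms=["interaction"], include_region=False,
                            control_effort=False, n_iter=3000, burn_in=500,
                            thin=2)
        long = VarpartSpec(terms=["interaction"], include_region=False,
                           control_effort=False, n_iter=30000, burn_in=5000,
                           thin=20)
        m_short = run_variance_partition(y, cov, short, seed=1) \
            .sigma2_samples["interaction"].mean()
        ref = run_variance_partition(y, cov, long, seed=2) \
            .sigma2_samples["interaction"]
        mc_err = 3 * ref.std() / np.sqrt(50)  # generous autocorrelation allowance
        assert abs(m_short - ref.mean()) < mc_err + 0.3

    def test_constant_response_rejected(self):
        cov = _iid_cov(4, 4)
        spec = VarpartSpec(terms=["interaction"], include_region=False,
                           n_iter=100, burn_in=10)
        with pytest.raises(ValueError, match="constant"):
            run_variance_partition(np.zeros((2, 4, 4), dtype=int), cov, spec)

    def test_prior_scale_smoke(self):
        # doubling the prior scale must not reshape a well-identified posterior
        y = self._toy_y(3, sigma2=1.5)
        cov = _iid_cov(10, 10)
        means = []
        for scale in (1.0, 2.0):
            spec = VarpartSpec(terms=["interaction"], include_region=False,
                               control_effort=False, n_iter=4000, burn_in=500,
                               thin=3, prior_scale=scale)
            res = run_variance_partition(y, cov, spec, seed=4)
            means.append(res.sigma2_samples["interaction"].mean())
        assert abs(means[0] - means[1]) < 0.5

    def test_batched_chains_match_problem_count(self):
        ys = np.stack([self._toy_y(s) for s in range(3)])
        cov = _iid_cov(10, 10)
        spec = VarpartSpec(terms=["interaction"], include_region=False,
                           control_effort=False, n_iter=400, burn_in=100,
                           thin=3)
        res = run_variance_partition_batch(ys, cov, spec, seed=5)
        assert len(res) == 3
        assert all(r.sigma2_samples["interaction"].size > 0 for r in res)


class TestModelVariants:
    def test_grid_shapes_and_term_lists(self, block_chem_similarity):
        saw = sim_bd_tree(20, seed=1)
        host = sim_bd_tree(20, seed=2)
        sim = sim_incidence(saw, host, block_chem_similarity,
                            {"host_defense_interaction": 1.0}, seed=6)
        spec = VarpartSpec(n_iter=400, burn_in=100, thin=3)
        grid = compare_model_variants(sim.table, sim.cov, base_spec=spec,
                                      seed=0)
        assert set(grid) == {(True, True), (True, False),
                             (False, True), (False, False)}
        with_region = grid[(True, True)]
        without = grid[(False, True)]
        assert "region" in with_region.terms
        assert "interaction" in with_region.terms
        assert "region" not in without.terms
        assert "interaction" not in without.terms

    def test_same_seed_reproducible(self, block_chem_similarity):
        saw = sim_bd_tree(20, seed=1)
        host = sim_bd_tree(20, seed=2)
        sim = sim_incidence(saw, host, block_chem_similarity,
                            {"coevolution": 1.0}, seed=7)
        spec = VarpartSpec(n_iter=300, burn_in=50, thin=2)
        a = compare_model_variants(sim.table, sim.cov, base_spec=spec, seed=1)
        b = compare_model_variants(sim.table, sim.cov, base_spec=spec, seed=1)
        for key in a:
            assert a[key].proportion_mean == b[key].proportion_mean
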