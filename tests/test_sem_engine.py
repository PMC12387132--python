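import numpy as np
import pytest

from readsem import consensus, sem_engine, synth


def chain_spec():
    return sem_engine.SemModelSpec(
        observed=("x", "y"), loadings=(), paths=(("x", "y"),)
    )


class TestModelSpec:
    def test_default_topology_counts(self):
        full = sem_engine.default_model_spec(gv_paths=True)
        restricted = sem_engine.default_model_spec(gv_paths=False)
        assert len(full.paths) - len(restricted.paths) == 5
        assert restricted.df - full.df == 5
        assert full.df == 13 * 14 // 2 - full.n_free

    def test_cyclic_spec_rejected(self):
        with pytest.raises(sem_engine.SemError, match="cycle"):
            sem_engine.SemModelSpec(
                observed=("x", "y"), loadings=(), paths=(("x", "y"), ("y", "x"))
            )

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        spec = sem_engine.default_model_spec(gv_paths=False)
        path = tmp_path / "model.yaml"
        path.write_text(yaml.safe_dump(spec.to_dict()))
        assert sem_engine.SemModelSpec.from_file(path) == spec


class TestImpliedMatrix:
    def test_empty_model_is_identity(self):
        spec = sem_engine.SemModelSpec(observed=("x", "y"), loadings=(), paths=())
        sigma = sem_engine.implied_matrix(spec, np.array([1.0, 1.0]))
        assert np.allclose(sigma, np.eye(2))

    def test_single_path_chain(self):
        # x -> y with path 0.5, unit total variances
        sigma = sem_engine.implied_matrix(chain_spec(), np.array([0.5, 1.0, 0.75]))
        assert sigma[0, 0] == pytest.approx(1.0)
        assert sigma[1, 1] == pytest.approx(1.0)
        assert sigma[0, 1] == pytest.approx(0.5)

    def test_reference_solution_implies_loading_product(self, reference_solution):
        # corr(Gc, Gf) must equal lambda_Gc * lambda_Gf = 0.70 * 0.64
        lam, B, labels = reference_solution
        sigma = synth.population_sigma(
            consensus.reference_lambda(), consensus.reference_b_matrix()
        )
        i, j = labels.index("Gc"), labels.index("Gf")
        assert sigma[i, j] == pytest.approx(0.70 * 0.64, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(sem_engine.SemError):
            sem_engine.implied_matrix(chain_spec(), np.array([0.5]))


class TestFitMl:
    def test_just_identified_two_variable_model(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = sem_engine.fit_ml(S, chain_spec(), N=100)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.estimates["beta[x->y]"] == pytest.approx(0.5, abs=1e-6)
        assert fit.rmsea is None and fit.tli is None

    def test_noiseless_population_matrix_recovers_parameters(self, reference_solution):
        lam_map, B, labels = reference_solution
        sigma = synth.population_sigma(
            consensus.reference_lambda(), consensus.reference_b_matrix()
        )
        spec = sem_engine.default_model_spec(gv_paths=False)
        fit = sem_engine.fit_ml(sigma, spec, N=1764, seed=0, compute_se=False)
        assert fit.fmin < 1e-10 and fit.chi2 < 1e-6
        idx = {c: i for i, c in enumerate(labels)}
        for b, lam in fit.loadings.items():
            assert lam == pytest.approx(lam_map[b], abs=1e-4)
        for (src, dst), est in fit.path_coefficients.items():
            assert est == pytest.approx(B[idx[dst], idx[src]], abs=1e-4)

    def test_chi2_scales_with_n_but_estimates_do_not(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 2))
        S = np.corrcoef(X, rowvar=False)
        spec = sem_engine.SemModelSpec(
            observed=("x", "y"), loadings=(), paths=()
        )  # independence structure fitted to correlated data: fmin > 0
        fit_a = sem_engine.fit_ml(S, spec, N=101, compute_se=False)
        fit_b = sem_engine.fit_ml(S, spec, N=1001, compute_se=False)
        assert fit_b.chi2 == pytest.approx(10 * fit_a.chi2, rel=1e-6)
        for name in fit_a.estimates:
            assert fit_a.estimates[name] == pytest.approx(
                fit_b.estimates[name], abs=1e-7
            )

    def test_random_starts_agree(self, reference_solution):
        # two seeds -> same converged solution to 1e-6
        rng = np.random.default_rng(9)
        sigma = synth.population_sigma(
            consensus.reference_lambda(), consensus.reference_b_matrix()
        )
        noise = rng.normal(0, 0.01, sigma.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        S = sigma + noise
        if np.linalg.eigvalsh(S).min() < 1e-6:
            S = sigma  # keep the input safely PD
        spec = sem_engine.default_model_spec(gv_paths=False)
        fit1 = sem_engine.fit_ml(S, spec, N=500, seed=1, compute_se=False)
        fit2 = sem_engine.fit_ml(S, spec, N=500, seed=2, compute_se=False)
        for name in fit1.estimates:
            assert fit1.estimates[name] == pytest.approx(
                fit2.estimates[name], abs=1e-6
            )

    def test_self_consistency_over_random_admissible_draws(self):
        # fitting the model to its own implied matrix returns the parameters
        rng = np.random.default_rng(123)
        spec = sem_engine.default_model_spec(gv_paths=False)
        n_ok = 0
        while n_ok < 50:
            lam = rng.uniform(0.35, 0.7, size=8)
            B = np.zeros((13, 13))
            idx = {c: i for i, c in enumerate(consensus.CONSTRUCTS)}
            for src, dst in spec.paths:
                B[idx[dst], idx[src]] = rng.uniform(-0.1, 0.35)
            try:
                sigma = synth.population_sigma(lam, B)
            except synth.SynthError:
                continue
            if np.linalg.eigvalsh(sigma).min() < 1e-4:
                continue
            n_ok += 1
            fit = sem_engine.fit_ml(sigma, spec, N=500, compute_se=False)
            assert fit.fmin < 1e-9
            # near-singular draws pass through; allow a looser bound there
            tol = 1e-3
            for b, l in zip(consensus.BROAD_ABILITIES, lam):
                assert fit.loadings[b] == pytest.approx(l, abs=tol)
            for (src, dst), est in fit.path_coefficients.items():
                assert est == pytest.approx(B[idx[dst], idx[src]], abs=tol)

    def test_non_psd_input_rejected(self):
        S = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        spec = sem_engine.SemModelSpec(
            observed=("a", "b", "c"), loadings=(), paths=()
        )
        with pytest.raises(sem_engine.SemError, match="positive semidefinite"):
            sem_engine.fit_ml(S, spec, N=100)


class TestFitIndices:
    def test_arithmetic_from_definitions(self):
        cfi, tli, rmsea, _ = sem_engine.fit_indices(50, 20, 500, 30, 100)
        assert cfi == pytest.approx(1 - 30 / 470)
        assert rmsea == pytest.approx(np.sqrt(30 / (20 * 99)))

    def test_zero_noncentrality_gives_zero_rmsea(self):
        cfi, tli, rmsea, _ = sem_engine.fit_indices(20, 20, 500, 30, 100)
        assert rmsea == 0.0
        assert cfi == 1.0 - 0.0 / 470

    def test_perfect_fit_srmr_zero(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        *_, srmr = sem_engine.fit_indices(0, 0, 10, 1, 100, S_obs=S, sigma_hat=S)
        assert srmr == 0.0


class TestCompareNested:
    def test_identical_fits_give_zero_delta(self, reference_solution):
        sigma = synth.population_sigma(
            consensus.reference_lambda(), consensus.reference_b_matrix()
        )
        spec = sem_engine.default_model_spec(gv_paths=False)
        fit = sem_engine.fit_ml(sigma, spec, N=500, compute_se=False)
        d_chi2, d_df, _ = sem_engine.compare_nested(fit, fit)
        assert d_chi2 == 0.0 and d_df == 0

    def test_gv_removed_variant_has_five_more_df(self):
        sigma = synth.population_sigma(
            consensus.reference_lambda(), consensus.reference_b_matrix()
        )
        full = sem_engine.fit_ml(
            sigma, sem_engine.default_model_spec(gv_paths=True), N=1764,
            compute_se=False,
        )
        restricted = sem_engine.fit_ml(
            sigma, sem_engine.default_model_spec(gv_paths=False), N=1764,
            compute_se=False,
        )
        d_chi2, d_df, p = sem_engine.compare_nested(full, restricted)
        assert d_df == 5
        # data generated with Gv paths = 0: removing them costs ~nothing
        assert d_chi2 == pytest.approx(0.0, abs=1e-4)

    def test_non_nested_rejected(self):
        sigma = np.eye(2)
        a = sem_engine.fit_ml(sigma, chain_spec(), N=100, compute_se=False)
        other = sem_engine.SemModelSpec(observed=("x", "y"), loadings=(), paths=(("y", "x"),))
        b = sem_engine.fit_ml(sigma, other, N=100, compute_se=False)
        with pytest.raises(sem_engine.SemError, match="not nested"):
            sem_engine.compare_nested(a, b)
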