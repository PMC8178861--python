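import numpy as np
import pandas as pd
import pytest

from picdesc.efa import (
    oblimin_rotate,
    parallel_analysis,
    principal_axis_factor,
    run_efa,
    tucker_congruence,
)
from picdesc.simulate import FactorModelSpec, simulate_factor_model


def two_factor_spec(p=12, loading=0.8, phi12=0.3, n=500):
    lam = np.zeros((p, 2))
    lam[: p // 2, 0] = loading
    lam[p // 2:, 1] = loading
    phi = np.array([[1.0, phi12], [phi12, 1.0]])
    return FactorModelSpec(loadings=lam, phi=phi, n=n)


def align_to_truth(pattern, true_loadings):
    """Permute/sign-flip recovered factors to best match the true ones."""
    k = pattern.shape[1]
    from itertools import permutations
    best, best_score = None, -np.inf
    for perm in permutations(range(k)):
        for signs in np.ndindex(*(2,) * k):
            cand = pattern[:, list(perm)] * np.where(np.array(signs), -1, 1)
            score = sum(
                tucker_congruence(cand[:, j], true_loadings[:, j]) for j in range(k)
            )
            if score > best_score:
                best, best_score = cand, score
    return best


class TestParallelAnalysis:
    def test_perfectly_correlated_pair_retains_a_factor(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        data = np.column_stack([x, x + 1e-9 * rng.standard_normal(200)])
        k, observed, _ = parallel_analysis(data, seed=1)
        assert k >= 1
        assert observed[0] == pytest.approx(2.0, abs=1e-3)

    def test_null_data_mostly_retains_zero(self):
        rng = np.random.default_rng(5)
        hits = sum(
            parallel_analysis(rng.standard_normal((300, 10)), seed=i)[0] == 0
            for i in range(20)
        )
        assert hits >= 18

    def test_two_factor_recovery(self):
        data = simulate_factor_model(two_factor_spec(), seed=4)
        k, _, _ = parallel_analysis(data, seed=4)
        assert k == 2

    def test_thresholds_decrease_with_position(self):
        rng = np.random.default_rng(6)
        _, _, thresholds = parallel_analysis(rng.standard_normal((100, 8)), seed=2)
        assert np.all(np.diff(thresholds) < 0)

    def test_constant_column_is_error(self):
        data = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="constant"):
            parallel_analysis(data, seed=0)

    def test_stable_under_more_iterations(self):
        data = simulate_factor_model(two_factor_spec(), seed=9)
        k100 = parallel_analysis(data, n_iter=100, seed=3)[0]
        k1000 = parallel_analysis(data, n_iter=1000, seed=3)[0]
        assert k100 == k1000


class TestPrincipalAxis:
    def test_identity_correlation_gives_null_loadings(self):
        loadings, h2, _ = principal_axis_factor(np.eye(6), k=1)
        assert np.max(np.abs(loadings)) < 0.05
        assert np.max(h2) < 0.05

    def test_uniform_one_factor_structure_recovered(self):
        p, lam = 6, 0.7
        r = np.full((p, p), lam * lam)
        np.fill_diagonal(r, 1.0)
        loadings, h2, converged = principal_axis_factor(r, k=1)
        assert converged
        assert np.allclose(loadings[:, 0], lam, atol=0.01)
        assert np.allclose(h2, lam * lam, atol=0.02)

    def test_singular_correlation_p_gt_n_runs(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((30, 31)) + rng.standard_normal((30, 1))
        r = np.corrcoef(x, rowvar=False)
        loadings, h2, _ = principal_axis_factor(r, k=2)
        assert np.all(np.isfinite(loadings))
        assert np.all((h2 >= 0) & (h2 <= 0.995))


class TestOblimin:
    def test_k1_is_identity(self):
        a = np.array([[0.8], [0.7], [0.6]])
        pattern, structure, phi, _ = oblimin_rotate(a)
        assert np.allclose(pattern, a)
        assert np.allclose(structure, a)
        assert phi.shape == (1, 1) and phi[0, 0] == 1.0

    def test_ideal_orthogonal_pattern_recovered(self):
        ideal = np.zeros((8, 2))
        ideal[:4, 0] = 0.8
        ideal[4:, 1] = 0.8
        # rotate away from simple structure, then recover it
        theta = 0.6
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pattern, _, phi, conv = oblimin_rotate(ideal @ rot, seed=0)
        assert conv
        aligned = align_to_truth(pattern, ideal)
        assert np.allclose(aligned, ideal, atol=0.02)
        assert np.allclose(phi, np.eye(2), atol=0.05)

    def test_rotation_preserves_the_fitted_common_covariance(self):
        data = simulate_factor_model(two_factor_spec(), seed=15)
        r = np.corrcoef(data, rowvar=False)
        loadings, h2, _ = principal_axis_factor(r, k=2)
        pattern, _, phi, _ = oblimin_rotate(loadings, seed=1)
        # oblique rotation must leave the implied common covariance untouched
        assert np.max(np.abs(pattern @ phi @ pattern.T - loadings @ loadings.T)) < 1e-6
        # and that fit tracks the reduced correlation matrix up to sampling error
        reduced = r.copy()
        np.fill_diagonal(reduced, h2)
        assert np.max(np.abs(pattern @ phi @ pattern.T - reduced)) < 0.1


class TestRunEfa:
    def test_two_factor_full_recovery_and_assignment(self):
        spec = two_factor_spec()
        data = simulate_factor_model(spec, seed=20)
        df = pd.DataFrame(data, columns=[f"v{i}" for i in range(12)])
        res = run_efa(df, seed=20)
        assert res.k == 2
        aligned = align_to_truth(res.pattern, spec.loadings)
        for j in range(2):
            assert tucker_congruence(aligned[:, j], spec.loadings[:, j]) >= 0.95
        truth = {f"v{i}": (0 if i < 6 else 1) for i in range(12)}
        recovered_groups = {}
        for var, factor in res.assignments.items():
            assert factor is not None
            recovered_groups.setdefault(factor, set()).add(var)
        assert sorted(map(len, recovered_groups.values())) == [6, 6]
        for group in recovered_groups.values():
            assert len({truth[v] for v in group}) == 1

    def test_sub_cutoff_variable_unassigned(self):
        lam = np.zeros((9, 2))
        lam[:4, 0] = 0.8
        lam[4:8, 1] = 0.8
        lam[8, 0] = 0.35  # weak variable: below the 0.6 cutoff
        data = simulate_factor_model(FactorModelSpec(loadings=lam, n=800), seed=31)
        df = pd.DataFrame(data, columns=[f"v{i}" for i in range(9)])
        res = run_efa(df, seed=31)
        assert res.k == 2
        assert res.assignments["v8"] is None

    def test_phi_and_communalities_within_bounds(self):
        data = simulate_factor_model(two_factor_spec(phi12=0.4), seed=40)
        res = run_efa(pd.DataFrame(data), seed=40)
        assert np.allclose(np.diag(res.phi), 1.0)
        assert np.max(np.abs(res.phi)) <= 1.0 + 1e-9
        assert np.all((res.communalities >= 0) & (res.communalities <= 1.0))
        assert res.var_prop.shape == (res.k,)

    def test_fixed_seed_is_bit_reproducible(self):
        data = simulate_factor_model(two_factor_spec(), seed=50)
        df = pd.DataFrame(data)
        a = run_efa(df, seed=123)
        b = run_efa(df, seed=123)
        assert np.array_equal(a.pattern, b.pattern)
        assert np.array_equal(a.phi, b.phi)
        assert a.assignments == b.assignments

    def test_k_zero_result_has_no_factors(self):
        rng = np.random.default_rng(60)
        df = pd.DataFrame(rng.standard_normal((300, 6)))
        res = run_efa(df, seed=60)
        if res.k == 0:  # overwhelmingly likely under the null
            assert res.pattern.shape == (6, 0)
            assert all(v is None for v in res.assignments.values())


class TestFactorModelSimulator:
    def test_zero_loadings_give_iid_columns(self):
        spec = FactorModelSpec(loadings=np.zeros((5, 1)), n=4000)
        x = simulate_factor_model(spec, seed=70)
        r = np.corrcoef(x, rowvar=False)
        assert np.max(np.abs(r - np.eye(5))) < 0.06

    def test_large_n_correlation_matches_implied(self):
        spec = two_factor_spec(p=8, n=20000)
        x = simulate_factor_model(spec, seed=71)
        lam, phi, psi = spec.resolve()
        implied = lam @ phi @ lam.T + np.diag(psi)
        assert np.max(np.abs(np.corrcoef(x, rowvar=False) - implied)) < 0.03

    def test_non_psd_spec_is_error(self):
        lam = np.full((4, 2), 0.9)
        with pytest.raises(ValueError):
            FactorModelSpec(loadings=lam, phi=np.array([[1.0, 0.9], [0.9, 1.0]])).resolve()

    def test_seed_reproducibility(self):
        spec = two_factor_spec()
        assert np.array_equal(simulate_factor_model(spec, seed=5),
                              simulate_factor_model(spec, seed=5))
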