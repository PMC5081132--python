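"""Unit and property tests for the synthetic-data generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from simclass.simdata import (
    SimConfig,
    assemble_correlation,
    base_expression_moments,
    hub_toeplitz_block,
    hub_toeplitz_rho_sequence,
    impose_correlation,
    inject_group_effect,
    make_block_partition,
    poisson_copula_correlation,
    read_dataset,
    sample_base_expressions,
    sample_effect_sizes,
    simulate_dataset,
    simulate_poisson_dataset,
    simulate_replicate_average,
    truncnorm_mean,
    write_dataset,
)


def truncnorm_mean_oracle(alpha, tau):
    """Independent oracle: numerical integration of delta * f(delta | A)."""
    norm_const = 1 - stats.norm.cdf(alpha / tau)
    val, _ = quad(
        lambda d: d * stats.norm.pdf(d / tau) / tau / norm_const, alpha, np.inf
    )
    return val


class TestBaseExpressions:
    def test_rejects_empty_feature_set(self, rng):
        with pytest.raises(ValueError):
            sample_base_expressions(0, rng)

    def test_deterministic_under_seed(self):
        a = sample_base_expressions(5, np.random.default_rng(7))
        b = sample_base_expressions(5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_moments_match_surrogate_distribution(self, rng):
        mu = sample_base_expressions(10_000, rng)
        m, sd = base_expression_moments()
        assert abs(mu.mean() - m) < 3 * sd / np.sqrt(len(mu))
        # SD of the sample SD ~ sd/sqrt(2n) for near-normal data
        assert abs(mu.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * len(mu))
        assert mu.min() >= 2.0 and mu.max() <= 14.0


class TestReplicateAverage:
    def test_marginal_variance_is_sigma_b2_plus_sigma_e2_over_r(self, rng):
        # sigma_b=2.5, sigma_e=1.5, r=3 -> v = 6.25 + 2.25/3 = 7.0
        cfg = SimConfig(n=10_000, p=4, sigma_b=2.5, sigma_e=1.5, r=3)
        mu = np.zeros(4)
        X = simulate_replicate_average(cfg, mu, rng)
        v = cfg.marginal_variance
        assert v == 7.0
        # MC SE of a sample variance of normal data: v * sqrt(2/(n-1))
        tol = 3 * v * np.sqrt(2 / (cfg.n - 1))
        assert np.all(np.abs(X.var(axis=0, ddof=1) - v) < tol)

    def test_noiseless_limit_returns_row_replicated_mu(self, rng):
        cfg = SimConfig(n=10, p=3, sigma_b=1e-8, sigma_e=1e-8, r=2)
        mu = np.array([1.0, 5.0, 9.0])
        X = simulate_replicate_average(cfg, mu, rng)
        np.testing.assert_allclose(X, np.tile(mu, (10, 1)), atol=1e-6)

    def test_replication_shrinks_variance(self):
        mu = np.zeros(2)
        cfg1 = SimConfig(n=5000, p=2, sigma_b=1.0, sigma_e=2.0, r=1)
        cfg100 = SimConfig(n=5000, p=2, sigma_b=1.0, sigma_e=2.0, r=100)
        v1 = simulate_replicate_average(cfg1, mu, np.random.default_rng(0)).var(axis=0)
        v100 = simulate_replicate_average(cfg100, mu, np.random.default_rng(0)).var(axis=0)
        assert np.all(v1 > v100)

    def test_invalid_noise_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            SimConfig(n=10, p=2, sigma_b=0.0, sigma_e=1.0)


class TestBlockPartition:
    def test_single_block_below_five_features(self, rng):
        assert make_block_partition(4, rng) == [4]
        assert make_block_partition(1, rng) == [1]

    @given(p=st.integers(5, 300), seed=st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_partition_sums_to_p_and_obeys_size_rule(self, p, seed):
        sizes = make_block_partition(p, np.random.default_rng(seed))
        H = len(sizes)
        assert 1 <= H <= p // 3
        assert sum(sizes) == p
        assert sizes[0] == p // H + p % H
        assert all(d == p // H for d in sizes[1:])

    def test_remainder_goes_to_first_block(self):
        # p=25, H=4 -> (7,6,6,6); p=25, H=5 -> (5,5,5,5,5)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            sizes = make_block_partition(25, rng)
            if len(sizes) == 4:
                assert sizes == [7, 6, 6, 6]
            if len(sizes) == 5:
                assert sizes == [5, 5, 5, 5, 5]


class TestHubToeplitz:
    def test_linear_decline_hand_values(self):
        # d=5, rho 0.7 -> 0.3 linearly over lags 2..5
        seq = hub_toeplitz_rho_sequence(5, 0.7, 0.3, 1.0)
        np.testing.assert_allclose(seq, [0.7, 0.7 - 0.4 / 3, 0.7 - 0.8 / 3, 0.3])

    def test_degenerate_two_feature_block_uses_rho_max(self):
        np.testing.assert_allclose(hub_toeplitz_rho_sequence(2, 0.7, 0.3, 3.0), [0.7])

    def test_single_feature_block_is_identity(self):
        np.testing.assert_array_equal(hub_toeplitz_block(1, 0.7, 0.3), [[1.0]])

    def test_block_is_symmetric_toeplitz_with_unit_diagonal(self):
        B = hub_toeplitz_block(6, 0.8, 0.2, 2.0)
        np.testing.assert_array_equal(B, B.T)
        np.testing.assert_array_equal(np.diag(B), np.ones(6))
        assert B[0, 1] == 0.8 and pytest.approx(B[0, 5]) == 0.2

    def test_invalid_rho_order_rejected(self):
        with pytest.raises(ValueError):
            hub_toeplitz_rho_sequence(5, 0.3, 0.7)


class TestAssembleCorrelation:
    def test_independent_gives_identity(self, rng):
        cfg = SimConfig(n=10, p=3, corr_kind="independent")
        np.testing.assert_array_equal(assemble_correlation(cfg, rng).R, np.eye(3))

    def test_exchangeable_min_eigenvalue_closed_form(self, rng):
        cfg = SimConfig(
            n=10, p=4, corr_kind="exchangeable_single_block", rho_fixed=0.6
        )
        R = assemble_correlation(cfg, rng).R
        w = np.linalg.eigvalsh(R)
        assert pytest.approx(w.min(), abs=1e-12) == 0.4
        assert pytest.approx(w.max(), abs=1e-12) == 1 + 3 * 0.6

    def test_exchangeable_requires_rho_and_pd_bound(self, rng):
        with pytest.raises(ValueError):
            assemble_correlation(
                SimConfig(n=10, p=4, corr_kind="exchangeable_single_block"), rng
            )
        with pytest.raises(ValueError):
            assemble_correlation(
                SimConfig(
                    n=10, p=4, corr_kind="exchangeable_single_block", rho_fixed=-0.5
                ),
                rng,
            )

    def test_hub_blocks_are_block_diagonal_and_pd(self, rng):
        cfg = SimConfig(n=10, p=25, corr_kind="hub_toeplitz_blocks")
        model = assemble_correlation(cfg, rng)
        R = model.R
        np.testing.assert_array_equal(R, R.T)
        np.testing.assert_array_equal(np.diag(R), np.ones(25))
        assert np.linalg.eigvalsh(R).min() > 1e-10
        # off-block entries exactly zero; first block's first row matches
        start = 0
        for d, seq in zip(model.block_sizes, model.rho_sequences):
            np.testing.assert_allclose(R[start, start + 1 : start + d], seq)
            assert np.all(R[start : start + d, start + d :] == 0)
            start += d

    def test_rho_draws_fall_in_configured_ranges(self, rng):
        cfg = SimConfig(n=10, p=30, corr_kind="hub_toeplitz_blocks")
        model = assemble_correlation(cfg, rng)
        hub = model.rho_sequences[0][0]
        assert 0.6 <= hub <= 0.8
        if model.block_sizes[0] >= 3:
            tail = model.rho_sequences[0][-1]
            assert 0.2 <= tail <= 0.4


class TestImposeCorrelation:
    def test_identity_correlation_is_identity_transform(self, rng):
        X = rng.normal(size=(50, 4))
        out = impose_correlation(X, np.zeros(4), 1.0, np.eye(4))
        np.testing.assert_array_equal(out, X)

    def test_recovers_target_correlation_and_variance(self):
        rng = np.random.default_rng(2024)
        n, v, rho = 100_000, 7.0, 0.7
        mu = np.array([3.0, -2.0])
        X = rng.normal(mu, np.sqrt(v), size=(n, 2))
        R = np.array([[1.0, rho], [rho, 1.0]])
        Y = impose_correlation(X, mu, v, R)
        emp_rho = np.corrcoef(Y.T)[0, 1]
        # MC SE of a correlation estimate ~ (1-rho^2)/sqrt(n)
        assert abs(emp_rho - rho) < 3 * (1 - rho**2) / np.sqrt(n)
        tol_v = 3 * v * np.sqrt(2 / (n - 1))
        assert np.all(np.abs(Y.var(axis=0, ddof=1) - v) < tol_v)
        tol_m = 3 * np.sqrt(v / n)
        assert np.all(np.abs(Y.mean(axis=0) - mu) < tol_m)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "theta_min,tau", [(2.0, 1.0), (1.0, 1.0), (1.5, 0.5), (4.0, 2.0)]
    )
    def test_sampler_mean_matches_integration_oracle(self, theta_min, tau):
        rng = np.random.default_rng(99)
        n = 100_000
        eff = sample_effect_sizes(n, theta_min, tau, rng)
        alpha = np.log2(theta_min)
        expected = truncnorm_mean_oracle(alpha, tau)
        assert np.all(eff.delta >= alpha)
        sd = eff.delta.std(ddof=1)
        assert abs(eff.delta.mean() - expected) < 3 * sd / np.sqrt(n)

    def test_truncnorm_mean_closed_forms(self):
        # alpha=0: half-normal mean sqrt(2/pi)
        assert pytest.approx(truncnorm_mean(0.0, 1.0), rel=1e-12) == np.sqrt(2 / np.pi)
        assert pytest.approx(truncnorm_mean(1.0, 1.0), abs=1e-4) == 1.5251
        # scale equivariance
        assert pytest.approx(truncnorm_mean(1.0, 2.0), rel=1e-12) == 2 * truncnorm_mean(0.5, 1.0)
        assert pytest.approx(truncnorm_mean(1.0, 1.0), rel=1e-9) == truncnorm_mean_oracle(1.0, 1.0)

    def test_delta_sorted_descending_and_signs(self, rng):
        eff = sample_effect_sizes(5, 2.0, 1.0, rng)
        assert np.all(np.diff(eff.delta) <= 0)
        assert set(np.unique(eff.z)).issubset({-1, 1})

    def test_rejects_theta_min_below_one(self, rng):
        with pytest.raises(ValueError):
            sample_effect_sizes(5, 0.5, 1.0, rng)


class TestInjectEffect:
    def test_direct_arithmetic(self):
        from simclass.simdata import EffectModel

        eff = EffectModel(0.0, 1.0, np.array([1.0, 1.0]), np.array([1, -1]))
        ds = inject_group_effect(np.zeros((4, 2)), eff, 2)
        np.testing.assert_array_equal(ds.X[:2], 0.0)
        np.testing.assert_array_equal(ds.X[2:], [[1.0, -1.0], [1.0, -1.0]])
        assert list(ds.y) == ["G1", "G1", "G2", "G2"]

    def test_odd_n_split_like_bipolar_study(self):
        # n=61 -> groups of 30 and 31 (n1 = floor(n/2))
        ds = simulate_dataset(SimConfig(n=61, p=3, seed=0, corr_kind="independent"))
        assert (ds.n1, ds.n2) == (30, 31)

    def test_group_mean_difference_recovers_z_delta(self, rng):
        from simclass.simdata import EffectModel

        eff = EffectModel(0.0, 1.0, np.array([2.0, 1.0]), np.array([-1, 1]))
        base = rng.normal(size=(10_000, 2))
        ds = inject_group_effect(base, eff, 5000)
        diff = ds.X[5000:].mean(axis=0) - ds.X[:5000].mean(axis=0)
        tol = 3 * np.sqrt(2 / 5000)
        np.testing.assert_allclose(diff, eff.z * eff.delta, atol=tol)

    def test_length_mismatch_rejected(self):
        from simclass.simdata import EffectModel

        eff = EffectModel(0.0, 1.0, np.ones(3), np.ones(3, dtype=int))
        with pytest.raises(ValueError):
            inject_group_effect(np.zeros((4, 2)), eff, 2)


class TestSimulateDataset:
    def test_shapes_labels_and_determinism(self):
        cfg = SimConfig(n=100, p=25, sigma_b=2.5, sigma_e=1.5, theta_min=2.0, r=3, seed=5)
        ds1 = simulate_dataset(cfg)
        ds2 = simulate_dataset(cfg)
        assert ds1.X.shape == (100, 25)
        assert (ds1.n1, ds1.n2) == (50, 50)
        np.testing.assert_array_equal(ds1.X, ds2.X)
        np.testing.assert_array_equal(ds1.effects.delta, ds2.effects.delta)
        assert ds1.correlation.block_sizes == ds2.correlation.block_sizes

    def test_noiseless_limit_group_difference_exact(self):
        cfg = SimConfig(
            n=8, p=5, sigma_b=1e-8, sigma_e=1e-8, r=1, theta_min=2.0,
            corr_kind="independent", seed=3,
        )
        ds = simulate_dataset(cfg)
        g1, g2 = ds.X[: ds.n1], ds.X[ds.n1 :]
        assert np.all(np.abs(g1 - g1[0]) < 1e-6)
        np.testing.assert_allclose(
            g2[0] - g1[0], ds.effects.z * ds.effects.delta, atol=1e-6
        )

    def test_correlation_recovery_on_large_sample(self):
        cfg = SimConfig(
            n=100_000, p=6, corr_kind="hub_toeplitz_blocks", seed=11,
            sigma_b=2.5, sigma_e=1.5, r=3,
        )
        ds = simulate_dataset(cfg)
        # remove the injected group effect before estimating correlation
        X = ds.X.copy()
        X[ds.n1 :] -= (ds.effects.z * ds.effects.delta)[None, :]
        emp = np.corrcoef(X.T)
        assert np.max(np.abs(emp - ds.correlation.R)) < 0.02


class TestPoisson:
    def test_marginal_mean_and_variance_lambda(self):
        cfg = SimConfig(
            n=10_000, p=3, family="poisson", lambda_rate=4.0,
            corr_kind="independent", theta_min=1.0, seed=2,
        )
        ds = simulate_poisson_dataset(cfg)
        pre = ds.X.copy()
        pre[ds.n1 :] -= (ds.effects.z * ds.effects.delta)[None, :]
        assert np.all(pre >= 0)
        assert np.all(pre == np.round(pre))
        lam = 4.0
        tol_mean = 3 * np.sqrt(lam / cfg.n)
        assert np.all(np.abs(pre.mean(axis=0) - lam) < tol_mean)
        # var of sample variance for Poisson ~ (lam + 2 lam^2)/n
        tol_var = 3 * np.sqrt((lam + 2 * lam**2) / cfg.n)
        assert np.all(np.abs(pre.var(axis=0, ddof=1) - lam) < tol_var)

    def test_copula_correlation_matches_independent_mc_oracle(self):
        lam, rho = 4.0, 0.7
        # independent Monte-Carlo oracle for the attenuated count correlation
        r = np.random.default_rng(123)
        z1 = r.standard_normal(200_000)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * r.standard_normal(200_000)
        x1 = stats.poisson.ppf(stats.norm.cdf(z1), lam)
        x2 = stats.poisson.ppf(stats.norm.cdf(z2), lam)
        oracle = np.corrcoef(x1, x2)[0, 1]
        assert abs(poisson_copula_correlation(rho, lam) - oracle) < 0.01
        cfg = SimConfig(
            n=100_000, p=2, family="poisson", lambda_rate=lam, theta_min=1.0,
            corr_kind="exchangeable_single_block", rho_fixed=rho, seed=7,
        )
        ds = simulate_poisson_dataset(cfg)
        pre = ds.X.copy()
        pre[ds.n1 :] -= (ds.effects.z * ds.effects.delta)[None, :]
        emp = np.corrcoef(pre.T)[0, 1]
        assert abs(emp - oracle) < 0.05

    def test_norta_correction_recovers_target(self):
        lam, rho = 4.0, 0.6
        cfg = SimConfig(
            n=100_000, p=2, family="poisson", lambda_rate=lam, theta_min=1.0,
            corr_kind="exchangeable_single_block", rho_fixed=rho, seed=8,
        )
        ds = simulate_poisson_dataset(cfg, norta_correction=True)
        pre = ds.X.copy()
        pre[ds.n1 :] -= (ds.effects.z * ds.effects.delta)[None, :]
        assert abs(np.corrcoef(pre.T)[0, 1] - rho) < 0.02

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n=10, p=2, family="poisson", lambda_rate=0.0)


class TestIO:
    def test_roundtrip_with_sidecar(self, tmp_path):
        cfg = SimConfig(n=20, p=4, seed=9)
        ds = simulate_dataset(cfg)
        path = tmp_path / "sim.tsv"
        write_dataset(ds, path)
        X, y, meta = read_dataset(path)
        np.testing.assert_allclose(X, ds.X, rtol=1e-12)
        np.testing.assert_array_equal(y, ds.y)
        assert meta["config"]["n"] == 20
        assert meta["block_sizes"] == ds.correlation.block_sizes
        np.testing.assert_allclose(meta["delta"], ds.effects.delta)


class TestLiteralCholeskyMode:
    def test_literal_transform_scales_covariance_keeps_correlation(self):
        """The reference pipeline's printed transform Y = X C yields row
        covariance v^2 R: correlation is still R but the noise scale is v."""
        cfg = SimConfig(
            n=40_000, p=2, sigma_b=2.5, sigma_e=1.5, r=3,
            corr_kind="exchangeable_single_block", rho_fixed=0.5,
            cholesky_mode="literal", seed=13,
        )
        ds = simulate_dataset(cfg)
        X = ds.X.copy()
        X[ds.n1 :] -= (ds.effects.z * ds.effects.delta)[None, :]
        v = cfg.marginal_variance
        emp_corr = np.corrcoef(X.T)[0, 1]
        assert abs(emp_corr - 0.5) < 3 * (1 - 0.25) / np.sqrt(cfg.n)
        tol = 3 * v**2 * np.sqrt(2 / (cfg.n - 1))
        assert np.all(np.abs(X.var(axis=0, ddof=1) - v**2) < tol)
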