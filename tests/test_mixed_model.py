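import numpy as np
import pytest
from scipy import stats

from eqtlmeta.datamodel import TissueSampleMap
from eqtlmeta.meta_analysis import fixed_effects
from eqtlmeta.mixed_model import (
    EffectEstimates,
    SpectralKernel,
    decorrelate,
    estimate_variance_components,
    gls_effects,
    marginal_error_correction,
    t_statistic_to_z,
)
from eqtlmeta.pipeline import TissueLayout
from eqtlmeta.simulate import make_tissue_maps
from eqtlmeta.tbt import fit_single_tissue

from conftest import random_pd_covariance


def _toy_design(rng, n=40, t=2, shared=True):
    maps = make_tissue_maps(n, t, "full" if shared else "none")
    layout = TissueLayout(maps)
    x = rng.binomial(2, 0.3, n).astype(float)
    dosages = [x.copy() for _ in range(t)]
    y = rng.normal(size=layout.n_obs)
    X = np.hstack([layout.intercept_block, layout.snp_block(dosages)])
    return layout, y, X, dosages


class TestVarianceComponents:
    def test_identity_kernel_matches_ols_residual_variance(self):
        rng = np.random.default_rng(1)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([0.5, 1.0]) + rng.normal(size=n)
        comps = estimate_variance_components(y, X, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        total_ml = resid @ resid / n
        # with K = I the two components are confounded; only their sum is
        # identified and must equal the ML residual variance
        assert comps.sigma_g2 + comps.sigma_e2 == pytest.approx(total_ml, rel=1e-6)

    def test_loglik_beats_random_admissible_pairs(self):
        rng = np.random.default_rng(2)
        maps = make_tissue_maps(30, 3, "full")
        layout = TissueLayout(maps)
        y = rng.normal(size=layout.n_obs)
        comps = estimate_variance_components(
            y, layout.intercept_block, kernel=layout.kernel
        )

        def loglik(sg2, se2):
            V = sg2 * layout.K + se2 * np.eye(layout.n_obs)
            sign, logdet = np.linalg.slogdet(V)
            Vi = np.linalg.inv(V)
            X = layout.intercept_block
            b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ b
            return -0.5 * (layout.n_obs * np.log(2 * np.pi) + logdet + r @ Vi @ r)

        ml = loglik(comps.sigma_g2, comps.sigma_e2)
        assert ml == pytest.approx(comps.loglik, abs=1e-6)
        for _ in range(50):
            sg2 = rng.uniform(0, 3)
            se2 = rng.uniform(0.05, 3)
            assert loglik(sg2, se2) <= ml + 1e-8

    def test_boundary_recovery_when_sharing_variance_absent(self):
        rng = np.random.default_rng(3)
        maps = make_tissue_maps(250, 4, "full")
        layout = TissueLayout(maps)
        # pure residual noise: no individual-sharing component
        y = rng.normal(size=layout.n_obs)
        comps = estimate_variance_components(
            y, layout.intercept_block, kernel=layout.kernel
        )
        assert comps.sigma_g2 < 0.02

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(4)
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            estimate_variance_components(rng.normal(size=n), X, np.eye(n))


class TestGls:
    def test_matches_brute_force_inversion_with_hand_built_v(self):
        rng = np.random.default_rng(5)
        # 2 tissues, 3 fully shared individuals: hand-built 6x6 covariance
        maps = [
            TissueSampleMap("t1", ("a", "b", "c")),
            TissueSampleMap("t2", ("a", "b", "c")),
        ]
        layout = TissueLayout(maps)
        V = 0.4 * layout.K + 0.6 * np.eye(6)
        x = np.array([0.0, 1.0, 2.0])
        X = np.hstack([layout.intercept_block, layout.snp_block([x, x])])
        y = rng.normal(size=6)
        est = gls_effects(y, X, V)
        # independent literal matrix-inversion oracle
        Vi = np.linalg.inv(V)
        A = np.linalg.inv(X.T @ Vi @ X)
        full = A @ X.T @ Vi @ y
        assert np.allclose(est.beta, full[2:], atol=1e-10)
        assert np.allclose(est.cov, A[2:, 2:], atol=1e-10)
        assert np.allclose(est.intercepts, full[:2], atol=1e-10)

    def test_iid_errors_reduce_to_per_tissue_ols(self):
        rng = np.random.default_rng(6)
        layout, y, X, dosages = _toy_design(rng, n=25, t=2, shared=False)
        est = gls_effects(y, X, 1.7 * np.eye(layout.n_obs))
        for j in range(2):
            rows = slice(j * 25, (j + 1) * 25)
            slope = np.polyfit(dosages[j], y[rows], 1)[0]
            assert est.beta[j] == pytest.approx(slope, abs=1e-10)

    def test_single_study_matches_textbook_simple_regression(self):
        rng = np.random.default_rng(7)
        n = 30
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        sigma2 = 1.3
        est = gls_effects(y, X, sigma2 * np.eye(n), n_snp=1)
        xc = x - x.mean()
        slope = xc @ (y - y.mean()) / (xc @ xc)
        assert est.beta[0] == pytest.approx(slope, abs=1e-12)
        assert est.se[0] ** 2 == pytest.approx(sigma2 / (xc @ xc), rel=1e-10)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(8)
        layout, y, X, _ = _toy_design(rng)
        V = 0.3 * layout.K + 0.7 * np.eye(layout.n_obs)
        a = gls_effects(y, X, V)
        b = gls_effects(3.0 * y, X, V)
        assert np.allclose(b.beta, 3.0 * a.beta, atol=1e-10)
        assert np.allclose(b.cov, a.cov, atol=1e-10)  # cov is y-scale free here

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            gls_effects(np.zeros(2), np.eye(2), -np.eye(2), n_snp=1)


class TestDecorrelate:
    def test_diagonal_covariance_is_fixed_point(self):
        est = EffectEstimates(
            beta=[1.0, -0.5], cov=np.diag([0.25, 4.0]), se=[0.5, 2.0]
        )
        out = decorrelate(est)
        assert out.decorrelated
        assert np.allclose(out.se**2, [0.25, 4.0], atol=1e-12)

    def test_preserves_optimal_correlated_statistic(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            k = rng.integers(2, 6)
            sigma = random_pd_covariance(rng, int(k))
            beta = rng.normal(size=k)
            out = decorrelate(EffectEstimates(
                beta=beta, cov=sigma, se=np.sqrt(np.diag(sigma))
            ))
            z, _, _, _ = fixed_effects(out.beta, out.se)
            ones = np.ones(k)
            si = np.linalg.solve(sigma, ones)
            z_opt = (si @ beta) / np.sqrt(ones @ si)
            assert z == pytest.approx(z_opt, abs=1e-10)

    def test_exchangeable_covariance_gives_equal_variances(self):
        sigma = np.array([[1.0, 0.6], [0.6, 1.0]])
        out = decorrelate(EffectEstimates(
            beta=[0.2, 0.4], cov=sigma, se=[1.0, 1.0]
        ))
        assert out.se[0] == pytest.approx(out.se[1], abs=1e-12)
        assert np.allclose(out.beta, [0.2, 0.4])

    def test_non_pd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            decorrelate(EffectEstimates(beta=[0.0, 0.0], cov=bad, se=[1.0, 1.0]))


class TestErrorCorrection:
    def test_quantile_match_values(self):
        # frozen from the independent t/normal distribution oracle
        assert t_statistic_to_z(2.0, 8) == pytest.approx(
            stats.norm.isf(stats.t.sf(2.0, 8)), abs=1e-12
        )
        assert t_statistic_to_z(2.0, 8) == pytest.approx(1.7476985620285195, abs=1e-10)
        assert t_statistic_to_z(0.0, 3) == 0.0
        assert t_statistic_to_z(-1.5, 10) == -t_statistic_to_z(1.5, 10)
        assert t_statistic_to_z(2.0, np.inf) == 2.0

    def test_infinite_df_is_identity(self):
        est = EffectEstimates(
            beta=[0.5, -0.2],
            cov=np.array([[0.04, 0.01], [0.01, 0.09]]),
            se=[0.2, 0.3],
        )
        fits = [(0.5, 0.2, np.inf), (-0.2, 0.3, np.inf)]
        out = marginal_error_correction(est, fits)
        assert np.allclose(out.se, est.se, atol=1e-12)
        assert np.allclose(out.cov, est.cov, atol=1e-12)

    def test_marginal_z_matches_single_tissue_quantile(self):
        est = EffectEstimates(
            beta=[0.6, 0.3], cov=np.diag([0.04, 0.09]), se=[0.2, 0.3]
        )
        fits = [(0.6, 0.25, 12), (0.3, 0.5, 20)]
        out = marginal_error_correction(est, fits)
        for i, (b, s, df) in enumerate(fits):
            z_target = t_statistic_to_z(b / s, df)
            assert out.beta[i] / out.se[i] == pytest.approx(z_target, abs=1e-10)

    def test_invalid_df_rejected(self):
        est = EffectEstimates(beta=[0.1], cov=[[0.01]], se=[0.1])
        with pytest.raises(ValueError, match="df"):
            marginal_error_correction(est, [(0.1, 0.1, 0.5)])


class TestNoSharingReduction:
    def test_pipeline_reproduces_tissue_by_tissue_ols(self):
        """With disjoint individuals the stacked model decouples into t
        independent single-tissue regressions."""
        rng = np.random.default_rng(11)
        n, t = 50, 3
        maps = make_tissue_maps(n, t, "none")
        layout = TissueLayout(maps)
        dosages = [rng.binomial(2, 0.3, n).astype(float) for _ in range(t)]
        ys = [rng.normal(size=n) + 0.4 * d for d, _ in zip(dosages, range(t))]
        from eqtlmeta.pipeline import AnalysisConfig

        res = layout.analyze(
            ys, dosages, AnalysisConfig(compute_mvalues=False), standardize=False
        )
        fits = [fit_single_tissue(y, d) for y, d in zip(ys, dosages)]
        for j in range(t):
            assert res.decorrelated.beta[j] == pytest.approx(fits[j].beta, abs=1e-8)
            # the quantile-matched variance equals the TBT variance mapped
            # through the same t->normal correspondence
            z = t_statistic_to_z(fits[j].t_stat, fits[j].df)
            assert res.decorrelated.se[j] == pytest.approx(
                abs(fits[j].beta / z), abs=1e-8
            )


class TestSpectralKernel:
    def test_rejects_invalid_kernels(self):
        with pytest.raises(ValueError):
            SpectralKernel(np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            SpectralKernel(np.array([[2.0, 0.0], [0.0, 1.0]]))
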