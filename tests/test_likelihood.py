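import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mrlink2.io import LDMatrix
from mrlink2.likelihood import (
    Link2Params,
    fit_region,
    ld_eigen_basis,
    log_likelihood,
    prepare_region,
    rotate_effects,
    run_mr_link2,
)
from mrlink2.simulate import (
    RegionSimulator,
    ScenarioSpec,
    synth_ld,
)

from conftest import random_correlation

NX, NY = 10_000.0, 300_000.0


def mvn_oracle(betaX, betaY, C, alpha, sx2, sy2, nX=NX, nY=NY):
    """Direct 2m-dimensional Gaussian log-density of the stacked effects.

    Assembles the full covariance from the model blocks (genetic variance
    through C^2, sampling noise through C/n) without any eigen machinery —
    an independent route to the same quantity the likelihood computes."""
    C2 = C @ C
    top = np.hstack([sx2 * C2 + C / nX, alpha * sx2 * C2])
    bottom = np.hstack(
        [alpha * sx2 * C2, (alpha**2 * sx2 + sy2) * C2 + C / nY]
    )
    cov = np.vstack([top, bottom])
    return multivariate_normal.logpdf(
        np.concatenate([betaX, betaY]), mean=np.zeros(2 * len(betaX)), cov=cov
    )


class TestPrepareRegion:
    def test_identity_ld_rotation_is_orthogonal_pass_through(self, rng):
        m = 10
        betaX, betaY = rng.normal(size=m), rng.normal(size=m)
        eig = prepare_region(betaX, betaY, np.eye(m), NX, NY, variance_kept=0.99)
        # identity C: eigenvalues all one, rotation preserves the norm
        assert eig.m == m
        np.testing.assert_allclose(eig.lambdas, 1.0)
        assert np.linalg.norm(eig.deltaX) == pytest.approx(np.linalg.norm(betaX))

    def test_rank_one_ld_keeps_single_component(self, rng):
        m = 6
        C = np.ones((m, m))
        eig = prepare_region(rng.normal(size=m), rng.normal(size=m), C, NX, NY)
        assert eig.m == 1
        assert eig.lambdas[0] == pytest.approx(m)

    def test_decomposition_reconstructs_c(self, rng):
        C = random_correlation(10, rng)
        basis = ld_eigen_basis(C, variance_kept=1.0)
        np.testing.assert_allclose(
            basis.U @ np.diag(basis.lambdas) @ basis.U.T, C, atol=1e-10
        )

    def test_truncation_keeps_requested_variance(self, rng):
        C = random_correlation(40, rng)
        basis = ld_eigen_basis(C, variance_kept=0.99)
        assert basis.lambdas.sum() >= 0.99 * np.trace(C)
        assert basis.m_full == 40
        # orthonormal columns
        np.testing.assert_allclose(
            basis.U.T @ basis.U, np.eye(len(basis.lambdas)), atol=1e-10
        )

    def test_misaligned_inputs_fatal(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            prepare_region(np.zeros(3), np.zeros(4), np.eye(4), NX, NY)


class TestLogLikelihood:
    @pytest.mark.parametrize("alpha", [-0.2, 0.0, 0.3])
    @pytest.mark.parametrize("sx2", [1e-5, 1e-4, 1e-3])
    @pytest.mark.parametrize("sy2", [0.0, 1e-6, 1e-4])
    def test_equals_direct_gaussian_density(self, rng, alpha, sx2, sy2):
        m = 4
        C = random_correlation(m, rng)
        betaX = rng.normal(scale=0.01, size=m)
        betaY = rng.normal(scale=0.005, size=m)
        eig = prepare_region(betaX, betaY, C, NX, NY, variance_kept=1.0)
        got = log_likelihood(Link2Params(alpha, sx2, sy2), eig)
        want = mvn_oracle(betaX, betaY, C, alpha, sx2, sy2)
        assert got == pytest.approx(want, abs=1e-6)

    def test_sign_symmetry(self, rng):
        m = 5
        C = random_correlation(m, rng)
        betaX = rng.normal(scale=0.01, size=m)
        betaY = rng.normal(scale=0.01, size=m)
        eig_pos = prepare_region(betaX, betaY, C, NX, NY, variance_kept=1.0)
        eig_neg = prepare_region(betaX, -betaY, C, NX, NY, variance_kept=1.0)
        for eps in (0.05, 0.2):
            a = log_likelihood(Link2Params(eps, 1e-4, 1e-5), eig_pos)
            b = log_likelihood(Link2Params(-eps, 1e-4, 1e-5), eig_neg)
            assert a == pytest.approx(b, rel=1e-12)

    def test_inflating_exposure_variance_without_signal_lowers_ll(self, rng):
        m = 5
        C = random_correlation(m, rng)
        betaY = rng.normal(scale=0.002, size=m)
        eig = prepare_region(np.zeros(m), betaY, C, NX, NY, variance_kept=1.0)
        lls = [
            log_likelihood(Link2Params(0.0, sx2, 1e-6), eig)
            for sx2 in (1e-5, 2e-5, 4e-5)
        ]
        assert lls[0] > lls[1] > lls[2]

    def test_nonfinite_guard(self, rng):
        eig = prepare_region(
            np.zeros(3), np.zeros(3), np.eye(3), NX, NY, variance_kept=1.0
        )
        # overflowing parameters must retreat to -inf, not raise
        assert log_likelihood(Link2Params(np.nan, 1e-4, 0.0), eig) == -np.inf
        assert log_likelihood(Link2Params(0.0, np.inf, 0.0), eig) == -np.inf


@pytest.fixture(scope="module")
def fitted_region():
    """One strong simulated region (alpha=0.2) shared across fit tests."""
    ld = synth_ld(120, seed=7)
    spec = ScenarioSpec(alpha=0.2, h2x=0.1, h2y=1e-20, m=120, m_causal=10, nX=10_000,
                        nY=300_000)
    sim = RegionSimulator(ld=ld, spec=spec)
    rng = np.random.default_rng(11)
    betaX, betaY = sim.replicate(rng)
    eig = prepare_region(betaX, betaY, ld, spec.nX, spec.nY)
    return eig, fit_region(eig), ld, betaX, betaY


class TestFitRegion:
    def test_nesting_of_constrained_fits(self, fitted_region):
        _, fit, _, _, _ = fitted_region
        assert fit.ll_full >= fit.ll_alpha0 - 1e-6
        assert fit.ll_full >= fit.ll_sigy0 - 1e-6

    def test_strong_signal_detected(self, fitted_region):
        _, fit, _, _, _ = fitted_region
        assert fit.p_alpha < 1e-6
        assert fit.params_full.alpha == pytest.approx(0.2, abs=0.05)
        assert np.isfinite(fit.se_alpha) and fit.se_alpha > 0

    def test_zero_outcome_gives_zero_alpha(self, fitted_region):
        eig, _, ld, betaX, _ = fitted_region
        eig0 = prepare_region(betaX, np.zeros_like(betaX), ld, NX, NY)
        fit0 = fit_region(eig0)
        assert abs(fit0.params_full.alpha) < 0.01
        assert fit0.p_alpha > 0.9

    def test_scale_equivariance(self, fitted_region):
        # scaling n by c, data by 1/sqrt(c) (and variances implicitly by 1/c)
        # leaves the profile in alpha unchanged
        eig, fit, ld, betaX, betaY = fitted_region
        c = 4.0
        eig_scaled = prepare_region(
            betaX / np.sqrt(c), betaY / np.sqrt(c), ld, NX * c, NY * c
        )
        fit_scaled = fit_region(eig_scaled, compute_se=False)
        assert fit_scaled.params_full.alpha == pytest.approx(
            fit.params_full.alpha, abs=2e-3
        )

    def test_result_wrapper_reports_heritabilities(self, fitted_region):
        _, _, ld, betaX, betaY = fitted_region
        res = run_mr_link2(betaX, betaY, ld, NX, NY, region_bounds=("1", 1, 2))
        assert res.method == "mr_link2"
        assert res.h2x_hat == pytest.approx(0.1, abs=0.08)
        assert res.h2y_hat >= 0
        assert res.region == ("1", 1, 2)

    def test_alpha_recovery_over_replicates(self):
        ld = synth_ld(80, seed=3)
        spec = ScenarioSpec(alpha=0.1, h2x=0.1, h2y=1e-20, m=80, m_causal=10)
        sim = RegionSimulator(ld=ld, spec=spec)
        basis = ld_eigen_basis(ld)
        rng = np.random.default_rng(5)
        alphas = []
        for _ in range(40):
            betaX, betaY = sim.replicate(rng)
            eig = rotate_effects(basis, betaX, betaY, spec.nX, spec.nY)
            alphas.append(fit_region(eig, compute_se=False).params_full.alpha)
        mc_se = np.std(alphas) / np.sqrt(len(alphas))
        assert np.mean(alphas) == pytest.approx(0.1, abs=3 * mc_se + 1e-3)


def test_negative_eigenvalues_repaired(rng):
    C = random_correlation(6, rng)
    # make it slightly indefinite
    bad = C - 1.5 * np.min(np.linalg.eigvalsh(C)) * (np.eye(6) - 1.0 / 6)
    bad = 0.5 * (bad + bad.T)
    d = np.sqrt(np.diag(bad))
    bad = bad / np.outer(d, d)
    eigvals = np.linalg.eigvalsh(bad)
    if eigvals.min() >= -1e-8:
        pytest.skip("construction did not produce an indefinite matrix")
    with pytest.warns(UserWarning, match="negative eigenvalues"):
        basis = ld_eigen_basis(bad)
    assert np.all(basis.lambdas > 0)
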