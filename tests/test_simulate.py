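import numpy as np
import pytest

from mrlink2.io import LDMatrix
from mrlink2.simulate import (
    RegionSimulator,
    ScenarioInfeasible,
    ScenarioSpec,
    sample_reference_ld,
    select_causal_sets,
    simulate_summary_stats,
    synth_ld,
)

from conftest import make_variants


class TestSynthLD:
    def test_zero_rho_gives_identity(self):
        ld = synth_ld(20, rho=0.0, seed=1)
        np.testing.assert_allclose(ld.C, np.eye(20))

    def test_positive_semidefinite_and_bounded(self):
        ld = synth_ld(500, block_size=50, rho=0.9, seed=2)
        eigvals = np.linalg.eigvalsh(ld.C)
        assert eigvals.min() > -1e-10
        off = ld.C[~np.eye(500, dtype=bool)]
        assert np.max(np.abs(off)) < 1.0

    def test_deterministic_given_seed(self):
        a = synth_ld(100, seed=42)
        b = synth_ld(100, seed=42)
        np.testing.assert_array_equal(a.C, b.C)
        assert (a.variants == b.variants).all().all()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            synth_ld(10, rho=1.0)


class TestSelectCausalSets:
    def test_unconstrained_selection_uniform(self):
        ld = synth_ld(50, seed=3)
        exp, out = select_causal_sets(ld, 10, 0.0, 1.0, seed=4)
        assert len(set(exp)) == 10 and len(set(out)) == 10
        assert exp.max() < 50

    def test_identity_ld_with_min_r_infeasible(self):
        ld = LDMatrix(np.eye(30), make_variants(30))
        with pytest.raises(ScenarioInfeasible):
            select_causal_sets(ld, 3, 0.1, 0.95, seed=5, max_tries=10)

    def test_constraints_hold_posthoc(self):
        ld = synth_ld(200, block_size=60, rho=0.95, seed=6)
        r_min, r_max = 0.1, 0.95
        exp, out = select_causal_sets(ld, 3, r_min, r_max, seed=7)
        absC = np.abs(ld.C)
        for i, a in enumerate(exp):
            for b in exp[i + 1:]:
                assert r_min <= absC[a, b] <= r_max
        for b in out:
            assert b in exp or np.any(
                (absC[exp, b] >= r_min) & (absC[exp, b] <= r_max)
            )


class TestSimulateSummaryStats:
    def test_exact_heritability_rescaling(self):
        ld = synth_ld(60, seed=8)
        spec = ScenarioSpec(alpha=0.1, h2x=0.05, h2y=0.01, m=60, m_causal=5)
        rng = np.random.default_rng(9)
        causal = select_causal_sets(ld, 5, seed=rng)
        # replicate the internal draw to verify gamma' C gamma == h2 exactly
        from mrlink2.simulate import _scaled_sparse_effects

        gamma = _scaled_sparse_effects(60, causal[0], spec.h2x, ld.C, rng)
        assert gamma @ ld.C @ gamma == pytest.approx(spec.h2x, rel=1e-12)

    def test_null_independence_of_traits(self):
        ld = synth_ld(40, seed=10)
        spec = ScenarioSpec(alpha=0.0, h2x=0.05, h2y=1e-20, m=40, m_causal=5)
        sim = RegionSimulator(ld=ld, spec=spec)
        rng = np.random.default_rng(11)
        cors = []
        for _ in range(300):
            betaX, betaY = sim.replicate(rng)
            cors.append(np.corrcoef(betaX, betaY)[0, 1])
        # per-replicate correlations fluctuate; their mean should be ~0
        assert abs(np.mean(cors)) < 0.05

    def test_noise_covariance_matches_model(self):
        # fixed causal effects, many replicates: Cov(betaX) -> C (1-h2x)/nX
        m = 25
        ld = synth_ld(m, block_size=8, rho=0.8, seed=12)
        spec = ScenarioSpec(alpha=0.0, h2x=0.02, h2y=1e-20, m=m, m_causal=m,
                            nX=1000, nY=2000)
        rng = np.random.default_rng(13)
        causal = (np.arange(m), np.arange(m))
        draws = []
        gamma_rng = np.random.default_rng(14)
        from mrlink2.simulate import _scaled_sparse_effects, cholesky_with_jitter

        gamma = _scaled_sparse_effects(m, causal[0], spec.h2x, ld.C, gamma_rng)
        chol = cholesky_with_jitter(ld.C)
        mean = ld.C @ gamma
        for _ in range(4000):
            noise = chol @ rng.normal(size=m) * np.sqrt((1 - spec.h2x) / spec.nX)
            draws.append(mean + noise)
        emp = np.cov(np.array(draws), rowvar=False)
        expected = ld.C * (1 - spec.h2x) / spec.nX
        assert np.max(np.abs(emp - expected)) < 6 * np.max(expected) / np.sqrt(4000) * 3

    def test_causal_z_variance_elevated(self):
        # identity LD, all SNPs causal: Var(z) ~ 1 - h2x + nX*h2x/m
        m, nx = 50, 10_000
        ld = LDMatrix(np.eye(m), make_variants(m))
        spec = ScenarioSpec(alpha=0.0, h2x=0.1, h2y=1e-20, m=m, m_causal=m, nX=nx)
        sim = RegionSimulator(ld=ld, spec=spec)
        rng = np.random.default_rng(15)
        zvars = []
        for _ in range(400):
            betaX, _ = sim.replicate(rng)
            zvars.append(np.var(betaX * np.sqrt(nx)))
        expected = 1 - spec.h2x + nx * spec.h2x / m
        assert np.mean(zvars) == pytest.approx(expected, rel=0.1)

    def test_determinism(self):
        ld = synth_ld(30, seed=16)
        spec = ScenarioSpec(m=30, m_causal=3, h2x=0.05)
        causal = select_causal_sets(ld, 3, seed=17)
        a = simulate_summary_stats(ld, spec, causal, seed=18)
        b = simulate_summary_stats(ld, spec, causal, seed=18)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestSampleReferenceLD:
    def test_exact_reference_returns_input(self):
        ld = synth_ld(20, seed=19)
        assert sample_reference_ld(ld, None, seed=20) is ld

    def test_large_reference_converges(self):
        ld = synth_ld(40, seed=21)
        sampled = sample_reference_ld(ld, 100_000, seed=22)
        assert np.max(np.abs(sampled.C - ld.C)) < 0.02
        assert sampled.n_ref == 100_000

    def test_mean_of_samples_nearly_unbiased(self):
        ld = synth_ld(15, seed=23)
        rng = np.random.default_rng(24)
        acc = np.zeros_like(ld.C)
        k = 400
        for _ in range(k):
            acc += sample_reference_ld(ld, 500, seed=rng).C
        bias = (acc / k - ld.C)[~np.eye(15, dtype=bool)]
        assert np.max(np.abs(bias)) < 0.02


class TestScenarioSpec:
    def test_invalid_residual_variance_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            ScenarioSpec(alpha=1.0, h2x=0.9, h2y=0.2)

    def test_from_dict_parses_exact_sentinel(self):
        spec = ScenarioSpec.from_dict({"n_ref": "exact", "m": 100, "m_causal": 5})
        assert spec.n_ref is None
        spec = ScenarioSpec.from_dict({"n_ref": "500", "m": 100, "m_causal": 5})
        assert spec.n_ref == 500
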