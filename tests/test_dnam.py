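import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emixed import dnam
from emixed.io import Config
from emixed.types import BulkMatrix, MethylSignature, ValidationError

from conftest import grid_search_dnam, random_dnam_instance


class TestClipSignature:
    @pytest.mark.parametrize("value,expected", [(0.0, 1e-6), (0.5, 0.5), (1.0, 1 - 1e-6)])
    def test_clipping_bounds(self, value, expected):
        pi = dnam.clip_signature(pd.DataFrame({"a": [value]}, index=["c1"]), 1e-6)
        assert pi.values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValidationError):
            dnam.clip_signature(pd.DataFrame({"a": [1.4]}, index=["c1"]))


class TestESteps:
    def test_uninformative_locus_returns_prior(self):
        pi = MethylSignature(["c1"], ["a", "b"], np.array([[0.4, 0.4]]))
        theta = np.array([0.3, 0.7])
        psi1, psi0 = dnam.dnam_e_step(pi, theta)
        np.testing.assert_allclose(psi1[0], theta)
        np.testing.assert_allclose(psi0[0], theta)

    def test_discriminating_locus_limit(self):
        eps = 1e-9
        pi = MethylSignature(["c1"], ["a", "b"], np.array([[1 - eps, eps]]))
        psi1, psi0 = dnam.dnam_e_step(pi, np.array([0.5, 0.5]))
        np.testing.assert_allclose(psi1[0], [1.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(psi0[0], [0.0, 1.0], atol=1e-8)

    def test_hand_evaluated_responsibilities(self, toy_signature):
        psi1, _ = dnam.dnam_e_step(toy_signature, np.array([0.3, 0.7]))
        np.testing.assert_allclose(psi1[0], np.array([0.27, 0.07]) / 0.34, atol=1e-9)

    def test_rows_are_simplex(self):
        rng = np.random.default_rng(0)
        meth, cov, pi, theta = random_dnam_instance(rng)
        psi1, psi0 = dnam.dnam_e_step(pi, theta)
        np.testing.assert_allclose(psi1.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(psi0.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((psi1 >= 0) & (psi1 <= 1))


class TestMSteps:
    def test_uninformative_signature_is_fixed_point(self):
        pi = MethylSignature(["c1", "c2"], ["a", "b"],
                             np.full((2, 2), 0.4))
        theta = np.array([0.3, 0.7])
        psi1, psi0 = dnam.dnam_e_step(pi, theta)
        out = dnam.dnam_m_step_seq(psi1, psi0, np.array([4.0, 1.0]),
                                   np.array([10.0, 10.0]))
        np.testing.assert_allclose(out, theta, atol=1e-12)

    def test_single_fully_methylated_locus(self):
        psi1 = np.array([[1.0, 0.0]])
        psi0 = np.array([[0.5, 0.5]])
        out = dnam.dnam_m_step_seq(psi1, psi0, np.array([10.0]), np.array([10.0]))
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_hand_evaluated_seq_update(self, toy_signature):
        # mirror-marker loci, full methylation at locus 1, none at locus 2
        psi1, psi0 = dnam.dnam_e_step(toy_signature, np.array([0.5, 0.5]))
        out = dnam.dnam_m_step_seq(psi1, psi0, np.array([10.0, 0.0]),
                                   np.array([10.0, 10.0]))
        np.testing.assert_allclose(out, [0.9, 0.1], atol=1e-9)

    def test_array_equals_seq_at_constant_coverage(self):
        rng = np.random.default_rng(1)
        meth, cov, pi, theta = random_dnam_instance(rng, D=20)
        psi1, psi0 = dnam.dnam_e_step(pi, theta)
        seq = dnam.dnam_m_step_seq(psi1, psi0, meth, cov)
        arr = dnam.dnam_m_step_array(psi1, psi0, meth / cov)
        np.testing.assert_allclose(seq, arr, atol=1e-12)

    def test_array_single_locus_normalizes_numerator(self):
        psi1 = np.array([[0.7941, 0.2059]])
        psi0 = np.array([[0.1, 0.9]])
        out = dnam.dnam_m_step_array(psi1, psi0, np.array([1.0]))
        np.testing.assert_allclose(out, [0.7941, 0.2059], atol=1e-9)

    def test_all_zero_coverage_raises(self):
        psi = np.full((1, 2), 0.5)
        with pytest.raises(ValidationError, match="coverage"):
            dnam.dnam_m_step_seq(psi, psi, np.array([0.0]), np.array([0.0]))


class TestLogLikelihood:
    def test_single_type_constant_in_theta(self):
        pi = MethylSignature(["c1", "c2"], ["a"], np.array([[0.2], [0.8]]))
        ll = dnam.dnam_log_likelihood(np.array([3.0, 4.0]), np.array([5.0, 5.0]),
                                      pi, np.array([1.0]))
        assert np.isfinite(ll)

    def test_concavity_in_theta(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            meth, cov, pi, _ = random_dnam_instance(rng, G=15, K=3)
            t1, t2 = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
            mid = 0.5 * (t1 + t2)
            f = lambda t: dnam.dnam_log_likelihood(meth, cov, pi, t)
            assert f(mid) >= 0.5 * (f(t1) + f(t2)) - 1e-9

    def test_grid_maximum_at_em_fixed_point(self):
        rng = np.random.default_rng(3)
        meth, cov, pi, _ = random_dnam_instance(rng, G=10, K=2, D=40)
        bulk = BulkMatrix(pi.loci, ["s1"], meth[:, None], "dnam_counts",
                          coverage=cov[:, None])
        fit = dnam.fit_dnam(bulk, pi, Config(tol=1e-10, max_iter=20000))
        best = grid_search_dnam(meth, cov, pi, step=1e-4)
        assert abs(fit.fractions.values[0, 0] - best[0]) <= 1e-3


class TestQuantileNormalize:
    def test_identical_multisets_fixed_point(self):
        col = np.array([0.1, 0.5, 0.9])
        ref = np.column_stack([col, col[::-1]])
        bulk = col[:, None]
        r, b = dnam.joint_quantile_normalize(ref, bulk)
        np.testing.assert_allclose(r, ref)
        np.testing.assert_allclose(b, bulk)

    def test_hand_evaluated_rank_means(self):
        r, b = dnam.joint_quantile_normalize(
            np.array([[0.1], [0.5], [0.9]]), np.array([[0.2], [0.6], [1.0]])
        )
        np.testing.assert_allclose(r.ravel(), [0.15, 0.55, 0.95])
        np.testing.assert_allclose(b.ravel(), [0.15, 0.55, 0.95])

    def test_all_output_columns_share_sorted_values(self):
        rng = np.random.default_rng(4)
        ref = rng.beta(2, 2, size=(30, 3))
        bulk = rng.beta(5, 1, size=(30, 4))
        r, b = dnam.joint_quantile_normalize(ref, bulk)
        out = np.hstack([r, b])
        ref_sorted = np.sort(out[:, 0])
        for c in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, c]), ref_sorted, atol=1e-12)

    def test_ties_get_mean_of_spanned_quantiles(self):
        ref = np.array([[0.2], [0.2], [0.8]])
        bulk = np.array([[0.1], [0.5], [0.9]])
        r, b = dnam.joint_quantile_normalize(ref, bulk)
        m = np.sort(np.hstack([ref, bulk]), axis=0).mean(axis=1)
        # tied 0.2s span ranks 1-2 and both get the mean of m[0:2]
        np.testing.assert_allclose(r.ravel()[:2], m[:2].mean())


class TestFitDnam:
    def test_single_cell_type_degenerate(self):
        pi = MethylSignature(["c1", "c2"], ["a"], np.array([[0.2], [0.7]]))
        bulk = BulkMatrix(["c1", "c2"], ["s1"], np.array([[0.3], [0.6]]), "dnam_beta")
        fit = dnam.fit_dnam(bulk, pi)
        np.testing.assert_allclose(fit.fractions.values, 1.0)

    def test_seq_recovery_bimodal_signature(self):
        rng = np.random.default_rng(12)
        G, theta = 500, np.array([0.2, 0.8])
        pi = MethylSignature(
            [f"cg{g}" for g in range(G)], ["a", "b"],
            np.clip(rng.beta(0.3, 0.3, size=(G, 2)), 1e-6, 1 - 1e-6),
        )
        meth = rng.binomial(50, pi.values @ theta).astype(float)
        bulk = BulkMatrix(pi.loci, ["s1"], meth[:, None], "dnam_counts",
                          coverage=np.full((G, 1), 50.0))
        fit = dnam.fit_dnam(bulk, pi)
        np.testing.assert_allclose(fit.fractions.values[0], theta, atol=0.03)

    def test_noise_free_array_identifiability(self):
        # exact mixture betas, well-conditioned signature, no QN distortion
        rng = np.random.default_rng(13)
        G, theta = 200, np.array([0.35, 0.65])
        pi = MethylSignature(
            [f"cg{g}" for g in range(G)], ["a", "b"],
            np.clip(rng.beta(0.3, 0.3, size=(G, 2)), 1e-3, 1 - 1e-3),
        )
        beta = pi.values @ theta
        bulk = BulkMatrix(pi.loci, ["s1"], beta[:, None], "dnam_beta")
        fit = dnam.fit_dnam(bulk, pi, Config(quantile_norm=False, tol=1e-12,
                                             max_iter=100_000))
        np.testing.assert_allclose(fit.fractions.values[0], theta, atol=1e-4)

    def test_seq_and_beta_paths_agree_at_constant_coverage(self):
        rng = np.random.default_rng(14)
        meth, cov, pi, _ = random_dnam_instance(rng, G=60, K=3, D=40)
        seq_bulk = BulkMatrix(pi.loci, ["s1"], meth[:, None], "dnam_counts",
                              coverage=cov[:, None])
        beta_bulk = BulkMatrix(pi.loci, ["s1"], (meth / cov)[:, None], "dnam_beta")
        opts = Config(quantile_norm=False)
        fit_seq = dnam.fit_dnam(seq_bulk, pi, opts)
        fit_beta = dnam.fit_dnam(beta_bulk, pi, opts)
        np.testing.assert_allclose(
            fit_seq.fractions.values, fit_beta.fractions.values, atol=1e-10
        )
        assert np.array_equal(fit_seq.iterations, fit_beta.iterations)

    def test_zero_coverage_loci_skipped_per_sample(self):
        rng = np.random.default_rng(15)
        meth, cov, pi, _ = random_dnam_instance(rng, G=30, K=2, D=20)
        cov2, meth2 = cov.copy(), meth.copy()
        cov2[:10] = 0.0
        meth2[:10] = 0.0
        bulk_full = BulkMatrix(pi.loci, ["s1"], meth2[:, None], "dnam_counts",
                               coverage=cov2[:, None])
        bulk_trim = BulkMatrix(pi.loci[10:], ["s1"], meth2[10:, None],
                               "dnam_counts", coverage=cov2[10:, None])
        pi_trim = pi.subset(np.arange(10, 30))
        f1 = dnam.fit_dnam(bulk_full, pi)
        f2 = dnam.fit_dnam(bulk_trim, pi_trim)
        np.testing.assert_allclose(f1.fractions.values, f2.fractions.values,
                                   atol=1e-12)

    def test_label_equivariance(self):
        rng = np.random.default_rng(16)
        meth, cov, pi, _ = random_dnam_instance(rng, G=40, K=3)
        bulk = BulkMatrix(pi.loci, ["s1"], meth[:, None], "dnam_counts",
                          coverage=cov[:, None])
        fit = dnam.fit_dnam(bulk, pi)
        perm = np.array([1, 2, 0])
        pi_perm = MethylSignature(pi.loci, [pi.cell_types[i] for i in perm],
                                  pi.values[:, perm])
        fit_perm = dnam.fit_dnam(bulk, pi_perm)
        np.testing.assert_allclose(
            fit_perm.fractions.values[0], fit.fractions.values[0, perm], atol=1e-9
        )

    def test_recovery_improves_with_coverage(self):
        rng = np.random.default_rng(17)
        theta = np.array([0.25, 0.45, 0.3])
        G = 200
        pi = MethylSignature(
            [f"cg{g}" for g in range(G)], ["a", "b", "c"],
            np.clip(rng.beta(0.3, 0.3, size=(G, 3)), 1e-6, 1 - 1e-6),
        )
        maes = []
        for D in (10, 100, 1000):
            errs = []
            for rep in range(10):
                meth = rng.binomial(D, pi.values @ theta).astype(float)
                bulk = BulkMatrix(pi.loci, ["s1"], meth[:, None], "dnam_counts",
                                  coverage=np.full((G, 1), float(D)))
                est = dnam.fit_dnam(bulk, pi).fractions.values[0]
                errs.append(np.mean(np.abs(est - theta)))
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_em_monotone_on_random_instances(seed):
    """Per-iteration DNAm log-likelihood never decreases (EM guarantee)."""
    rng = np.random.default_rng(seed)
    meth, cov, pi, _ = random_dnam_instance(rng, G=25, K=3, D=30)
    bulk = BulkMatrix(pi.loci, ["s1"], meth[:, None], "dnam_counts",
                      coverage=cov[:, None])
    fit = dnam.fit_dnam(bulk, pi, Config(max_iter=300))
    assert np.all(np.diff(fit.loglik_trace[0]) >= -1e-8)
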