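import numpy as np
import pandas as pd
import pytest

from atacmod import deconvolution as dc
from atacmod.io import ValidationError
from atacmod.synthetic import SyntheticConfig, generate_mixture_experiment


class TestPseudoBulk:
    def test_tiny_group_sums(self):
        counts = np.array([[1, 0], [0, 2]])
        u, a, types, samples = dc.pseudo_bulk(counts, ["t"] * 2, ["s"] * 2)
        np.testing.assert_array_equal(u[:, 0, 0], [1, 2])
        assert a[0, 0] == 2

    def test_matches_bruteforce_loop(self, rng):
        counts = rng.poisson(3, size=(10, 30))
        cts = rng.choice(["a", "b"], 30)
        smp = rng.choice(["s1", "s2", "s3"], 30)
        u, a, types, samples = dc.pseudo_bulk(counts, cts, smp)
        for j, t in enumerate(types):
            for k, s in enumerate(samples):
                mask = (cts == t) & (smp == s)
                expect = counts[:, mask].sum(axis=1) if mask.any() else 0
                np.testing.assert_array_equal(u[:, j, k], expect)
                assert a[j, k] == mask.sum()


class TestQuantileNormalize:
    def test_identical_vectors_unchanged(self):
        X = np.array([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        out, _ = dc.quantile_normalize(X)
        np.testing.assert_allclose(out, X)

    def test_two_vector_example(self):
        X = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out, ref = dc.quantile_normalize(X)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_all_columns_share_sorted_values(self, rng):
        X = rng.random((50, 4))
        out, _ = dc.quantile_normalize(X)
        base = np.sort(out[:, 0])
        for c in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, c]), base)

    def test_ties_receive_mean_of_assigned_values(self):
        X = np.array([[1.0], [1.0], [5.0]])
        out, _ = dc.quantile_normalize(X, reference=np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out[:, 0], [15.0, 15.0, 30.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dc.quantile_normalize(np.ones((3, 1)), reference=np.ones(4))


class TestNucleiEquivalents:
    def test_direct_formula(self):
        u = np.array([[1.0], [1.0]])
        v = 2 * u
        b = dc.nuclei_equivalents(u, v, np.array([3.0]))
        np.testing.assert_allclose(b, [6.0])

    def test_total_preserving_normalization_keeps_a(self):
        u = np.array([[1.0], [3.0]])
        v = np.array([[2.0], [2.0]])  # same total
        np.testing.assert_allclose(dc.nuclei_equivalents(u, v, np.array([5.0])), [5.0])


class TestFactorizeB:
    def test_exact_product_recovered(self):
        c = np.array([1.0, 2.0, 0.5])
        d = np.array([1.0, 3.0])
        b = np.outer(c, d)
        c_hat, d_hat = dc.factorize_b(b)
        np.testing.assert_allclose(c_hat, c, rtol=1e-9)
        np.testing.assert_allclose(d_hat, d, rtol=1e-9)

    def test_all_ones(self):
        c_hat, d_hat = dc.factorize_b(np.ones((3, 4)))
        np.testing.assert_allclose(c_hat, 1.0)
        np.testing.assert_allclose(d_hat, 1.0)

    def test_ploidy_flagged_type_halved(self):
        b = np.ones((2, 2))
        c_hat, _ = dc.factorize_b(b, ploidy_flags=np.array([True, False]))
        np.testing.assert_allclose(c_hat, [0.5, 1.0])

    def test_unobserved_type_rejected(self):
        b = np.ones((2, 2))
        b[1, :] = np.nan
        with pytest.raises(ValidationError):
            dc.factorize_b(b)


class TestMarkerSelection:
    def test_orthogonal_signatures_near_unit_condition(self, rng):
        P, K, S = 90, 3, 4
        v = np.full((P, K, S), 0.01)
        for j in range(K):
            v[j * 30 : (j + 1) * 30, j, :] = 1.0 + rng.normal(0, 0.01, (30, S))
        sel = dc.select_marker_peaks(v, grid=(10, 20, 30))
        W = v.mean(axis=2)[sel]
        assert np.linalg.cond(W) < 2.0

    def test_identical_profiles_not_identifiable(self, rng):
        base = rng.random((50, 1, 4))
        v = np.tile(base, (1, 3, 1))
        with pytest.raises(ValidationError, match="identifiab"):
            dc.select_marker_peaks(v, grid=(10, 20))


class TestReference:
    def test_identical_replicates_zero_variance(self, rng):
        v = np.tile(rng.random((20, 3, 1)), (1, 1, 4))
        ref = dc.build_reference(v, np.arange(20), np.ones(3), np.ones(4),
                                 np.zeros(20))
        np.testing.assert_allclose(ref.e2, 0.0)

    def test_two_sample_variance_example(self):
        v = np.zeros((1, 1, 2))
        v[0, 0, :] = [0.0, 2.0]
        ref = dc.build_reference(v, np.array([0]), np.ones(1), np.ones(2),
                                 np.zeros(1))
        np.testing.assert_allclose(ref.e2, [2.0])  # sample variance, ddof=1

    def test_matches_bruteforce_mean_and_variance(self, rng):
        v = rng.random((15, 3, 4))
        sel = np.arange(15)
        ref = dc.build_reference(v, sel, np.ones(3), np.ones(4), np.zeros(15))
        for i in range(15):
            for j in range(3):
                assert abs(ref.W[i, j] - v[i, j].mean()) < 1e-12
            e2 = np.mean([np.var(v[i, j], ddof=1) for j in range(3)])
            assert abs(ref.e2[i] - e2) < 1e-12
        lo, hi = np.percentile(ref.e2, 25) ** 2 / np.percentile(ref.e2, 50), \
            np.percentile(ref.e2, 75) ** 2 / np.percentile(ref.e2, 50)
        assert (ref.e2_capped >= lo - 1e-12).all() and (ref.e2_capped <= hi + 1e-12).all()


class TestMixtureSynthesis:
    def _ref(self, W, c):
        return dc.DeconvolutionReference(
            peaks=np.arange(W.shape[0]), W=W, e2=np.zeros(W.shape[0]),
            e2_capped=np.zeros(W.shape[0]), c=c, d=np.ones(1),
            quantile_ref=np.zeros(W.shape[0]))

    def test_single_type(self):
        W = np.array([[2.0], [4.0]])
        ref = self._ref(W, np.array([2.0]))
        np.testing.assert_allclose(dc.synthesize_mixture(ref, np.array([7.0])),
                                   W[:, 0] / 2.0)

    def test_equal_mixture(self):
        W = np.array([[2.0, 4.0], [0.0, 6.0]])
        ref = self._ref(W, np.ones(2))
        np.testing.assert_allclose(dc.synthesize_mixture(ref, np.array([5.0, 5.0])),
                                   W.mean(axis=1))

    def test_three_type_hand_computed(self):
        W = np.array([[1.0, 2.0, 3.0]])
        ref = self._ref(W, np.array([1.0, 2.0, 4.0]))
        a = np.array([1.0, 1.0, 2.0])
        # x = 0.25*1/1 + 0.25*2/2 + 0.5*3/4 = 0.25 + 0.25 + 0.375
        np.testing.assert_allclose(dc.synthesize_mixture(ref, a), [0.875])


class TestPlatformCorrection:
    def test_identity_when_matched(self, rng):
        x = rng.random((30, 3)) + 0.1
        np.testing.assert_allclose(dc.platform_correction(x, x), 1.0)

    def test_geometric_mean_of_ratios(self):
        x = np.ones((9, 2))
        y = np.ones((9, 2)) * 2.0
        y[0] = [1.0, 4.0]  # geometric mean 2
        f = dc.platform_correction(x, y)
        np.testing.assert_allclose(f, 2.0)

    def test_planted_lognormal_factors_recovered(self):
        """log f-hat correlates strongly with the planted log platform
        factors across peaks (5 matched samples, sigma 0.3)."""
        rng = np.random.default_rng(3)
        P, S = 1000, 5
        f_true = np.exp(rng.normal(0, 0.3, P))
        x = rng.random((P, S)) + 0.5
        y = f_true[:, None] * x * np.exp(rng.normal(0, 0.05, (P, S)))
        f_hat = dc.platform_correction(x, y)
        r = np.corrcoef(np.log(f_hat), np.log(f_true))[0, 1]
        assert r >= 0.9


class TestDeconvolve:
    def _noise_free_ref(self, seed=0, K=4, P=200):
        rng = np.random.default_rng(seed)
        W = rng.random((P, K)) + 0.05
        return dc.DeconvolutionReference(
            peaks=np.arange(P), W=W, e2=np.zeros(P), e2_capped=np.zeros(P),
            c=np.ones(K), d=np.ones(1), quantile_ref=np.zeros(P))

    def test_exact_linear_recovery(self):
        ref = self._noise_free_ref()
        theta = np.array([0.4, 0.0, 0.35, 0.25])
        y = ref.W @ theta
        est = dc.deconvolve(y, ref, prenormalized=True)
        np.testing.assert_allclose(est.composition, theta, atol=1e-6)

    def test_pure_type_gives_unit_vector(self):
        ref = self._noise_free_ref()
        est = dc.deconvolve(ref.W[:, 2] * 3.7, ref, prenormalized=True)
        np.testing.assert_allclose(est.composition, [0, 0, 1, 0], atol=1e-6)

    def test_scale_equivariance_via_quantile_normalization(self):
        """Multiplying a raw bulk vector by a constant leaves the inferred
        composition unchanged (quantile normalization makes it scale-free)."""
        rng = np.random.default_rng(1)
        ref = self._noise_free_ref(seed=1)
        ref.quantile_ref = np.sort(rng.random(200))
        y = rng.poisson(1000 * (ref.W @ np.array([0.3, 0.3, 0.2, 0.2]))).astype(float)
        est1 = dc.deconvolve(y, ref)
        est2 = dc.deconvolve(7.0 * y, ref)
        np.testing.assert_allclose(est1.composition, est2.composition, atol=1e-12)

    def test_composition_on_simplex(self):
        rng = np.random.default_rng(2)
        ref = self._noise_free_ref(seed=2)
        y = ref.W @ np.array([0.5, 0.2, 0.2, 0.1]) + rng.normal(0, 0.05, 200)
        est = dc.deconvolve(y, ref, prenormalized=True)
        assert (est.composition >= 0).all()
        np.testing.assert_allclose(est.composition.sum(), 1.0, atol=1e-9)

    def test_nnls_option_agrees_in_easy_case(self):
        ref = self._noise_free_ref()
        y = ref.W @ np.array([0.4, 0.1, 0.3, 0.2])
        a = dc.deconvolve(y, ref, prenormalized=True, method="huber")
        b = dc.deconvolve(y, ref, prenormalized=True, method="nnls")
        np.testing.assert_allclose(a.composition, b.composition, atol=1e-6)


class TestEndToEnd:
    def test_noise_free_pipeline_recovers_exactly(self):
        """Noise-free counts, unit platform factors: the full reference +
        deconvolution chain recovers the planted proportions to 1e-6."""
        cfg = SyntheticConfig(seed=5, platform_sd=0.0)
        u, a, y, truth = generate_mixture_experiment(cfg, noise_free=True)
        ref = dc.build_pipeline_reference(u, a, truth.ploidy_flags)
        errs = []
        for k in range(y.shape[1]):
            est = dc.deconvolve(y[:, k] / y[:, k].sum(), ref, prenormalized=True)
            errs.append(est.composition - truth.mixture_proportions[k])
        assert np.abs(np.array(errs)).max() <= 1e-6

    def test_nuclei_bookkeeping_on_one_nucleus_scale(self):
        """For a synthetic bulk scaled to one nucleus, sum_j c_j theta_j is
        about 1 (within 10% under default noise)."""
        cfg = SyntheticConfig(seed=6)
        u, a, y, truth = generate_mixture_experiment(cfg)
        ref = dc.build_pipeline_reference(u, a, truth.ploidy_flags)
        x0 = dc.synthesize_mixture(ref, a[:, 0])
        est = dc.deconvolve(x0, ref, prenormalized=True)
        assert abs(est.diagnostics["c_theta_total"] - 1.0) < 0.1


class TestCompareCompositions:
    def test_bonferroni_threshold(self):
        rng = np.random.default_rng(0)
        comp = pd.DataFrame(rng.random((16, 7)),
                            columns=[f"t{j}" for j in range(7)])
        conditions = np.repeat(["normal", "hfd4", "hfd8", "washout"], 4)
        res = dc.compare_compositions(comp, conditions, "normal")
        np.testing.assert_allclose(res.attrs["threshold"], 0.05 / 21)
        assert abs(res.attrs["threshold"] - 0.0023810) < 1e-6

    def test_identical_compositions_no_flags(self):
        comp = pd.DataFrame(np.tile([0.5, 0.5], (12, 1)), columns=["a", "b"])
        conditions = np.repeat(["x", "y", "z"], 4)
        res = dc.compare_compositions(comp, conditions, "x")
        assert not res["significant"].any()

    def test_planted_shift_detected_with_high_power(self):
        """+0.2 shift in one cell type, n = 4 per group, noise SD 0.02:
        flagged in >= 95% of 100 simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            base = np.full((16, 7), 1 / 7)
            comp = base + rng.normal(0, 0.02, base.shape)
            conditions = np.repeat(["ref", "c1", "c2", "c3"], 4)
            comp[4:8, 0] += 0.2  # cell type 0 shifted under c1
            res = dc.compare_compositions(pd.DataFrame(comp), conditions, "ref")
            row = res[(res.cell_type == 0) & (res.condition == "c1")]
            hits += int(row["significant"].iloc[0])
        assert hits >= 0.95 * n_sim

    def test_standard_error_of_validation(self):
        assert round(dc.composition_standard_error(0.035, 4), 3) == 0.018
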