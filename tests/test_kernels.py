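"""Kernel values against hand computations and brute-force oracles, plus the
centering / normalization / combination machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iokr import (
    FingerprintTable,
    GaussianParams,
    KernelMatrix,
    PPKParams,
    Spectrum,
    center_cross,
    center_train,
    gaussian_fp_kernel,
    gaussian_tanimoto_kernel,
    linear_fp_kernel,
    normalize,
    ppk,
    ppk_matrix,
    preprocess_cross,
    preprocess_train,
    select_gamma_by_entropy,
    tanimoto_kernel,
    unimkl_combine,
)


def spec(sid, mz, inten):
    return Spectrum(sid, sid, np.asarray(mz, float), np.asarray(inten, float))


def fp_table(vectors):
    ids = [f"m{i}" for i in range(len(vectors))]
    d = len(vectors[0])
    return ids, FingerprintTable(ids, d, {m: np.array(v, dtype=np.uint8)
                                          for m, v in zip(ids, vectors)})


def random_spectra(rng, n, n_peaks=6):
    return [
        spec(f"s{i}", np.sort(rng.uniform(50, 500, n_peaks)), rng.uniform(0.1, 1, n_peaks))
        for i in range(n)
    ]


class TestPPK:
    def test_single_identical_peak_closed_form(self):
        s = spec("a", [100.0], [1.0])
        p = PPKParams(0.7, 0.3)
        assert ppk(s, s, p) == pytest.approx(1.0 / (4 * np.pi * 0.7 * 0.3), rel=1e-12)

    def test_distant_peaks_vanish(self):
        a = spec("a", [100.0], [1.0])
        b = spec("b", [900.0], [1.0])
        assert ppk(a, b, PPKParams(0.01, 1.0)) == pytest.approx(0.0, abs=1e-300)

    def test_brute_force_double_sum(self):
        a = spec("a", [100.0, 101.5], [0.2, 1.0])
        b = spec("b", [99.0, 100.5, 103.0], [0.5, 1.0, 0.1])
        p = PPKParams(1.0, 1.0)
        # independent oracle: explicit 6-term double sum on max-rescaled intensities
        ia = np.array([0.2, 1.0])
        ib = np.array([0.5, 1.0, 0.1])
        expected = 0.0
        for ma, va in zip([100.0, 101.5], ia):
            for mb, vb in zip([99.0, 100.5, 103.0], ib):
                expected += np.exp(-((ma - mb) ** 2) / 4.0) * np.exp(-((va - vb) ** 2) / 4.0)
        expected /= 2 * 3 * 4 * np.pi
        assert ppk(a, b, p) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            PPKParams(0.0, 1.0)

    def test_matrix_elementwise_and_symmetry(self):
        rng = np.random.default_rng(3)
        rows = random_spectra(rng, 2)
        cols = random_spectra(rng, 3)
        p = PPKParams(0.5, 0.2)
        R = ppk_matrix(rows, cols, p)
        assert R.shape == (2, 3)
        for i, a in enumerate(rows):
            for j, b in enumerate(cols):
                assert R.values[i, j] == pytest.approx(ppk(a, b, p), rel=1e-12)
        S = ppk_matrix(rows, rows, p)
        np.testing.assert_allclose(S.values, S.values.T, atol=1e-12)


class TestFingerprintKernels:
    def test_linear_values(self):
        ids, t = fp_table([[1, 1, 0], [1, 0, 1], [0, 0, 0]])
        K = linear_fp_kernel(t, ids, ids).values
        assert K[0, 1] == 1.0 and K[0, 0] == 2.0 and K[0, 2] == 0.0

    def test_tanimoto_values(self):
        ids, t = fp_table([[1, 1, 0], [1, 0, 1], [0, 1, 0]])
        K = tanimoto_kernel(t, ids, ids).values
        assert K[0, 1] == pytest.approx(1 / 3)
        assert K[0, 0] == 1.0
        assert K[1, 2] == 0.0  # disjoint supports

    def test_tanimoto_all_zero_convention(self):
        ids, t = fp_table([[0, 0], [0, 0]])
        assert tanimoto_kernel(t, ids, ids).values[0, 1] == 1.0

    def test_gaussian_hamming_distance(self):
        ids, t = fp_table([[1, 1, 0, 0], [1, 0, 1, 0]])
        K = gaussian_fp_kernel(t, ids, ids, GaussianParams(0.5)).values
        assert K[0, 1] == pytest.approx(np.exp(-1.0))  # 2 differing bits, gamma 0.5
        assert K[0, 0] == 1.0

    def test_gaussian_monotone_in_gamma(self):
        ids, t = fp_table([[1, 0], [0, 1]])
        vals = [gaussian_fp_kernel(t, ids, ids, GaussianParams(g)).values[0, 1]
                for g in (0.1, 1.0, 10.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_gaussian_tanimoto_closed_form(self):
        # pair with k_tan = 1/3: distance^2 = 1 + 1 - 2/3 = 4/3
        ids, t = fp_table([[1, 1, 0], [1, 0, 1]])
        K = gaussian_tanimoto_kernel(t, ids, ids, GaussianParams(1.0)).values
        assert K[0, 1] == pytest.approx(np.exp(-4 / 3))
        assert K[0, 0] == 1.0

    @pytest.mark.parametrize("kernel", ["linear", "tanimoto", "gaussian", "gaussian-tanimoto"])
    def test_gram_matrices_psd(self, kernel):
        rng = np.random.default_rng(8)
        vectors = rng.integers(0, 2, size=(20, 32))
        vectors[vectors.sum(1) == 0, 0] = 1
        ids, t = fp_table(vectors.tolist())
        g = GaussianParams(0.1)
        K = {
            "linear": lambda: linear_fp_kernel(t, ids, ids),
            "tanimoto": lambda: tanimoto_kernel(t, ids, ids),
            "gaussian": lambda: gaussian_fp_kernel(t, ids, ids, g),
            "gaussian-tanimoto": lambda: gaussian_tanimoto_kernel(t, ids, ids, g),
        }[kernel]().values
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * np.trace(K)

    def test_ppk_gram_psd(self):
        rng = np.random.default_rng(9)
        spectra = random_spectra(rng, 20)
        K = ppk_matrix(spectra, spectra, PPKParams(0.5, 0.2)).values
        assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.trace(K)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1), min_size=6, max_size=6),
                    min_size=2, max_size=6))
    def test_tanimoto_range_and_symmetry(self, vectors):
        ids, t = fp_table(vectors)
        K = tanimoto_kernel(t, ids, ids).values
        assert np.all(K >= 0) and np.all(K <= 1)
        np.testing.assert_allclose(K, K.T, atol=1e-12)


class TestCentering:
    def test_single_point_collapses_to_zero(self):
        K = KernelMatrix(["a"], ["a"], np.array([[3.0]]))
        assert center_train(K).values[0, 0] == pytest.approx(0.0)

    def test_two_by_two_hand_case(self):
        K = KernelMatrix(["a", "b"], ["a", "b"], np.eye(2))
        Kc = center_train(K)
        np.testing.assert_allclose(Kc.values, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_row_sums_vanish(self):
        rng = np.random.default_rng(1)
        F = rng.normal(size=(50, 10))
        ids = [f"p{i}" for i in range(50)]
        Kc = center_train(KernelMatrix(ids, ids, F @ F.T))
        assert np.abs(Kc.values.sum(0)).max() < 1e-8
        assert np.abs(Kc.values.sum(1)).max() < 1e-8

    def test_double_centering_refused(self):
        K = KernelMatrix(["a", "b"], ["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="centered"):
            center_train(center_train(K))

    def test_cross_consistent_with_train(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(12, 5))
        ids = [f"p{i}" for i in range(12)]
        K = KernelMatrix(ids, ids, F @ F.T)
        Kc = center_train(K)
        cross = KernelMatrix(ids, ids, K.values.copy(), row_self=np.diag(K.values))
        Cc = center_cross(cross, K)
        np.testing.assert_allclose(Cc.values, Kc.values, atol=1e-10)
        np.testing.assert_allclose(Cc.row_self, np.diag(Kc.values), atol=1e-10)

    def test_cross_hand_expansion(self):
        train = KernelMatrix(["a", "b"], ["a", "b"], np.array([[2.0, 1.0], [1.0, 3.0]]))
        tx = KernelMatrix(["q"], ["a", "b"], np.array([[4.0, 5.0]]))
        out = center_cross(tx, train).values[0]
        grand = (2 + 1 + 1 + 3) / 4
        expected = [4 - 4.5 - 1.5 + grand, 5 - 4.5 - 2.0 + grand]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_cross_columns_need_not_sum_to_zero(self):
        # only train-side means enter the cross centering, so sums over the
        # test rows (columns of the cross matrix) are not driven to zero
        rng = np.random.default_rng(3)
        F = rng.normal(size=(8, 4))
        ids = [f"p{i}" for i in range(8)]
        K = KernelMatrix(ids, ids, F @ F.T)
        q = rng.normal(size=(2, 4))
        tx = KernelMatrix(["q1", "q2"], ids, q @ F.T)
        assert np.abs(center_cross(tx, K).values.sum(0)).max() > 1e-6


class TestNormalize:
    def test_rank_one_case(self):
        K = KernelMatrix(["a", "b"], ["a", "b"], np.array([[4.0, 2.0], [2.0, 1.0]]))
        Kn = normalize(K, np.array([4.0, 1.0]), np.array([4.0, 1.0]))
        np.testing.assert_allclose(Kn.values, np.ones((2, 2)), atol=1e-12)
        assert Kn.normalized

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        F = rng.normal(size=(6, 3))
        ids = [f"p{i}" for i in range(6)]
        Kn = normalize(KernelMatrix(ids, ids, F @ F.T))
        Kn2 = normalize(Kn)
        np.testing.assert_allclose(Kn2.values, Kn.values, atol=1e-12)
        np.testing.assert_allclose(Kn.values, Kn.values.T, atol=1e-12)
        assert np.abs(Kn.values).max() <= 1 + 1e-10

    def test_degenerate_self_value_names_id(self):
        K = KernelMatrix(["a", "b"], ["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="'b'"):
            normalize(K, np.array([1.0, 0.0]), np.array([1.0, 0.0]))


class TestUnimkl:
    def _cn(self, values, ids):
        return preprocess_train(KernelMatrix(ids, ids, values)).processed

    def test_entrywise_mean(self):
        ids = ["a", "b"]
        K1 = KernelMatrix(ids, ids, np.eye(2), centered=True, normalized=True)
        K2 = KernelMatrix(ids, ids, np.ones((2, 2)), centered=True, normalized=True)
        U = unimkl_combine([K1, K2])
        np.testing.assert_allclose(U.values, [[1.0, 0.5], [0.5, 1.0]])
        assert U.centered and not U.normalized

    def test_single_kernel_identity(self):
        ids = ["a", "b"]
        K = KernelMatrix(ids, ids, np.eye(2), centered=True, normalized=True)
        np.testing.assert_allclose(unimkl_combine([K]).values, K.values)

    def test_uncentered_inputs_refused(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError):
            unimkl_combine([KernelMatrix(ids, ids, np.eye(2))])

    def test_mean_of_psd_is_psd(self):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(20)]
        Ks = [self._cn((lambda F: F @ F.T)(rng.normal(size=(20, 6))), ids)
              for _ in range(3)]
        U = unimkl_combine(Ks)
        assert np.linalg.eigvalsh(U.values).min() >= -1e-8 * np.trace(U.values)


class TestGammaSelection:
    def test_single_grid_value(self):
        assert select_gamma_by_entropy(np.array([1.0, 2.0]), [0.3]).gamma == 0.3

    def test_tie_breaks_to_smaller_gamma(self):
        # one off-diagonal distance: every gamma puts its single value in one
        # bin, entropy 0 for all -> smallest gamma wins
        assert select_gamma_by_entropy(np.array([2.0]), [1.0, 0.1, 10.0]).gamma == 0.1

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        F = rng.integers(0, 2, size=(50, 32)).astype(float)
        diffs = (F[:, None, :] != F[None, :, :]).sum(2)
        d2 = diffs[np.triu_indices(50, k=1)].astype(float)
        grid = np.logspace(-3, 1, 9)
        chosen = select_gamma_by_entropy(d2, grid).gamma

        def entropy(g):
            counts, _ = np.histogram(np.exp(-g * d2), bins=100, range=(0, 1))
            p = counts[counts > 0] / counts.sum()
            return -(p * np.log(p)).sum()

        best = max(sorted(grid), key=lambda g: (entropy(g), -g))
        assert chosen == best

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError):
            select_gamma_by_entropy(np.zeros(10), [0.1, 1.0])


class TestPreprocessPipeline:
    def test_cross_row_self_is_unit(self):
        rng = np.random.default_rng(7)
        F = rng.normal(size=(10, 4))
        Q = rng.normal(size=(3, 4))
        ids = [f"p{i}" for i in range(10)]
        stats = preprocess_train(KernelMatrix(ids, ids, F @ F.T))
        cross = preprocess_cross(
            KernelMatrix(["q0", "q1", "q2"], ids, Q @ F.T),
            (Q**2).sum(1), stats,
        )
        assert cross.centered and cross.normalized
        np.testing.assert_allclose(cross.row_self, 1.0)
        # training rows passed through the cross pipeline reproduce the
        # processed training matrix
        cross_tr = preprocess_cross(
            KernelMatrix(ids, ids, F @ F.T), ((F**2).sum(1)), stats
        )
        np.testing.assert_allclose(cross_tr.values, stats.processed.values, atol=1e-10)
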