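"""Purity checking, component counting, and PARAFAC deconvolution."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from dadkit.io import Chromatogram, RunMeta
from dadkit.peaks import Peak
from dadkit.purity import (DeconvComponent, Spectrum, build_tensor,
                           check_purity, deconvolve, estimate_component_count,
                           parafac_nnls, pearson_similarity, spectrum_at)
from dadkit.simulate import make_spectrum


WL = np.arange(200.0, 401.0, 5.0)
T = np.arange(0.0, 0.4 + 1e-12, 0.002)


def gauss(t, c, s):
    return np.exp(-0.5 * ((t - c) / s) ** 2)


def slab_chrom(matrix):
    return Chromatogram(T[: matrix.shape[0]], WL, matrix, RunMeta(run_id="t"))


def rank1_chrom(height=100.0):
    a = height * gauss(T, 0.2, 0.02)
    s = make_spectrum([(254.0, 20.0, 1.0)], WL).values
    return slab_chrom(np.outer(a, s))


def two_component_chrom(sep_sigma=1.5, r_target=-0.06, height2=80.0, seed=0):
    from dadkit.simulate import make_correlated_spectrum
    s1 = make_spectrum([(230.0, 15.0, 1.0), (300.0, 25.0, 0.4)], WL)
    s2 = make_correlated_spectrum(s1, r_target, seed=seed)
    sigma = 0.02
    a1 = 100.0 * gauss(T, 0.2, sigma)
    a2 = height2 * gauss(T, 0.2 + sep_sigma * sigma, sigma)
    return slab_chrom(np.outer(a1, s1.values) + np.outer(a2, s2.values)), s1, s2


def full_window_peak(chrom):
    trace = chrom.absorbance.sum(axis=1)
    return Peak(run_id="t", apex_index=int(np.argmax(trace)), left_index=0,
                right_index=chrom.n_time - 1)


class TestSpectrumAt:
    def test_rank1_matches_spectrum(self):
        chrom = rank1_chrom()
        s_true = make_spectrum([(254.0, 20.0, 1.0)], WL).values
        got = spectrum_at(chrom, 100)
        np.testing.assert_allclose(got.values, s_true, atol=1e-9)

    def test_zero_row_errors(self):
        matrix = np.ones((20, WL.size))
        matrix[3] = 0.0
        with pytest.raises(ValueError):
            spectrum_at(slab_chrom(matrix), 3)

    def test_overlap_apex_prefers_own_spectrum(self):
        chrom, s1, s2 = two_component_chrom(sep_sigma=3.0)
        trace = chrom.absorbance.sum(axis=1)
        apex1 = int(np.argmax(trace[:110]))
        got = spectrum_at(chrom, apex1)
        assert pearson_similarity(got, s1) > pearson_similarity(got, s2)


class TestPearson:
    def test_self_correlation(self):
        s = make_spectrum([(254.0, 20.0, 1.0)], WL)
        assert pearson_similarity(s, s) == pytest.approx(1.0)

    def test_mean_centered_negation(self):
        v = np.linspace(0.1, 1.0, WL.size)
        s1 = Spectrum(WL, v)
        s2 = Spectrum(WL, v.max() + v.min() - v)  # reflected about the mean
        assert pearson_similarity(s1, s2) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        s1 = Spectrum(WL, np.ones(WL.size))
        s2 = make_spectrum([(254.0, 20.0, 1.0)], WL)
        with pytest.raises(ValueError):
            pearson_similarity(s1, s2)

    def test_grid_mismatch_errors(self):
        s1 = make_spectrum([(254.0, 20.0, 1.0)], WL)
        s2 = make_spectrum([(254.0, 20.0, 1.0)], WL[:-1])
        with pytest.raises(ValueError):
            pearson_similarity(s1, s2)


class TestCheckPurity:
    def test_noiseless_rank1_is_pure(self):
        chrom = rank1_chrom()
        report = check_purity(chrom, full_window_peak(chrom))
        assert report.pure
        assert report.min_correlation == pytest.approx(1.0, abs=1e-9)
        assert report.pca_explained_1 == pytest.approx(1.0, abs=1e-9)

    def test_dissimilar_coelution_is_impure(self):
        chrom, _, _ = two_component_chrom(sep_sigma=1.5, r_target=-0.06)
        report = check_purity(chrom, full_window_peak(chrom))
        assert not report.pure

    def test_identical_spectra_coelution_is_pure_false_positive(self):
        # indistinguishable spectra cannot be resolved from the data alone
        s = make_spectrum([(254.0, 20.0, 1.0)], WL).values
        a = 100.0 * gauss(T, 0.2, 0.02) + 80.0 * gauss(T, 0.21, 0.02)
        chrom = slab_chrom(np.outer(a, s))
        report = check_purity(chrom, full_window_peak(chrom))
        assert report.pure

    def test_narrow_window_errors(self):
        chrom = rank1_chrom()
        peak = Peak(run_id="t", apex_index=2, left_index=0, right_index=3)
        with pytest.raises(ValueError):
            check_purity(chrom, peak)


class TestComponentCount:
    def test_rank1(self):
        assert estimate_component_count(rank1_chrom().absorbance) == 1

    def test_rank2_distinct(self):
        chrom, _, _ = two_component_chrom(sep_sigma=2.0)
        assert estimate_component_count(chrom.absorbance) == 2

    def test_minor_component_below_threshold(self):
        # second component tuned to < 0.5% of centered variance
        chrom, s1, s2 = two_component_chrom(sep_sigma=2.0, height2=1.0)
        slab = chrom.absorbance
        centered = slab - slab.mean(axis=0)
        evals = np.linalg.svd(centered, compute_uv=False) ** 2
        assert evals[1] / evals.sum() < 0.005  # oracle: eigenvalue spectrum
        assert estimate_component_count(slab) == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_component_count(np.empty((0, 5)))


class TestBuildTensor:
    def test_impure_only(self):
        slab = rank1_chrom().absorbance
        tensor, shifts = build_tensor(slab, [])
        assert tensor.shape == slab.shape + (1,)
        assert shifts == [0]

    def test_identical_reference_zero_shift(self):
        slab = rank1_chrom().absorbance
        tensor, shifts = build_tensor(slab, [slab.copy()])
        assert shifts == [0, 0]
        np.testing.assert_allclose(tensor[..., 1], slab)

    def test_shifted_reference_recovered(self):
        a = 100.0 * gauss(T, 0.2, 0.02)
        s = make_spectrum([(254.0, 20.0, 1.0)], WL).values
        slab = np.outer(a, s)
        shifted = np.outer(np.roll(a, 5), s)  # reference apex 5 points late
        # oracle: brute-force cross-correlation over all lags
        best = max(range(-20, 21),
                   key=lambda lag: np.dot(np.roll(shifted.sum(axis=1), lag),
                                          slab.sum(axis=1)))
        tensor, shifts = build_tensor(slab, [shifted])
        assert shifts[1] == -5 == best
        np.testing.assert_allclose(tensor[..., 1], slab, atol=1e-9)


def congruence(u, v):
    return abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))


def match_components(est, truth):
    """Hungarian matching on spectral congruence; returns column permutation."""
    k = truth.shape[1]
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = -congruence(est[:, i], truth[:, j])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows
    return perm


def random_cp_tensor(k, shape=(40, 30, 3), seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, shape[0])
    A = np.stack([gauss(t, 0.2 + 0.25 * i, 0.06) for i in range(k)], axis=1)
    B = rng.uniform(0, 1, size=(shape[1], k)) ** 2
    # keep spectra distinguishable (pairwise r < 0.9)
    C = rng.uniform(0.5, 2.0, size=(shape[2], k))
    X = np.einsum("ir,jr,kr->ijk", A, B, C)
    return X, (A, B, C)


class TestParafac:
    @pytest.mark.parametrize("k", [2, 3])
    def test_recovers_known_factors(self, k):
        X, (A, B, C) = random_cp_tensor(k, seed=k)
        res = parafac_nnls(X, k, restarts=5, seed=1)
        perm = match_components(res.spectra, B)
        for est, truth in ((res.elutions, A), (res.spectra, B),
                           (res.loadings, C)):
            for j in range(k):
                assert congruence(est[:, perm[j]], truth[:, j]) >= 0.999

    def test_rank1_exact(self):
        X, _ = random_cp_tensor(1, seed=9)
        res = parafac_nnls(X, 1, restarts=2)
        assert res.relative_loss < 1e-10

    def test_loss_non_increasing(self):
        X, _ = random_cp_tensor(2, seed=3)
        res = parafac_nnls(X, 2, restarts=3, seed=5)
        diffs = np.diff(res.loss_history)
        assert np.all(diffs <= 1e-9 * max(res.loss_history[0], 1.0))

    def test_k_exceeding_time_or_wavelength_dim_errors(self):
        X, _ = random_cp_tensor(2, shape=(4, 3, 2))
        with pytest.raises(ValueError):
            parafac_nnls(X, 4)

    def test_single_slab_rank2_allowed(self):
        X, (A, B, C) = random_cp_tensor(2, shape=(40, 30, 1), seed=4)
        res = parafac_nnls(X, 2, restarts=4, seed=2)
        assert res.relative_loss < 1e-6

    def test_nonfinite_rejected(self):
        X = np.full((4, 4, 2), np.nan)
        with pytest.raises(ValueError):
            parafac_nnls(X, 1)


class _FakeEntry:
    def __init__(self, spectrum, ref_time, chrom):
        self.spectrum = spectrum
        self.ref_time = ref_time
        self.reference_chrom = chrom


class _FakeLibrary:
    def __init__(self, entries):
        self.entries = entries


class TestDeconvolve:
    def make_case(self, ratio=1.0, r_target=-0.06, sep_sigma=1.5):
        chrom, s1, s2 = two_component_chrom(sep_sigma=sep_sigma,
                                            r_target=r_target,
                                            height2=100.0 * ratio)
        sigma = 0.02
        a_main = 100.0 * gauss(T, 0.2, sigma)
        ref = slab_chrom(np.outer(a_main, s1.values))
        library = _FakeLibrary({"main": _FakeEntry(s1, 0.2, ref)})
        dt = float(T[1] - T[0])
        true_main_area = float(np.trapezoid(a_main * s1.values.sum(), dx=dt))
        return chrom, library, true_main_area

    def test_main_compound_recovered_within_paper_q3(self):
        chrom, library, true_area = self.make_case(ratio=1.0)
        peak = full_window_peak(chrom)
        comps = deconvolve(chrom, peak, library)
        main = [c for c in comps if c.assignment == "main"]
        assert len(main) == 1
        assert abs(main[0].integral - true_area) / true_area < 0.06

    def test_unmatched_components_stay_unknown(self):
        chrom, _, _ = self.make_case()
        peak = full_window_peak(chrom)
        comps = deconvolve(chrom, peak, _FakeLibrary({}))
        assert len(comps) == 2
        assert all(c.assignment.startswith("component_") for c in comps)

    def test_component_integrals_conserve_window_area(self):
        chrom, library, _ = self.make_case(ratio=0.7)
        peak = full_window_peak(chrom)
        comps = deconvolve(chrom, peak, library)
        dt = chrom.dt
        window_area = float(np.trapezoid(chrom.absorbance.sum(axis=1), dx=dt))
        total = sum(c.integral for c in comps)
        assert abs(total - window_area) / window_area < 0.01
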