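"""K-selection: eigengap, dip statistic, multimodality gap, kernel tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectrumclust import (
    DipSeries,
    DropSearchParams,
    KernelParams,
    ParameterError,
    dip_statistic,
    eigengap_k,
    last_substantial_drop,
    multimodality_diffs,
    spectrum_cluster,
    tune_kernel,
)
from spectrumclust.io import ari
from spectrumclust.kernels import adaptive_kernel, cnn_counts, local_scale, pairwise_distances
from spectrumclust.kernels import _kernel_matrix
from spectrumclust.spectral import eigendecompose, graph_laplacian
from spectrumclust.types import EigenSystem

from oracles import dip_lp, drop_replay, eigengap_scan


class TestEigengap:
    def test_five_component_spectrum(self):
        ev = np.array([1, 1, 1, 1, 1, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005])
        assert eigengap_k(ev, maxK=10).k == 5

    def test_three_clique_spectrum(self):
        ev = np.array([1, 1, 1, 0.1, 0.05])
        assert eigengap_k(ev, maxK=4).k == 3

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            ev = np.sort(rng.uniform(size=15))[::-1]
            assert eigengap_k(ev, maxK=10).k == eigengap_scan(ev, 10)

    def test_tie_breaks_toward_smaller_k(self):
        ev = np.array([1.0, 1.0, 0.5, 0.5, 0.0, 0.0])
        # gaps: k=2 -> 0.5, k=3 -> 0, k=4 -> 0.5: tie between 2 and 4
        assert eigengap_k(ev, maxK=5).k == 2

    def test_too_few_eigenvalues(self):
        with pytest.raises(ParameterError):
            eigengap_k(np.ones(5), maxK=10)


class TestDipStatistic:
    def test_two_point_masses_reach_upper_bound(self):
        assert dip_statistic(np.array([0.0, 0.0, 1.0, 1.0])) == pytest.approx(0.25)

    def test_evenly_spaced_sample_attains_lower_bound(self):
        x = np.arange(1.0, 9.0)  # n = 8
        assert dip_statistic(x) == pytest.approx(1 / 16)

    def test_bimodal_exceeds_unimodal(self, rng):
        uni = rng.normal(size=60)
        bi = np.concatenate([rng.normal(-4, 0.2, 30), rng.normal(4, 0.2, 30)])
        assert dip_statistic(bi) > dip_statistic(uni)

    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.1, 0.4, 0.45, 0.5, 0.9, 1.3, 2.0, 2.1])
        assert dip_statistic(a * x + b) == pytest.approx(dip_statistic(x), abs=1e-12)

    def test_constant_sample_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert dip_statistic(np.ones(10)) == 0.0

    def test_short_sample_rejected(self):
        with pytest.raises(ParameterError):
            dip_statistic(np.array([1.0, 2.0, 3.0]))

    @pytest.mark.parametrize("kind", ["normal", "bimodal", "uniform", "tied"])
    def test_agrees_with_unimodal_cdf_lp_oracle(self, rng, kind):
        for trial in range(6):
            n = int(rng.integers(10, 61))
            if kind == "normal":
                x = rng.normal(size=n)
            elif kind == "bimodal":
                x = np.concatenate(
                    [rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n - n // 2)]
                )
            elif kind == "uniform":
                x = rng.uniform(size=n)
            else:
                x = np.round(rng.normal(size=n), 1)
                if x.max() == x.min():
                    continue
            assert dip_statistic(x) == pytest.approx(dip_lp(x), abs=1e-9)

    def test_oracle_agreement_at_n100(self, rng):
        x = rng.normal(size=100)
        assert dip_statistic(x) == pytest.approx(dip_lp(x), abs=1e-9)


class TestMultimodalityDiffs:
    def test_five_blob_largest_drop_at_five(self):
        from spectrumclust import gaussian_blobs
        from spectrumclust.fusion import fuse_graphs, symmetrize
        from spectrumclust.types import FusionParams

        truth = gaussian_blobs(K=5, n_per=100, dims=2, separation=12, seed=0)
        D = pairwise_distances(truth.X)
        g = adaptive_kernel(D, KernelParams(), sample_ids=truth.X.sample_ids)
        fused = fuse_graphs([g], FusionParams())
        es = eigendecompose(graph_laplacian(symmetrize(fused.values)))
        series = multimodality_diffs(es, maxK=10)
        assert int(np.argmin(series.diffs)) + 1 == 5

    def test_duplicated_eigenvectors_give_zero_diff(self, rng):
        V = rng.normal(size=(30, 5))
        V[:, 3] = V[:, 2]
        es = EigenSystem(np.linspace(1, 0.5, 5), V)
        series = multimodality_diffs(es, maxK=4)
        assert series.diffs[2] == pytest.approx(0.0)

    def test_diffs_equal_elementwise_subtraction(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(40, 8)))
        es = EigenSystem(np.linspace(1, 0, 8), Q)
        series = multimodality_diffs(es, maxK=8)
        dips = [dip_statistic(Q[:, j]) for j in range(8)]
        np.testing.assert_allclose(series.diffs, np.diff(dips), atol=1e-12)
        assert series.dips.size == 8 and series.diffs.size == 7


class TestLastSubstantialDrop:
    def run(self, diffs, cmax=7, f=2.0):
        series = DipSeries(dips=np.zeros(len(diffs) + 1), diffs=np.array(diffs))
        return last_substantial_drop(series, DropSearchParams(cmax=cmax, f=f))

    def test_single_large_drop_at_five(self):
        d = [0.0, -0.01, 0.0, 0.0, -0.2, 0.0, 0.0, 0.0, 0.0]
        assert self.run(d).k == 5

    def test_default_drop_at_two_retained(self):
        d = [0.0, -0.3, -0.01, -0.02, 0.0, -0.01, 0.0, 0.0, 0.0]
        assert self.run(d).k == 2

    def test_later_drop_replaces_when_f_fold_larger(self):
        d = [0.0, -0.01, -0.1, 0.0, 0.0, -0.25, 0.0, 0.0, 0.0]
        assert self.run(d).k == 6

    def test_search_abandoned_beyond_cmax(self):
        # huge drop 8 positions past the stored one is out of the window
        d = [0.0, -0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -5.0]
        assert self.run(d, cmax=7).k == 2

    def test_all_non_negative_defaults_to_two_with_warning(self):
        with pytest.warns(UserWarning):
            assert self.run([0.0, 0.01, 0.02, 0.0, 0.01]).k == 2

    def test_matches_rule_replay_oracle(self, rng):
        for _ in range(200):
            d = np.round(rng.normal(0, 0.1, size=int(rng.integers(4, 25))), 3)
            got = self.run(d).k
            expected = drop_replay(d, cmax=7, f=2.0)
            assert got == expected


class TestTuneKernel:
    def test_matches_exhaustive_loop(self, blobs3):
        kp, diag = tune_kernel(blobs3.X, maxK=8)
        D = pairwise_distances(blobs3.X)
        cnn = cnn_counts(D, 7)
        best_p, best = None, np.inf
        for P in range(1, 11):
            A = _kernel_matrix(D, local_scale(D, P), cnn)
            es = eigendecompose(graph_laplacian(A))
            series = multimodality_diffs(es, maxK=8)
            score = series.diffs.min()
            if score < best:
                best_p, best = P, score
        assert kp.P == best_p
        np.testing.assert_allclose(np.sort(diag.min_dip_diff)[0], best, atol=1e-12)

    def test_single_blob_does_not_crash(self):
        from spectrumclust import gaussian_blobs

        truth = gaussian_blobs(K=1, n_per=40, dims=3, seed=2)
        kp, _ = tune_kernel(truth.X, maxK=6)
        assert 1 <= kp.P <= 10

    def test_tuning_separates_spirals(self):
        from spectrumclust import preset

        truth = preset("spirals")
        tuned = spectrum_cluster(truth.X, method="dip", tune=True, seed=0)
        untuned = spectrum_cluster(truth.X, method="dip", seed=0)
        assert ari(tuned.labels, truth.labels) == 1.0
        assert ari(untuned.labels, truth.labels) < 1.0
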