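"""Count spectrum, zero-truncated Poisson mixture EM and genome size."""

import numpy as np
import pytest
from scipy.stats import poisson

from conftest import make_readset
from preqc import KmerIndex
from preqc.count_model import (
    CountHistogram,
    estimate_genome_size,
    fit_mixture_em,
    initialize_lambda,
    sample_count_histogram,
    ztp_pmf,
)


def _ztp_draws(lam, n, rng):
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n,))
    c = rng.poisson(lam)
    while (c == 0).any():
        z = c == 0
        c[z] = rng.poisson(lam[z])
    return c


def _hist_from_draws(draws, k=31):
    v, f = np.unique(draws, return_counts=True)
    return CountHistogram(k, {int(a): int(b) for a, b in zip(v, f)})


# -- histogram sampling ----------------------------------------------------


def test_histogram_single_read():
    idx = KmerIndex(make_readset(["ACGTA"]), [5])
    h = sample_count_histogram(idx, 5, 10, np.random.default_rng(0))
    assert h.counts == {1: 1}


def test_histogram_repeated_read():
    idx = KmerIndex(make_readset(["ACGTAGGC"] * 7), [8])
    h = sample_count_histogram(idx, 8, 100, np.random.default_rng(0))
    # each of the 7 sampled reads contributes its single k-mer of count 7
    assert h.counts == {7: 7}


def test_histogram_deterministic_under_seed(small_index):
    h1 = sample_count_histogram(small_index, 21, 500, np.random.default_rng(3))
    h2 = sample_count_histogram(small_index, 21, 500, np.random.default_rng(3))
    assert h1.counts == h2.counts


def test_histogram_rejects_count_zero():
    with pytest.raises(ValueError):
        CountHistogram(21, {0: 5})


# -- zero-truncated Poisson ------------------------------------------------


def test_ztp_normalizes():
    for lam in (0.1, 1.0, 5.0, 40.0, 100.0):
        c = np.arange(1, 2000)
        assert abs(ztp_pmf(c, lam).sum() - 1.0) < 1e-10


def test_ztp_matches_closed_form():
    # Poisson(2; 1) / (1 - e^-1), cross-checked against a normalized table
    # exact: (e^-1 / 2) / (1 - e^-1) = 0.29098835...
    assert abs(ztp_pmf(2, 1.0) - 0.2909884) < 1e-6
    table = poisson.pmf(np.arange(1, 200), 1.0)
    assert abs(ztp_pmf(2, 1.0) - table[1] / table.sum()) < 1e-12


def test_ztp_agrees_with_poisson_ratio():
    for lam in np.geomspace(0.1, 100, 12):
        c = np.arange(1, 50)
        expected = poisson.pmf(c, lam) / (1 - np.exp(-lam))
        assert np.allclose(ztp_pmf(c, lam), expected, atol=1e-12)


def test_ztp_limit_and_errors():
    assert abs(ztp_pmf(900, 900.0) - poisson.pmf(900, 900.0)) < 1e-12
    with pytest.raises(ValueError, match="truncated"):
        ztp_pmf(0, 1.0)
    with pytest.raises(ValueError):
        ztp_pmf(1, -1.0)


# -- lambda initialization -------------------------------------------------


def test_lambda_init_unimodal():
    rng = np.random.default_rng(1)
    h = _hist_from_draws(_ztp_draws(30.0, 100_000, rng))
    assert 28 <= initialize_lambda(h, size_biased=False) <= 32


def test_lambda_init_bimodal_with_error_peak():
    rng = np.random.default_rng(2)
    draws = np.concatenate(
        [_ztp_draws(1.0, 60_000, rng), _ztp_draws(30.0, 100_000, rng)]
    )
    assert 28 <= initialize_lambda(_hist_from_draws(draws), size_biased=False) <= 32


def test_lambda_init_monotone_fallback_warns():
    rng = np.random.default_rng(3)
    h = _hist_from_draws(_ztp_draws(0.5, 50_000, rng))
    with pytest.warns(RuntimeWarning, match="error-dominated"):
        initialize_lambda(h)


def test_lambda_init_empty_errors():
    with pytest.raises(ValueError):
        initialize_lambda(CountHistogram(31, {}))


# -- EM fit ----------------------------------------------------------------


def test_em_self_consistency():
    """Data from the model itself: weights and lambda_e recovered."""
    rng = np.random.default_rng(4)
    lam, lam_e = 40.0, 1.2
    w = np.array([0.3, 0.2, 0.45, 0.05, 0, 0, 0, 0, 0, 0])
    rates = np.concatenate(([lam_e], [lam / 2, lam], np.arange(2, 9) * lam))
    comp = rng.choice(10, size=1_000_000, p=w)
    hist = _hist_from_draws(_ztp_draws(rates[comp], 1_000_000, rng))
    m = fit_mixture_em(hist)
    assert np.abs(m.weights - w).max() < 0.02
    assert abs(m.lambda_e - lam_e) < 0.2
    assert np.all(np.diff(m.log_likelihood_trace) >= -1e-6)


def test_em_pure_homozygous():
    rng = np.random.default_rng(5)
    hist = _hist_from_draws(_ztp_draws(35.0, 200_000, rng))
    m = fit_mixture_em(hist)
    assert m.weights[2] >= 0.95


def test_em_loglik_monotone_on_varied_fixtures(small_index):
    h = sample_count_histogram(small_index, 21, 2000, np.random.default_rng(6))
    m = fit_mixture_em(h)
    assert np.all(np.diff(m.log_likelihood_trace) >= -1e-6)
    assert abs(m.weights.sum() - 1.0) < 1e-9
    assert np.all(m.weights >= 0)


def test_em_degenerate_single_count_warns():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        m = fit_mixture_em(CountHistogram(31, {7: 100}), lambda_init=7.0)
    assert np.isfinite(m.log_likelihood_trace[-1])


def test_em_rates_pinned_to_lambda():
    rng = np.random.default_rng(7)
    hist = _hist_from_draws(_ztp_draws(30.0, 50_000, rng))
    m = fit_mixture_em(hist, lambda_init=30.0)
    assert m.lam == 30.0
    expected = np.concatenate(([m.lambda_e], [15.0, 30.0], np.arange(2, 9) * 30.0))
    assert np.allclose(m.rates, expected)


# -- posteriors ------------------------------------------------------------


def test_posteriors_normalize_and_separate():
    rng = np.random.default_rng(8)
    w = np.array([0.3, 0.1, 0.5, 0.1, 0, 0, 0, 0, 0, 0])
    rates = np.concatenate(([1.0], [20.0, 40.0], np.arange(2, 9) * 40.0))
    comp = rng.choice(10, size=400_000, p=w)
    m = fit_mixture_em(
        _hist_from_draws(_ztp_draws(rates[comp], 400_000, rng)), lambda_init=40.0
    )
    post = m.posterior(np.arange(1, 201))
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
    assert m.posterior_homozygous(40) > 0.5
    assert m.posterior(np.array([1]))[0, 0] > 0.99  # c=1 is an error k-mer
    assert m.posterior_homozygous(1) < 0.01


# -- genome size -----------------------------------------------------------


def test_genome_size_arithmetic():
    from preqc.count_model import CountMixtureModel

    m = CountMixtureModel(
        lam=10.0, lambda_e=1.0,
        weights=np.array([0.3, 0.1, 0.6, 0, 0, 0, 0, 0, 0, 0.0]), k=31,
    )
    est = estimate_genome_size(m, 10_000, 100, 31)
    assert est.G == pytest.approx(49_000)
    m.weights[0] = 0.0
    est2 = estimate_genome_size(
        CountMixtureModel(lam=1.0, lambda_e=1.0, weights=m.weights, k=31),
        1000, 100, 31,
    )
    assert est2.G == pytest.approx(70_000)


def test_genome_size_rejects_bad_lambda():
    from preqc.count_model import CountMixtureModel

    m = CountMixtureModel(
        lam=0.0, lambda_e=1.0, weights=np.full(10, 0.1), k=31
    )
    with pytest.raises(ValueError):
        estimate_genome_size(m, 1000, 100)


def test_genome_size_end_to_end_small(small_reads):
    """Error-free 30X reads from 20 kb: recovery within 5%."""
    idx = KmerIndex(small_reads, [31])
    h = sample_count_histogram(idx, 31, 50_000, np.random.default_rng(9))
    m = fit_mixture_em(h)
    est = estimate_genome_size(m, len(small_reads), 100)
    assert abs(est.G - 20_000) / 20_000 < 0.05
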