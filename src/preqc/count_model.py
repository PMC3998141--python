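"""k-mer count spectrum: histogram sampling, zero-truncated Poisson mixture
EM, per-count posteriors and genome-size estimation.

The generative model for the count c of a sampled k-mer is a 10-component
mixture of zero-truncated Poissons. Component 0 (rate lambda_e, free) holds
k-mers containing sequencing errors; component 1 (rate lambda/2) heterozygous
k-mers; component 2 (rate lambda) homozygous k-mers; components 3..9 repeat
k-mers at rates 2*lambda .. 8*lambda, one per extra genomic copy. Only the
mixture weights w and lambda_e are free during EM — the genomic rates are
pinned to lambda, which ties every copy-number state to overall coverage.

Genome size follows from inverting the coverage identity
lambda = n (l - k + 1) / G, corrected by the error-component weight w0 for
the fraction of read k-mers that are artifacts:

    G = (1 - w0) * n * (l - k + 1) / lambda
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import poisson

logger = logging.getLogger(__name__)

HISTOGRAM_COUNT_CAP = 1000
N_COMPONENTS = 10


@dataclass
class CountHistogram:
    """N_c: number of sampled k-mer instances with occurrence count c."""

    k: int
    counts: dict[int, int]
    n_sampled_reads: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("count histogram has no support at c < 1")
        if any(f < 0 for f in self.counts.values()):
            raise ValueError("negative frequency in histogram")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.array(sorted(self.counts), dtype=np.int64)
        return c, np.array([self.counts[x] for x in c], dtype=np.float64)

    @property
    def n_kmers(self) -> int:
        return int(sum(self.counts.values()))


def sample_count_histogram(
    index, k: int, n_reads: int = 50_000, rng=None
) -> CountHistogram:
    """Histogram of count_rc over every k-mer of n_reads sampled reads.

    Counts above HISTOGRAM_COUNT_CAP are binned at the cap (the far tail is
    all repeat mass and would otherwise dominate EM cost). When fewer reads
    are available than requested, all reads are used once.
    """
    rng = np.random.default_rng(rng)
    if n_reads > index.n_reads:
        logger.info(
            "requested %d reads but only %d available; using all reads once",
            n_reads,
            index.n_reads,
        )
    sel = index.sample_read_indices(n_reads, rng)
    codes = index.selected_codes(sel)
    crc, _, _, valid, _ = index.window_count_rc(codes, k)
    crc = np.minimum(crc[valid], HISTOGRAM_COUNT_CAP)
    values, freqs = np.unique(crc, return_counts=True)
    return CountHistogram(
        k, {int(v): int(f) for v, f in zip(values, freqs)}, len(sel)
    )


def ztp_pmf(c, rate: float):
    """Zero-truncated Poisson pmf: Poisson(c; rate) / (1 - e^{-rate})."""
    return np.exp(ztp_logpmf(c, rate))


def ztp_logpmf(c, rate):
    c = np.asarray(c)
    if np.any(c < 1):
        raise ValueError("zero-truncated support starts at c = 1")
    rate = np.asarray(rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("rate must be positive")
    # log(1 - e^-rate), stable for both tiny and huge rates
    with np.errstate(divide="ignore"):
        log_norm = np.where(
            rate > 700, 0.0, np.log1p(-np.exp(-np.minimum(rate, 700)))
        )
    return poisson.logpmf(c, rate) - log_norm


def _ztp_mean_inverse(m: float) -> float:
    """Solve mu / (1 - e^-mu) = m for mu (ZTP maximum-likelihood update)."""
    if m <= 1.0 + 1e-9:
        return 1e-6
    f = lambda mu: mu / -np.expm1(-mu) - m
    return brentq(f, 1e-9, m, xtol=1e-10)


def initialize_lambda(hist: CountHistogram, size_biased: bool = True) -> float:
    """Initial homozygous mean count from the shape of the spectrum.

    Finds the first local minimum of N_c (the trough between the error peak
    and the genomic peaks), takes the mode above it, and refines it to the
    weighted mean count within +/- 2*sqrt(mode) of the mode. Falls back to
    the overall weighted mean (with a warning) when the histogram decreases
    monotonically, i.e. is error-dominated.

    Histograms built by sampling k-mer *instances* from reads are
    size-biased: a k-mer of count c is drawn with probability proportional
    to c, which makes homozygous instance counts distributed as
    1 + Poisson(lambda) rather than Poisson(lambda). With ``size_biased``
    (the default, correct for ``sample_count_histogram`` output) the peak
    mean is therefore shifted down by one.
    """
    if not hist.counts:
        raise ValueError("empty count histogram")
    cmax = max(hist.counts)
    dense = np.zeros(cmax + 2)
    for c, f in hist.counts.items():
        dense[c] = f
    # light smoothing so single-bin noise does not fake a trough
    sm = dense.copy()
    if cmax >= 3:
        sm[2:cmax] = (dense[1 : cmax - 1] + dense[2:cmax] + dense[3 : cmax + 1]) / 3.0
    trough = None
    for c in range(1, cmax):
        if sm[c] <= sm[c + 1]:
            trough = c
            break
    counts_arr, freqs = hist.arrays()
    shift = 1.0 if size_biased else 0.0
    if trough is None or trough >= cmax:
        warnings.warn(
            "count histogram decreases monotonically (error-dominated); "
            "falling back to the overall weighted mean for lambda",
            RuntimeWarning,
            stacklevel=2,
        )
        mean = float(np.average(counts_arr, weights=freqs))
        return max(mean - shift, 0.5 * mean)
    mode = trough + int(np.argmax(dense[trough : cmax + 1]))
    half = 2.0 * np.sqrt(mode)
    sel = (counts_arr >= mode - half) & (counts_arr <= mode + half)
    if not sel.any():  # pragma: no cover - mode always selects itself
        return max(float(mode) - shift, 0.5 * mode)
    mean = float(np.average(counts_arr[sel], weights=freqs[sel]))
    return max(mean - shift, 0.5 * mean)


@dataclass
class CountMixtureModel:
    """Fitted zero-truncated Poisson mixture over k-mer counts."""

    lam: float
    lambda_e: float
    weights: np.ndarray
    k: int
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_components: int = N_COMPONENTS

    @property
    def rates(self) -> np.ndarray:
        """Component rates: [lambda_e, lambda/2, lambda, 2*lambda .. 8*lambda]."""
        mult = np.concatenate(([0.5, 1.0], np.arange(2.0, self.n_components - 1)))
        return np.concatenate(([self.lambda_e], mult * self.lam))

    def posterior(self, c) -> np.ndarray:
        """Component responsibilities at count(s) c; rows sum to 1."""
        c = np.atleast_1d(c)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(self.weights, 1e-300))[None, :] + np.stack(
                [ztp_logpmf(c, r) for r in self.rates], axis=1
            )
        logp -= logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp)

    def posterior_homozygous(self, c):
        """Posterior probability that a k-mer with count c is homozygous."""
        p = self.posterior(c)[:, 2]
        return float(p[0]) if np.isscalar(c) or np.ndim(c) == 0 else p

    def posterior_homozygous_table(self, cap: int = HISTOGRAM_COUNT_CAP):
        """hom posterior for counts 0..cap (index 0 unused, set to 0)."""
        table = np.zeros(cap + 1)
        table[1:] = self.posterior(np.arange(1, cap + 1))[:, 2]
        return table


def fit_mixture_em(
    hist: CountHistogram,
    n_components: int = N_COMPONENTS,
    max_iter: int = 30,
    tol: float = 1e-6,
    lambda_init: float | None = None,
) -> CountMixtureModel:
    """Fit the mixture by EM over the count histogram.

    Only the weights and the error rate lambda_e are updated; the genomic
    component rates stay pinned to multiples of the initial lambda. Stops at
    ``max_iter`` iterations or when the relative log-likelihood improvement
    drops below ``tol``.
    """
    if not hist.counts:
        raise ValueError("cannot fit mixture to an empty histogram")
    if n_components < 4:
        raise ValueError("need at least error/het/hom/repeat components")
    if len(hist.counts) == 1:
        warnings.warn(
            "degenerate histogram with a single count value; "
            "EM will converge immediately",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = float(lambda_init) if lambda_init is not None else initialize_lambda(hist)
    lam = max(lam, 1e-6)
    c, n_c = hist.arrays()
    total = n_c.sum()

    weights = np.concatenate(
        ([0.3, 0.1, 0.5], np.full(n_components - 3, 0.1 / (n_components - 3)))
    )
    lambda_e = 1.0
    mult = np.concatenate(([0.5, 1.0], np.arange(2.0, n_components - 1)))
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        rates = np.concatenate(([lambda_e], mult * lam))
        logp = np.log(np.maximum(weights, 1e-300))[None, :] + np.stack(
            [ztp_logpmf(c, r) for r in rates], axis=1
        )
        row = logsumexp(logp, axis=1)
        loglik = float(np.dot(n_c, row))
        trace.append(loglik)
        resp = np.exp(logp - row[:, None])
        # M-step
        comp_mass = resp.T @ n_c
        weights = comp_mass / total
        if comp_mass[0] > 0:
            m0 = float(np.dot(resp[:, 0] * n_c, c) / comp_mass[0])
            lambda_e = _ztp_mean_inverse(m0)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * abs(prev):
            break
        prev = loglik
    return CountMixtureModel(
        lam=lam,
        lambda_e=lambda_e,
        weights=weights,
        k=hist.k,
        log_likelihood_trace=trace,
        n_components=n_components,
    )


def posterior_homozygous(c, model: CountMixtureModel):
    return model.posterior_homozygous(c)


@dataclass
class GenomeSizeEstimate:
    G: float
    lambda_used: float
    w0_used: float
    k_used: int
    n_reads: int
    read_len: int


def estimate_genome_size(
    model: CountMixtureModel, n_reads: int, read_len: int, k: int = 31
) -> GenomeSizeEstimate:
    """G = (1 - w0) * n * (l - k + 1) / lambda (error-corrected inversion)."""
    if model.lam <= 0:
        raise ValueError("lambda must be positive to estimate genome size")
    if read_len <= k:
        raise ValueError("read length must exceed k")
    w0 = float(model.weights[0])
    G = (1.0 - w0) * n_reads * (read_len - k + 1) / model.lam
    if G <= 0:
        raise ValueError("non-positive genome size estimate")
    return GenomeSizeEstimate(
        G=G,
        lambda_used=model.lam,
        w0_used=w0,
        k_used=k,
        n_reads=n_reads,
        read_len=read_len,
    )
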