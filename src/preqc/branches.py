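"""De Bruijn branch detection and error/variant/repeat classification.

At every homozygous k-mer k_i (homozygous by count posterior) with two
strand-validated suffix neighbors k_a, k_b (counts c_a >= c_b), two pieces of
evidence separate the three branch causes:

* the discordance statistic d = (c_a - c_ia) + (c_b - c_ib), where c_ia is
  the number of reads containing both k_i and k_a, i.e. the count of the
  joining (k+1)-mer. d counts reads holding a neighbor but not k_i. Under the
  error and variant models this needs a read starting exactly at the neighbor
  (or an error in the first base of k_i), so d ~ Poisson(rho + eps) with rho
  = lambda / (l - k + 1) the per-copy read-start density. Under the repeat
  model the neighbors live at extra genomic copies, so d ~ Poisson(m*lambda +
  rho) mixed over the fitted repeat states m = 1..7.

* the coverage balance of c_b against c_a + c_b: Binomial(1/2) for a variant
  (two alleles, equal sampling), Binomial(p_err) for an error (most reads
  support the true base), and a Beta-Binomial(alpha, beta) for a repeat
  (copy-number configuration unknown).

Posteriors combine both likelihoods under a uniform prior; branch *rates* per
k accumulate the posteriors as soft counts F_error/F_variant/F_repeat over
every k-mer instance of the sampled reads, normalized by the number N_h of
homozygous k-mers checked.

``reference_branch_rates`` computes the same two rates exactly from the k-mer
graph of a known diploid genome, the validation route for the estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import betabinom, binom, poisson

from . import _hashing as H
from .count_model import (
    CountMixtureModel,
    fit_mixture_em,
    sample_count_histogram,
)
from .index import KmerIndex
from .simulate import DiploidGenome

logger = logging.getLogger(__name__)

CLASSES = ("error", "variant", "repeat")


@dataclass
class ClassifierParams:
    """Parameters of the branch classifier at one k."""

    lam: float
    read_len: int
    k: int
    repeat_weights: np.ndarray  # over extra-copy states m = 1..7
    p_error_balance: float = 0.05
    alpha: float = 2.0
    beta: float = 2.0
    hom_threshold: float = 0.90
    min_lambda: float = 15.0
    mu_eps: float = 0.05  # first-base-error allowance in the d model

    def __post_init__(self) -> None:
        q = np.asarray(self.repeat_weights, dtype=float)
        s = q.sum()
        self.repeat_weights = q / s if s > 0 else np.full(q.size, 1.0 / q.size)

    @property
    def rho(self) -> float:
        """Density of read-starting positions per genomic copy."""
        return self.lam / (self.read_len - self.k + 1)

    @classmethod
    def from_model(
        cls, model: CountMixtureModel, read_len: int, k: int, **kw
    ) -> "ClassifierParams":
        return cls(
            lam=model.lam,
            read_len=read_len,
            k=k,
            repeat_weights=np.asarray(model.weights[3:], dtype=float),
            **kw,
        )


@dataclass
class BranchObservation:
    """One suffix branch: k_i with its two highest-coverage neighbors."""

    k_i: str
    k_a: str
    k_b: str
    c_a: int
    c_b: int
    c_ia: int
    c_ib: int
    k: int

    @property
    def d(self) -> int:
        return max(0, (self.c_a - self.c_ia) + (self.c_b - self.c_ib))


@dataclass
class BranchPosterior:
    p_error: float
    p_variant: float
    p_repeat: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_error, self.p_variant, self.p_repeat])

    @property
    def argmax(self) -> str:
        return CLASSES[int(np.argmax(self.as_array()))]


def observe_branch(index: KmerIndex, k_i: str) -> BranchObservation | None:
    """Inspect k_i for a suffix branch; None when < 2 validated neighbors.

    Requires k and k+1 indexed (the joining (k+1)-mer counts c_ia/c_ib come
    from the (k+1)-mer table). Ties between equal-coverage neighbors break in
    base order A<C<G<T.
    """
    k = len(k_i)
    validated = [
        (nb, index.count_rc(nb))
        for nb, ok in index.neighbors(k_i, "suffix")
        if ok
    ]
    if len(validated) < 2:
        return None
    order = sorted(range(len(validated)), key=lambda i: -validated[i][1])
    (k_a, c_a), (k_b, c_b) = validated[order[0]], validated[order[1]]
    c_ia = index.count_rc(k_i + k_a[-1])
    c_ib = index.count_rc(k_i + k_b[-1])
    return BranchObservation(
        k_i=k_i, k_a=k_a, k_b=k_b, c_a=c_a, c_b=c_b, c_ia=c_ia, c_ib=c_ib, k=k
    )


# -- likelihoods ----------------------------------------------------------


def likelihood_d(d, cls: str, params: ClassifierParams):
    """P(d | class): Poisson(rho+eps) for error/variant; repeat-state
    mixture of Poisson(m*lambda + rho) for repeats."""
    d = np.asarray(d)
    mu_ev = params.rho + params.mu_eps
    if cls in ("error", "variant"):
        return poisson.pmf(d, mu_ev)
    if cls == "repeat":
        m = np.arange(1, params.repeat_weights.size + 1, dtype=float)
        mus = m * params.lam + params.rho
        return poisson.pmf(d[..., None], mus[None, :]) @ params.repeat_weights
    raise ValueError(f"unknown class {cls!r}")


def likelihood_balance(c_a, c_b, cls: str, params: ClassifierParams):
    """P(c_b | c_a + c_b, class) for the coverage-balance evidence."""
    n = np.asarray(c_a) + np.asarray(c_b)
    if cls == "variant":
        return binom.pmf(c_b, n, 0.5)
    if cls == "error":
        return binom.pmf(c_b, n, params.p_error_balance)
    if cls == "repeat":
        return betabinom.pmf(c_b, n, params.alpha, params.beta)
    raise ValueError(f"unknown class {cls!r}")


def _classify_arrays(
    c_a: np.ndarray, c_b: np.ndarray, d: np.ndarray, params: ClassifierParams
) -> np.ndarray:
    """(n, 3) posterior matrix over (error, variant, repeat)."""
    like = np.stack(
        [
            likelihood_d(d, cls, params) * likelihood_balance(c_a, c_b, cls, params)
            for cls in CLASSES
        ],
        axis=-1,
    )
    tot = like.sum(axis=-1, keepdims=True)
    # degenerate all-zero likelihood (far tails): fall back to uniform
    uniform = np.full_like(like, 1.0 / 3.0)
    return np.where(tot > 0, like / np.where(tot > 0, tot, 1.0), uniform)


def classify_branch(
    obs: BranchObservation, params: ClassifierParams
) -> BranchPosterior:
    """Posterior over error/variant/repeat (uniform prior, d and balance
    independent); no argmax is taken."""
    post = _classify_arrays(
        np.array([obs.c_a]), np.array([obs.c_b]), np.array([obs.d]), params
    )[0]
    return BranchPosterior(*map(float, post))


# -- branch rates over sampled reads --------------------------------------


@dataclass
class BranchRateEntry:
    k: int
    N_h: int
    n_branches: int
    F_error: float
    F_variant: float
    F_repeat: float
    lam: float

    MIN_SOFT_COUNT = 2.0

    def _rate(self, soft: float) -> float | None:
        """Rates are reported only when the soft count reaches 2."""
        if self.N_h == 0 or soft < self.MIN_SOFT_COUNT:
            return None
        return soft / self.N_h

    @property
    def variant_rate(self) -> float | None:
        return self._rate(self.F_variant)

    @property
    def repeat_rate(self) -> float | None:
        return self._rate(self.F_repeat)

    @property
    def error_rate(self) -> float | None:
        return self._rate(self.F_error)


@dataclass
class BranchRates:
    entries: list[BranchRateEntry] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def entry(self, k: int) -> BranchRateEntry | None:
        for e in self.entries:
            if e.k == k:
                return e
        return None


def branch_rates_at_k(
    index: KmerIndex,
    model: CountMixtureModel,
    params: ClassifierParams,
    k: int,
    n_reads: int = 1_000_000,
    rng=None,
) -> BranchRateEntry:
    """Soft-classified branch counts over every k-mer of sampled reads.

    N_h counts k-mer *instances* passing the homozygous-posterior threshold;
    each branch found there contributes its posterior to the three soft
    counts, so F_error + F_variant + F_repeat equals the number of branches
    examined.
    """
    rng = np.random.default_rng(rng)
    sel = index.sample_read_indices(n_reads, rng)
    codes = index.selected_codes(sel)
    crc, hf, hr, valid, x0 = index.window_count_rc(codes, k)

    hom_table = model.posterior_homozygous_table()
    cap = hom_table.size - 1
    p_hom = hom_table[np.minimum(crc, cap)]
    hom = valid & (p_hom >= params.hom_threshold)
    N_h = int(hom.sum())
    if N_h == 0:
        return BranchRateEntry(k, 0, 0, 0.0, 0.0, 0.0, model.lam)

    hf_h = hf[hom]
    hr_h = hr[hom]
    x0_h = x0[hom].astype(np.uint64)

    table_k = index._table(k)
    table_k1 = index._table(k + 1)
    powk1 = np.uint64(H.pow_base(k - 1))
    powk = np.uint64(H.pow_base(k))
    B = np.uint64(H.BASE)
    Binv = np.uint64(H.BASE_INV)
    bases = np.arange(1, 5, dtype=np.uint64)

    with np.errstate(over="ignore"):
        stem_f = (hf_h - x0_h * powk1) * B
        hf_nb = stem_f[:, None] + bases[None, :]
        stem_r = (hr_h - (np.uint64(5) - x0_h)) * Binv
        hr_nb = stem_r[:, None] + ((np.uint64(5) - bases) * powk1)[None, :]

    cf_nb = table_k.lookup_many(hf_nb.ravel()).reshape(hf_nb.shape)
    cr_nb = table_k.lookup_many(hr_nb.ravel()).reshape(hr_nb.shape)
    validated = (cf_nb > 0) & (cr_nb > 0)
    n_valid = validated.sum(axis=1)
    is_branch = n_valid >= 2
    n_branches = int(is_branch.sum())
    if n_branches == 0:
        return BranchRateEntry(k, N_h, 0, 0.0, 0.0, 0.0, model.lam)

    crc_nb = np.where(validated, cf_nb + cr_nb, -1)[is_branch]
    # stable sort on negative counts: ties resolve in base order A<C<G<T
    order = np.argsort(-crc_nb, axis=1, kind="stable")
    a_col = order[:, 0]
    b_col = order[:, 1]
    rows = np.arange(n_branches)
    c_a = crc_nb[rows, a_col]
    c_b = crc_nb[rows, b_col]

    hf_b = hf_h[is_branch]
    hr_b = hr_h[is_branch]

    def joint_count(col: np.ndarray) -> np.ndarray:
        b = (col + 1).astype(np.uint64)
        with np.errstate(over="ignore"):
            hfj = hf_b * B + b
            hrj = (np.uint64(5) - b) * powk + hr_b
        return table_k1.lookup_many(hfj) + table_k1.lookup_many(hrj)

    c_ia = joint_count(a_col)
    c_ib = joint_count(b_col)
    d = np.maximum(0, (c_a - c_ia) + (c_b - c_ib))

    post = _classify_arrays(c_a, c_b, d, params)
    F_error, F_variant, F_repeat = post.sum(axis=0)
    return BranchRateEntry(
        k, N_h, n_branches, float(F_error), float(F_variant), float(F_repeat),
        model.lam,
    )


def estimate_branch_rates(
    reads,
    k_values=tuple(range(21, 72, 5)),
    n_reads: int = 1_000_000,
    hist_reads: int = 50_000,
    rng=None,
    min_lambda: float = 15.0,
    hom_threshold: float = 0.90,
) -> BranchRates:
    """Per-k branch rates with the mixture model refit at each k.

    k values whose fitted lambda falls below ``min_lambda`` are skipped with
    a notice (the classifier has no power there); missing points mirror the
    behavior on low-coverage datasets.
    """
    rng = np.random.default_rng(rng)
    out = BranchRates()
    for k in k_values:
        index = KmerIndex(reads, [k, k + 1])
        hist = sample_count_histogram(index, k, hist_reads, rng)
        model = fit_mixture_em(hist)
        if model.lam < min_lambda:
            msg = f"lambda {model.lam:.2f} below minimum {min_lambda}"
            logger.info("k=%d skipped: %s", k, msg)
            out.skipped.append((k, msg))
            continue
        params = ClassifierParams.from_model(
            model,
            index.modal_read_length,
            k,
            min_lambda=min_lambda,
            hom_threshold=hom_threshold,
        )
        out.entries.append(
            branch_rates_at_k(index, model, params, k, n_reads, rng)
        )
    return out


# -- exact rates from a reference diploid genome --------------------------


def reference_branch_rates(
    genome: DiploidGenome, k: int
) -> tuple[float, float]:
    """(variant_rate, repeat_rate) computed exactly from the diploid k-mer
    graph of a known genome.

    Vertices are canonical k-mers of both haplotypes. A vertex is homozygous
    when it occurs exactly once on each haplotype — the population the
    read-based classifier's count filter selects. Each homozygous vertex is
    checked, in its hap_a forward orientation, for >= 2 existing suffix
    neighbors; a branch is a variant when exactly two alternatives exist and
    each is haplotype-specific with multiplicity 1, and a repeat otherwise.
    Rates are branches per distinct homozygous vertex.
    """
    if k > len(genome):
        raise ValueError("k exceeds genome length")
    codes_a = H.encode(genome.hap_a)
    codes_b = H.encode(genome.hap_b)

    def canonical(codes):
        hf, hr, valid = H.paired_window_hashes(codes, k)
        return np.minimum(hf, hr)[valid], hf, hr, valid

    can_a, hf_a, hr_a, valid_a = canonical(codes_a)
    can_b, _, _, _ = canonical(codes_b)
    tab_a = H.CountTable.from_occurrences(can_a)
    tab_b = H.CountTable.from_occurrences(can_b)

    in_b = tab_b.lookup_many(tab_a.hashes)
    hom_mask = (tab_a.counts == 1) & (in_b == 1)
    hom_hashes = tab_a.hashes[hom_mask]
    N_h = int(hom_mask.sum())
    if N_h == 0:
        return (0.0, 0.0)

    def member(q):
        if hom_hashes.size == 0:
            return np.zeros(q.shape, bool)
        i = np.minimum(np.searchsorted(hom_hashes, q), hom_hashes.size - 1)
        return hom_hashes[i] == q

    # positions of homozygous k-mers along hap_a (each occurs exactly once)
    can_full = np.minimum(hf_a, hr_a)
    pos_mask = valid_a & member(can_full)
    hf_h = hf_a[pos_mask]
    hr_h = hr_a[pos_mask]
    x0_h = codes_a[: hf_a.size][pos_mask].astype(np.uint64)

    powk1 = np.uint64(H.pow_base(k - 1))
    B = np.uint64(H.BASE)
    Binv = np.uint64(H.BASE_INV)
    bases = np.arange(1, 5, dtype=np.uint64)
    with np.errstate(over="ignore"):
        hf_nb = ((hf_h - x0_h * powk1) * B)[:, None] + bases[None, :]
        hr_nb = ((hr_h - (np.uint64(5) - x0_h)) * Binv)[:, None] + (
            (np.uint64(5) - bases) * powk1
        )[None, :]
    can_nb = np.minimum(hf_nb, hr_nb)
    mult_a = tab_a.lookup_many(can_nb.ravel()).reshape(can_nb.shape)
    mult_b = tab_b.lookup_many(can_nb.ravel()).reshape(can_nb.shape)
    mult = mult_a + mult_b
    exists = mult > 0
    n_nb = exists.sum(axis=1)
    branch = n_nb >= 2

    specific = exists & (mult == 1)
    is_variant = branch & (n_nb == 2) & (specific.sum(axis=1) == 2)
    n_variant = int(is_variant.sum())
    n_repeat = int(branch.sum()) - n_variant
    return (n_variant / N_h, n_repeat / N_h)
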