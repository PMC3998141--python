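"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on plain Python strings and dictionaries, with no use
of the package's hashing or numpy machinery, so agreement with the package
is a genuine dual-route check.
"""

from collections import Counter

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def naive_count(seqs, p: str) -> int:
    """Occurrences of p (literal strand, overlapping) across sequences."""
    total = 0
    for s in seqs:
        start = 0
        while True:
            i = s.find(p, start)
            if i < 0:
                break
            total += 1
            start = i + 1
    return total


def naive_count_rc(seqs, p: str) -> int:
    return naive_count(seqs, p) + naive_count(seqs, rc(p))


def all_kmers(seqs, k: int):
    out = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                out.add(w)
    return out


def naive_suffix_neighbors(seqs, x: str):
    """[(neighbor, strand_validated)] in base order, count_rc > 0 only."""
    out = []
    for b in "ACGT":
        nb = x[1:] + b
        fwd = naive_count(seqs, nb)
        rev = naive_count(seqs, rc(nb))
        if fwd + rev > 0:
            out.append((nb, fwd > 0 and rev > 0))
    return out


def n50_enumeration(lengths) -> int:
    """Largest L in the multiset with sum(lengths >= L) >= total / 2."""
    if not lengths:
        return 0
    total = sum(lengths)
    best = 0
    for candidate in sorted(set(lengths)):
        if sum(x for x in lengths if x >= candidate) >= total / 2:
            best = candidate
    return best


def enumerate_reference_rates(hap_a: str, hap_b: str, k: int):
    """(variant_rate, repeat_rate, n_variant, n_repeat, N_h) by exhaustive
    enumeration of the canonical k-mer graph of a diploid genome.

    A vertex is homozygous iff its canonical k-mer occurs exactly once on
    each haplotype. Checked in hap_a forward orientation for >= 2 existing
    suffix neighbors; variant iff exactly two alternatives each with total
    multiplicity 1.
    """
    canon = lambda s: min(s, rc(s))
    occ_a = Counter(canon(hap_a[i : i + k]) for i in range(len(hap_a) - k + 1))
    occ_b = Counter(canon(hap_b[i : i + k]) for i in range(len(hap_b) - k + 1))
    total = occ_a + occ_b
    hom = {x for x, c in occ_a.items() if c == 1 and occ_b.get(x, 0) == 1}
    n_var = n_rep = 0
    for i in range(len(hap_a) - k + 1):
        x = hap_a[i : i + k]
        if canon(x) not in hom:
            continue
        mults = [
            total[canon(x[1:] + b)]
            for b in "ACGT"
            if total.get(canon(x[1:] + b), 0) > 0
        ]
        if len(mults) >= 2:
            if len(mults) == 2 and mults == [1, 1]:
                n_var += 1
            else:
                n_rep += 1
    n_h = len(hom)
    return (n_var / n_h, n_rep / n_h, n_var, n_rep, n_h)
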