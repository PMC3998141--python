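# Methods

This note documents the models behind each metric, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Counting framework

All metrics reduce to two primitives over the read collection: counting a
fixed-length DNA word, and drawing reads uniformly at random. Words are
counted strand-specifically; `count_rc(P) = count(P) + count(rc(P))` is the
double-stranded count used throughout. The index is an exact hash-count
table per declared k (the pipeline uses k in {21..91 step 5} plus 31/51 and
the k+1 companions), built over a 64-bit polynomial rolling hash with a
fixed odd multiplier. The hash is position-wise invertible modulo 2^64, so
the hashes of all four suffix/prefix extensions, of the reverse complement
and of the joining (k+1)-mer follow from the current word in O(1) — this is
what makes the de Bruijn traversals and the vectorized branch scans cheap.
K-mers are identified by hash alone: with at most ~1e8 distinct words the
expected number of colliding pairs is below 1e-3, negligible against the
sampling noise of every estimate. K-mers containing N are never counted; a
k-mer and its reverse complement are one graph vertex; neighbor lists are
reported in fixed base order A<C<G<T for determinism.

An edge of the graph is *strand-validated* when the neighboring k-mer has
been seen at least once on each sequencing strand. All branch detection and
all greedy walks use only strand-validated edges, which suppresses branches
caused by strand-specific systematic errors.

## k-mer count spectrum and mixture model

The count c of a sampled k-mer is modeled as a 10-component mixture of
zero-truncated Poissons (zero-truncated because an unobserved k-mer has
count zero by construction): an error component with free rate lambda_e, a
heterozygous component at lambda/2, a homozygous component at lambda, and
seven repeat components pinned at 2·lambda .. 8·lambda (one per extra
genomic copy). EM updates only the weights w and lambda_e (exact ZTP
maximum-likelihood updates, so the log-likelihood is non-decreasing); the
genomic rates stay tied to lambda on the assumption that every copy-number
state is driven by the same overall coverage. Defaults: initial
w = [0.3, 0.1, 0.5, 0.1/7 x 7], lambda_e = 1.0, at most 30 iterations,
relative log-likelihood tolerance 1e-6. Histogram counts are capped at 1000
(the far tail is all repeat mass and only its total weight matters).

**lambda initialization.** The spectrum is sampled per k-mer *instance* of
50 000 random reads. Instance sampling is size-biased — a k-mer of count c
is drawn with probability proportional to c — which makes homozygous
instance counts exactly 1 + Poisson(lambda). The initializer finds the
first local minimum of the (lightly smoothed) histogram, takes the mode
above it, averages counts within ±2·sqrt(mode) of the mode (narrow enough
to exclude the heterozygous and first repeat peaks), and subtracts 1 for
the size bias. If the histogram decreases monotonically (error-dominated
data) it falls back to the overall weighted mean with a warning.

## Genome size

With n reads of length l, the reads contain n(l-k+1) k-mers and the
homozygous sampling rate satisfies lambda = n(l-k+1)/G. Error-containing
k-mers inflate the numerator, so the estimate corrects by the fitted error
weight w0:

    G = (1 - w0) · n (l - k + 1) / lambda       (k = 31 by default)

Read-length heterogeneity is handled by using the modal read length.

## Branch classification

At every k-mer instance of the sampled reads whose posterior probability of
being homozygous is at least 0.90 (N_h counts these instances), the suffix
side is checked for >= 2 strand-validated neighbors. For a branch with top
neighbors k_a, k_b (counts c_a >= c_b, ties in base order), two independent
pieces of evidence are combined under a uniform prior:

* **Discordance** d = max(0, (c_a - c_ia) + (c_b - c_ib)), with c_ia the
  count of the joining (k+1)-mer — the number of reads containing a
  neighbor but not k_i. Under the error and variant models this requires a
  read starting exactly at the neighbor or an error in the first base of
  k_i, so d ~ Poisson(rho + 0.05) with rho = lambda/(l - k + 1) the
  read-start density per genomic copy. Under the repeat model the neighbors
  occupy m extra copies, so d ~ sum_m q_m · Poisson(m·lambda + rho) with
  q_m the renormalized fitted repeat weights.
* **Balance** of c_b against n = c_a + c_b: Binomial(n, 1/2) for a variant,
  Binomial(n, 0.05) for an error, Beta-Binomial(n, alpha=2, beta=2) for a
  repeat (mild overdispersion reflecting the unknown copy-number split).

Posteriors are accumulated as *soft counts* F_error/F_variant/F_repeat, so
their sum equals the number of branches examined; rates are F_x/N_h and a
rate is only reported when its soft count reaches 2. k values whose fitted
lambda falls below 15 are skipped entirely (no classification power). The
numeric constants 0.05, alpha = beta = 2, the 0.90 homozygous threshold and
the minimum lambda of 15 are deliberate, conservative defaults exposed on
`ClassifierParams`; the model's behavior is insensitive to them within
reasonable ranges because the three classes separate by orders of magnitude
in likelihood for typical observations.

The classifier is refit (histogram + EM) at every analyzed k rather than
rescaling lambda from k = 31, because lambda depends on k through l - k + 1.

**Reference-graph rates.** For a known diploid genome the same two rates
are computed exactly: vertices are canonical k-mers of both haplotypes; a
vertex is *homozygous* when it occurs exactly once on each haplotype — the
same population the count-posterior filter selects on read data; each
homozygous vertex is checked in hap-A forward orientation for >= 2 existing
suffix neighbors; a branch is a variant when exactly two alternatives exist,
each haplotype-specific with multiplicity one, and a repeat otherwise.
Rates are branches per distinct homozygous vertex. Instance-based and
distinct-vertex-based normalizations agree in expectation because every
homozygous vertex is sampled at the same rate lambda.

Note that *identical* repeat copies produce branching only at multi-copy
vertices, which neither the posterior filter (read route) nor the
multiplicity-2 rule (reference route) counts — both routes deliberately
measure branching at single-copy vertices. Repeat branches at single-copy
vertices arise from *diverged* copies: two loci sharing a (k-1)-mer context
that then diverges. This is why the simulator supports diverged repeat
families and why the validation genomes use them.

## Per-base error rates

For each of M sampled reads R (M = 100 000 at full scale): candidate
overlaps are reads sharing a 31-mer with R on either strand, skipping seeds
seen more than 200 times (repeat pile-ups); each candidate is aligned
ungapped at the diagonal of the first shared seed and kept when the overlap
is >= 50 bp at >= 95% identity; the kept reads form a multiple alignment in
R's frame. A base b of R at position j is an error iff b differs from the
column consensus, the consensus has >= 3 supporting reads, and fewer than 4
reads support b. Columns with fewer than 4 reads are not assessed (they
enter neither numerator nor denominator). Consensus ties break toward R's
own base, so a 50/50 column never flags an error. Positions are 0-based
from the 5' end as sequenced. Overlaps are ungapped by design: the error
model targeted is substitution-dominated short-read data; indel errors
would truncate overlaps rather than be measured.

## Fragment sizes and simulated assembly

**Fragment sizes.** For a sampled pair (X, Y) in forward/reverse
orientation, a greedy walk starts at X's first 51-mer and repeatedly moves
to the highest-coverage strand-validated suffix neighbor until the first
51-mer of rc(Y) is reached, a dead end occurs, or 1500 steps pass. On
success the fragment size is (edges walked) + |Y|, i.e. the span from X's
start to Y's far end. Under low coverage long walks break more often, so
the distribution is biased toward shorter fragments — inherent to the
method. A config flag flips the expected mate orientation.

**Simulated assembly.** Per k (21..91 step 5 at full scale): walks start at
the first k-mer of sampled reads with homozygous posterior >= 0.5, extend
greedily in both directions, continue through branches classified error or
variant (argmax), and stop at repeat branches, dead ends, in-walk revisits,
or 50 000 k-mers. Visited k-mers enter a Bloom filter (16 bits/item, 3
probes, false-positive rate well under 1%) and starts already present are
skipped, so each genomic region seeds at most one walk; a Bloom false
positive can only skip a start, never corrupt a walk. Contig length is the
number of k-mers visited; the per-k summary is the N50.

## Synthetic data

The generator produces what the models assume: a diploid genome as a
uniform random sequence with planted repeat families (each family one
random unit planted copy_count times, non-overlapping, optionally diverged
per copy at `repeat_divergence` substitutions/base, default 0) and
per-base heterozygous substitutions at rate `het_rate`; reads as uniformly
placed fragments (Normal length, clipped at read length) from a random
haplotype, in forward/reverse orientation, with independent position-
specific substitution errors and constant Q30 qualities.

Not emulated: indels (in genome or reads), instrument-specific quality
profiles, GC-dependent coverage bias, chimeric fragments and adapter
contamination, ploidy other than 2. Passing tests therefore demonstrate
correctness of the estimators under the models' own assumptions, not
robustness to every artifact of real instruments; the real-data behaviors
the metrics are designed to *display* (3'-degrading quality, GC bias,
multi-modal insert distributions) can be injected through the explicit
parameters (`error_rate_by_pos`, quality strings, fragment mixtures).

## Validation problem sizes

The validation experiments (tests and `scripts/acceptance.py`) run at desk
scale, chosen so that every sampling error is several times smaller than
the tolerance being checked: genome-size recovery on 100 kb genomes at 40x
(within 5% error-free, 10% with 1% errors and heterozygosity 1e-3); EM
self-consistency on 1e6 draws (weights within 0.02, lambda_e within 0.2);
branch rates on a 1 Mb diploid genome at 40x with 0.5% errors and two
20-copy 5 kb repeat families at 5% divergence, scanned over 40 000 sampled
reads per k in {21, 31, 41, 51} (within a factor 2 of the reference graph;
repeat rate non-increasing in k); the error-profile ramp 0.2%->1.5% at 30x
with 8000 sampled reads; fragment recovery on 200 kb with 2000 pairs. The
repeat-family geometry (long, moderately diverged copies, as for real
interspersed elements) is what yields the characteristic monotone decline
of repeat branch rate with k: the shared-context probability decays like
(1 - divergence)^(k-1).

## Numerical choices

* ZTP pmf evaluated in log space; the normalizer log(1 - e^-rate) is
  clamped for rate > 700 where it is 0 to double precision.
* The lambda_e M-step solves mu/(1 - e^-mu) = m by Brent's method; sample
  means <= 1 (degenerate all-ones component) map to lambda_e ~ 0.
* All-zero classification likelihoods (deep tails) fall back to a uniform
  posterior rather than NaN.
* Greedy ties (equal neighbor coverage) break in base order A<C<G<T;
  branch top-2 selection uses a stable sort for the same determinism.
* Every sampler takes an explicit seed/generator; `run_all` fans a single
  seed into independent substreams per metric, so reports are
  byte-reproducible and metrics can be toggled without perturbing others.
* d is floored at 0: strand-resolved counting lets c_ia exceed c_a at read
  boundaries.

## Known limitations

* Arbitrary-length pattern counting is restricted to the declared k values
  (all the pipeline needs); the exact-count index trades the memory
  economy of a compressed full-text index for simplicity at desk scale.
* Ploidy > 2 and mate-pair/long-insert libraries are out of scope.
* The classifier loses power when lambda is small (overlapping count
  components); such k values are skipped rather than reported noisily.
* Fragment-size estimation reports resolved walks only; under low coverage
  the unresolved fraction is biased toward long fragments.
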