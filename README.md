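# preqc

Reference-free pre-assembly quality assessment and genome characterization
from raw sequencing reads.

Before committing to a de novo assembly, it helps to know what you are up
against: how big the genome is, how heterozygous and repeat-rich it is, how
noisy the reads are, and whether the library's fragment sizes match what
was ordered. `preqc` estimates all of this from a FASTQ read set alone — no
reference genome — and summarizes how hard the assembly will be by
measuring how often a de Bruijn graph built from the data branches because
of sequencing errors, allelic variants, or repeats.

## What it computes

Everything rests on exact k-mer counting over the reads (strand-aware, with
`count_rc(P) = count(P) + count(rc(P))`) and uniform read sampling.

* **k-mer count spectrum + mixture model.** Counts of sampled k-mers are
  modeled as a 10-component zero-truncated Poisson mixture — error k-mers
  at a free rate λ_e, heterozygous at λ/2, homozygous at λ, repeats at
  2λ…8λ — fitted by EM (weights **w** and λ_e free, genomic rates pinned
  to λ).
* **Genome size.** From the coverage identity λ = n(l−k+1)/G, corrected
  for artifact k-mers: G = (1 − w₀)·n(l−k+1)/λ, with k = 31.
* **Branch classification.** Every sampled homozygous k-mer (posterior
  from the mixture) is checked for a suffix branch; each branch is
  classified error/variant/repeat by combining a read-discordance
  statistic d (Poisson models; repeats make d large) with the coverage
  balance of the two alternatives (Binomial(½) for variants,
  Binomial(0.05) for errors, Beta-Binomial for repeats). Posteriors
  accumulate as soft counts into per-k branch rates. For a known diploid
  genome the same rates are computed exactly from the reference k-mer
  graph, which is how the estimator is validated.
* **Per-base error rates.** Overlap-consensus: sampled reads are aligned
  (ungapped, 31-mer seeded, ≥ 50 bp, ≥ 95% identity) against the reads
  they overlap; a base is an error when it contradicts a consensus
  supported by ≥ 3 reads while < 4 reads support it.
* **Fragment sizes.** Greedy walks through the 51-mer de Bruijn graph from
  one mate to the other; the walk length is the fragment size.
* **Simulated assembly.** Greedy bidirectional walks that resolve
  error/variant branches and stop at repeat branches mimic an idealized
  assembler; contig N50 as a function of k shows which k the data can
  support.

A built-in simulator generates diploid genomes (heterozygosity, repeat
families with optional per-copy divergence) and paired error-bearing reads,
so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from preqc import (simulate_diploid_genome, simulate_reads, KmerIndex,
                   sample_count_histogram, fit_mixture_em,
                   estimate_genome_size, estimate_branch_rates)

genome = simulate_diploid_genome(100_000, het_rate=1e-3, seed=1)
reads = simulate_reads(genome, coverage=40,
                       error_rate_by_pos=np.full(100, 0.01), seed=2)

index = KmerIndex(reads, [31])
hist = sample_count_histogram(index, 31, 50_000, np.random.default_rng(3))
model = fit_mixture_em(hist)
est = estimate_genome_size(model, len(reads), 100)
print(f"lambda={model.lam:.1f}  w0={model.weights[0]:.3f}  G={est.G:,.0f}")

rates = estimate_branch_rates(reads, k_values=[21, 31], n_reads=20_000, rng=4)
for e in rates.entries:
    print(f"k={e.k}  variant_rate={e.variant_rate:.2e}  "
          f"repeat_rate={e.repeat_rate or 0:.2e}")
```

Output:

```
lambda=20.2  w0=0.267  G=101,571
k=21  variant_rate=8.66e-04  repeat_rate=0.00e+00
k=31  variant_rate=8.47e-04  repeat_rate=0.00e+00
```

λ ≈ 20 is the homozygous 31-mer sampling rate (40× coverage, but only 70 of
100 read positions start a 31-mer, and ~27% of k-mer instances contain an
error at a 1% error rate — the fitted w₀ = 0.27); correcting by w₀ recovers
the 100 kb genome within 1.6%. The variant branch rate ≈ 9e-4 per
homozygous vertex reflects the simulated heterozygosity of 1e-3, and the
repeat rate is zero because this genome has no planted repeats.

Command line:

```
preqc simulate --genome-size 100000 --coverage 40 --error 0.01 --out sim
preqc run sim.fastq.gz --paired --out report.json --seed 1 --scale 0.05
preqc report report.json -o report.pdf
```

`preqc run` writes a schema-versioned JSON report (byte-reproducible for a
given seed); `preqc report` renders the panels (count spectrum, branch
rates vs k, N50 vs k, error-by-position, GC×coverage, quality, fragment
sizes) into a PDF.

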