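# bcar

**Barcode-sequence mapping by quality-aware alignment and Bayesian consensus.**

In high-throughput sequence–function experiments, each variant of interest is
tagged with a short DNA barcode on the same molecule. Building the
barcode→sequence map requires collapsing the several sequencing reads of each
barcode into one consensus sequence — a step that is easy when errors are rare
and hard when indel errors throw reads out of phase, because a single missing
or extra base makes two reads disagree at every downstream position.

`bcar` is a mapper built specifically for this error-correction setting rather
than for homology comparison. Its three stages:

1. **Sort** — reads are sorted by barcode with an external (disk) merge sort,
   so arbitrarily large FASTQ files are processed within a fixed memory budget.
2. **Align** — the reads of each barcode are converted into *evidence arrays*:
   at position *t*, the entry for base *b* is the log-likelihood
   ℓ_b = Σ log P(observed call | true base = b), with
   P(obs = x | true = x) = 1 − e and P(obs = x | true = b ≠ x) = e/3, where
   e = 10^(−Q/10) is the Phred error probability of the call. Arrays are
   progressively merged by a modified Needleman–Wunsch: the match score of two
   columns is the cosine similarity of their posterior-weighted base/gap
   vectors, mapped linearly onto [−1, +1], with affine gap penalties and a
   banded DP for long reads. Reads are folded in by decreasing similarity to an
   unaligned consensus — the role a guide tree plays in classical MSA, adapted
   to reads that differ only by sequencing error.
3. **Call** — columns where a strict majority of spanning reads are gapped are
   removed; each remaining column is called as the maximum-posterior base
   (uniform prior over A/C/G/T), with quality Q = −10·log₁₀(1 − p*) capped at
   93. Positions without a posterior majority (p* < 0.5) become `N` with Q = 2.
   No read-count or quality filtering is imposed — singleton barcodes are
   emitted and the user filters downstream.

Input and output are plain FASTQ (gzip supported); no reference sequence is
needed. The package also ships a read simulator with controlled substitution
(missense) and indel error rates, an exact-reconstruction evaluator, and the
analytic *majority bound*: the probability that at every one of L positions at
least ⌈n/2⌉ of the n reads carry the correct base,
P(X ≥ ⌈n/2⌉)^L with X ~ Binomial(n, 1 − e) — a soft ceiling on exact
reconstruction, since below a majority the consensus typically degrades to `N`.

## Worked example

Simulate 50 barcodes × 10 reads of 1 kb at 0.3% substitution + 0.3% indel
rates (≈ 6 errors per read, ≈ 3 of them indels), collapse, and score:

```bash
bcar simulate --length 1000 --reads-per-barcode 10 --barcodes 50 \
     --missense-rate 0.003 --indel-rate 0.003 --seed 42 \
     --out-fastq reads.fastq --out-truth truth.tsv
bcar map --input reads.fastq --output consensus.fastq --stats-out stats.tsv
bcar evaluate --consensus consensus.fastq --truth truth.tsv \
     --reads-per-barcode 10 --error-rate 0.006
```

prints

```
INFO simulated 50 barcodes x 10 reads (mean indels/read 3.050)
INFO map: 500 reads in, 50 barcodes out, 0 reads skipped, 10.00 reads/barcode
exact_match_rate	0.960000
majority_bound	1.000000
```

48 of 50 barcodes are reconstructed *exactly* even though essentially every
raw read contains multiple indels; the measured rate sits slightly below the
missense-only majority bound, the expected signature of occasional alignment
errors when indels are frequent. `stats.tsv` lists per-barcode read count,
mean/min consensus quality and length:

```
barcode	n_reads	mean_q	min_q	length
AAATTAGACGGTAACC	10	93.00	93	1000
ACGTAGTTCACTTGAA	10	93.00	93	1000
```

Useful `map` flags: `--no-align` (positional stacking baseline, no alignment),
`--barcode-length`, `--input2 barcodes.fastq` (barcodes in a separate file),
`--chunk-size`/`--tmp-dir`/`--keep-tmp` (external sort), `--gap-open`,
`--gap-extend`, `--band-width`, `--free-end-gaps`.

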