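# Methods

## The evidence model

A read is treated as evidence about its template, not as a string. Each
position contributes a 4-vector of log-likelihoods over the true-base
hypotheses {A, C, G, T}: the called base *x* with Phred quality Q (error
probability e = 10^(−Q/10)) contributes log(1 − e) to hypothesis *x* and
log(e/3) to each alternative — the error mass is split uniformly because
platform-specific substitution matrices are deliberately out of scope. An `N`
call contributes log(1/4) to every hypothesis (no information) but still
counts toward coverage. Evidence from multiple reads of the same molecule
combines by adding log-likelihoods, which is the exact Bayesian update for
independent observations and is numerically stable at any depth.

e is clamped to [1e−6, 0.75]. The floor stops a single Q≳60 base from
out-weighing any realistic amount of contrary evidence irreversibly; the
ceiling keeps Q=0 calls weakly informative rather than anti-informative
(e > 0.75 would make the *called* base the least likely hypothesis).

Indel support is a **count channel**, not a likelihood: FASTQ qualities
quantify substitution confidence only, so each column tracks how many
spanning reads place a gap there (`gap_count`) out of how many span it at all
(`coverage`). The gap fraction g = gap_count/coverage enters the aligner
through the similarity vector and the consensus through the column-drop rule.

## Alignment

Two evidence arrays are aligned globally with a Needleman–Wunsch variant.
Each column is summarized by a 5-component similarity vector
(p_A(1−g), p_C(1−g), p_G(1−g), p_T(1−g), g), where p is the posterior under a
uniform prior; the match score of two columns is the cosine similarity of
these vectors mapped linearly onto [s_min, s_max] = [−1, +1]. Two confident
identical columns score +1 exactly; confident conflicts approach −1;
ambiguous columns land in between, so the DP trades off a soft mismatch
against a gap instead of being forced into a hard call. The linear map is the
minimal interpretation of "scaled" cosine scoring; s_max/s_min are
user-adjustable if a different contrast is wanted.

Gaps are affine: −1.5 to open, −0.5 per additional column (switching gap
direction re-opens). These defaults make a 1-column gap (−1.5) cheaper than
two forced mismatches (≈ −2 · cost of a confident conflict) but more
expensive than one, which is the right trade-off when indel errors are rarer
per base than substitutions yet must be absorbed rather than filtered.

The DP is banded around the length-proportional diagonal with half-width
max(16, ⌈0.05·L⌉), making long-read alignment O(L·band) instead of O(L²). If
the optimal traceback touches the band edge at an interior column the band is
doubled (to at most 4× the initial width) and the alignment re-run; still
touching at 4× raises an error rather than silently returning a possibly
clipped path. Ties are broken deterministically (MATCH over DELETE over
INSERT, at the end cell and at every traceback step) so output is
bit-reproducible. An optional free-end-gap mode (off by default, since the
underlying model is global alignment of same-template reads) waives terminal
gap penalties for truncated-read data. The band kernel is compiled with
numba; an affine-gap recurrence is sequentially dependent within a row, so
vectorizing it in pure numpy is not possible.

**Merging.** Along the optimal path, MATCH columns add element-wise; a column
where one array is absent charges that array's reads to the gap and coverage
channels — but only between the array's first and last aligned columns, so a
short read does not accrue gap evidence for positions it never observed.

**Progressive order.** All reads are first stacked positionally (no
alignment) and hard-called; each read is scored by its fraction of agreement
with that call string over the overlap, reads shorter than half the consensus
go last, and reads are folded in by descending score (ties by input order).
Starting from the most typical reads keeps the early profile reliable — the
function a guide tree serves in homology MSA, without assuming a phylogeny
that sequencing reads do not have.

## Consensus

Columns where gap_count > coverage/2 are dropped (minority insertions and
alignment artifacts); a tie keeps the column. Each surviving column is called
as the maximum-posterior base, Q = round(−10·log₁₀(1 − p*)) with the
complement clamped at 10^−9.3 so Q caps at 93 (the last printable Phred+33
character); rounding is half-away-from-zero for determinism. If p* < 0.5, or
the maximum is tied, the position is emitted as `N` with the conventional
no-call quality 2 — a posterior-majority rule rather than a raw-vote rule,
since the evidence weights already incorporate the qualities. No filtering on
read count or quality is applied anywhere; singleton barcodes pass through.

## Sorting and grouping

An external merge sort keeps at most `chunk_size` records (default 10⁶) in
memory: chunks are sorted stably by barcode and spilled as plain FASTQ with
the barcode prepended to the record id, then k-way merged with ties broken by
chunk index (preserving input order overall). Merging opens at most 256
chunk files at once; beyond that, chunks are merged in cascaded passes so the
sort never exhausts file descriptors. Grouping is by exact barcode match —
barcode error correction/clustering is a separate problem this tool does not
claim to solve.

## The simulator

The simulator generates the study conditions: `n_barcodes` distinct random
barcodes (16 bp default, error-free in reads, since grouping is exact-match)
each tagging a uniform-random true sequence of length L, sequenced `n_reads`
times. Per insert base, independently: deletion with probability i/2;
otherwise substitution to a uniformly chosen different base with probability
m; and before each position, insertion of one uniform random base with
probability i/2 — total per-base indel rate i, split evenly. Every insert
base carries the constant quality Q = round(−10·log₁₀ max(m, 10⁻⁶)) clamped
to [2, 93], making the quality string consistent with the substitution rate;
indels are not representable in Phred space and are left to the aligner.
Output is byte-identical for a fixed seed.

What this emulates — and what it does not: errors are i.i.d. across positions
and reads, qualities are constant within a run, and barcodes are error-free.
Real platforms have homopolymer-biased indels, cycle- and context-dependent
qualities, chimeras and barcode errors. Passing tests on this generator
therefore demonstrate the correctness of the sort/align/consensus machinery
and its calibration under the stated error model, not robustness to
platform-specific artifacts.

The evaluator scores **exact** reconstruction (an `N`, any length difference,
or a missing barcode is a failure). The analytic majority bound
P(X ≥ ⌈n/2⌉)^L, X ~ Binomial(n, 1 − e), is the probability that every
position retains a correct-base majority; "at least half" is implemented as
X ≥ ⌈n/2⌉, so for n = 10 reads five correct copies suffice.

## Problem sizes and numerical choices

The shipped verification runs use scaled-down dataset sizes chosen to make
the statistical checks decisive while keeping a full run of the suite and the
acceptance script in the minutes range on one CPU: 200 barcodes per
error-rate point for bound-tracking (binomial sampling σ ≲ 0.4% near the
bound), 100 barcodes for the alignment-versus-stacking contrast, 5 barcodes
of 20 reads at L = 10 kb for the long-read check, and 10⁴ records for the
external-sort oracle. Posteriors are computed via max-shifted softmax;
alignment scores are float64 and verified against path recomputation to
1e−9; DP correctness is checked against exhaustive path enumeration on short
pairs, and consensus posteriors/qualities against a direct
likelihood-product oracle.

## Known limitations

* Uniform substitution model and uniform prior; no platform error profiles.
* No barcode error correction: reads whose barcode contains an error form
  their own (usually singleton) group.
* Quality calibration is exact under the model at low depth but consensus
  qualities saturate at the 93 cap quickly with concordant reads; with
  constant-quality input reads the consensus quality spectrum is strongly
  quantized.
* Single-threaded; barcode groups are independent, so a parallel map over
  groups is a safe future extension.
* A minority-read insertion at the extreme ends of a template survives
  consensus (overhang columns carry no gap evidence from reads that do not
  span them); interior minority insertions are dropped by the gap-majority
  rule.
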