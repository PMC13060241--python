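"""Per-position evidence model: reads as log-likelihood matrices.

The central representation shift: a read is not a string of bases but a matrix
of evidence.  Each position holds the log-likelihood of the observed data
under each of the four true-base hypotheses, derived from the base call and
its Phred quality.  Evidence from reads of the same molecule combines by
adding log-likelihoods (the Bayes-exact rule for independent observations),
which is numerically stable no matter how many reads are stacked.

Gaps are tracked as counts, not likelihoods: sequencing qualities quantify
substitution confidence, so indel support is summarized by the fraction of
spanning reads that place a gap at a column.  That fraction feeds the
alignment match score (5th similarity component) and the consensus
gap-column-drop rule.

Hypothesis order is A, C, G, T (indices 0..3); 'N' is index 4.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .fastq_io import SequenceRead

BASES = "ACGT"
N_INDEX = 4

# Error-probability clamp: the floor stops one overconfident read from
# dominating irreversibly; the ceiling keeps Q=0 calls weakly informative
# instead of anti-informative.
ERROR_FLOOR = 1e-6
ERROR_CEIL = 0.75

_BASE_INDEX = np.full(256, N_INDEX, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i
_IDX_TO_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)

LOG_QUARTER = float(np.log(0.25))


def seq_to_indices(bases: str) -> np.ndarray:
    """Base string -> int8 indices (A=0, C=1, G=2, T=3, anything else=4)."""
    return _BASE_INDEX[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def indices_to_seq(idx: np.ndarray) -> str:
    return _IDX_TO_CHAR[idx].tobytes().decode("ascii")


def phred_to_error(q: Union[int, float, np.ndarray]) -> Union[float, np.ndarray]:
    """Phred score -> error probability 10^(-Q/10), clamped to [1e-6, 0.75]."""
    e = np.clip(10.0 ** (-np.asarray(q, dtype=np.float64) / 10.0),
                ERROR_FLOOR, ERROR_CEIL)
    if np.ndim(q) == 0:
        return float(e)
    return e


@dataclass
class EvidenceColumn:
    """Accumulated evidence for one alignment column.

    loglik[b] = sum over contributing reads of log P(observation | true base b);
    gap_count = spanning reads aligned to a gap here; coverage = spanning reads
    total (base or gap).
    """

    loglik: np.ndarray  # shape (4,), float64
    gap_count: int = 0
    coverage: int = 0

    @classmethod
    def zero(cls) -> "EvidenceColumn":
        return cls(loglik=np.zeros(4), gap_count=0, coverage=0)


@dataclass
class EvidenceArray:
    """Ordered evidence columns for one (partially) merged set of reads."""

    loglik: np.ndarray      # (L, 4) float64
    gap_count: np.ndarray   # (L,)   int64
    coverage: np.ndarray    # (L,)   int64
    n_reads: int

    def __len__(self) -> int:
        return self.loglik.shape[0]

    def column(self, i: int) -> EvidenceColumn:
        return EvidenceColumn(loglik=self.loglik[i].copy(),
                              gap_count=int(self.gap_count[i]),
                              coverage=int(self.coverage[i]))


def read_to_evidence(read: SequenceRead) -> EvidenceArray:
    """Convert one read into a single-read evidence array.

    Observed base x with error probability e contributes log(1-e) to
    hypothesis x and log(e/3) to each other base (error mass split uniformly).
    'N' contributes log(1/4) to every hypothesis — no information — but still
    counts toward coverage.
    """
    if len(read) == 0:
        raise ValueError("cannot build evidence from an empty read")
    idx = seq_to_indices(read.bases)
    e = phred_to_error(read.qual_array)
    L = idx.size
    ll = np.repeat(np.log(e / 3.0)[:, None], 4, axis=1)
    rows = np.arange(L)
    called = idx < 4
    ll[rows[called], idx[called]] = np.log1p(-e[called])
    ll[~called, :] = LOG_QUARTER
    return EvidenceArray(
        loglik=ll,
        gap_count=np.zeros(L, dtype=np.int64),
        coverage=np.ones(L, dtype=np.int64),
        n_reads=1,
    )


def posterior_matrix(loglik: np.ndarray) -> np.ndarray:
    """Posterior over {A,C,G,T} per column under a uniform prior (softmax).

    Accepts (..., 4); an all-zero row (all-gap column) yields (1/4,)*4.
    """
    ll = np.asarray(loglik, dtype=np.float64)
    z = ll - ll.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    return p


def column_posterior(col: EvidenceColumn) -> np.ndarray:
    return posterior_matrix(col.loglik)


def similarity_matrix(arr: EvidenceArray) -> np.ndarray:
    """Per-column 5-vectors (p_A(1-g), p_C(1-g), p_G(1-g), p_T(1-g), g).

    g is the gap fraction among spanning reads.  Every column of a real array
    has at least one base observation, so the vector is never all-zero and its
    entries sum to 1.
    """
    if np.any(arr.coverage < 1):
        raise ValueError("similarity vector requires coverage >= 1 at every column")
    p = posterior_matrix(arr.loglik)
    g = arr.gap_count / arr.coverage
    v = np.empty((len(arr), 5))
    v[:, :4] = p * (1.0 - g)[:, None]
    v[:, 4] = g
    return v


def column_similarity_vector(col: EvidenceColumn) -> np.ndarray:
    if col.coverage < 1:
        raise ValueError("similarity vector requires coverage >= 1")
    g = col.gap_count / col.coverage
    v = np.empty(5)
    v[:4] = column_posterior(col) * (1.0 - g)
    v[4] = g
    return v


def merge_columns(a: EvidenceColumn, b: EvidenceColumn) -> EvidenceColumn:
    """Combine evidence from two aligned columns (element-wise addition)."""
    return EvidenceColumn(loglik=a.loglik + b.loglik,
                          gap_count=a.gap_count + b.gap_count,
                          coverage=a.coverage + b.coverage)


def merge_without_alignment(reads: Sequence[SequenceRead]) -> EvidenceArray:
    """Stack reads strictly by position index, no alignment.

    Array length is the longest read; shorter reads contribute nothing (not
    even coverage) past their own end.  This is the no-alignment baseline mode:
    a single indel in any read throws every downstream position out of phase.
    """
    if not reads:
        raise ValueError("merge_without_alignment requires at least one read")
    L = max(len(r) for r in reads)
    out = EvidenceArray(
        loglik=np.zeros((L, 4)),
        gap_count=np.zeros(L, dtype=np.int64),
        coverage=np.zeros(L, dtype=np.int64),
        n_reads=len(reads),
    )
    for read in reads:
        ev = read_to_evidence(read)
        n = len(ev)
        out.loglik[:n] += ev.loglik
        out.coverage[:n] += 1
    return out


def hard_calls(arr: EvidenceArray) -> str:
    """Maximum-posterior base per column; exact posterior ties give 'N'."""
    p = posterior_matrix(arr.loglik)
    best = p.argmax(axis=1).astype(np.int8)
    tie = (p == p.max(axis=1, keepdims=True)).sum(axis=1) > 1
    best[tie] = N_INDEX
    return indices_to_seq(best)
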