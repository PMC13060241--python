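"""Quality-aware global alignment of evidence arrays, and progressive merging.

The pairwise aligner is a Needleman–Wunsch variant modified for evidence
columns rather than letters: the match score between two columns is the cosine
similarity of their 5-component similarity vectors (posterior base weights
scaled by the non-gap fraction, plus the gap fraction), mapped linearly onto
[s_min, s_max].  Two confident identical columns score s_max; two confident
conflicting columns score close to s_min; ambiguous columns land in between,
so the DP weighs uncertain positions softly instead of forcing a hard call.

Gaps are affine (open + extend) and the DP is banded around the
length-proportional diagonal so that very long reads stay tractable; the band
doubles automatically (up to 4x) if the optimal path presses against its edge.

Progressive alignment folds reads one at a time into a growing evidence
profile, in descending order of similarity to an unaligned consensus — the
role a guide tree plays in homology MSA, but appropriate for reads that differ
only by sequencing error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .evidence import (
    EvidenceArray,
    hard_calls,
    merge_without_alignment,
    read_to_evidence,
    similarity_matrix,
)
from .fastq_io import SequenceRead

MATCH, DELETE, INSERT = 0, 1, 2  # DELETE consumes a column of `a`, INSERT of `b`

_NEG = -1.0e30


class BandOverflowError(RuntimeError):
    """Optimal alignment path could not be contained in the DP band."""


@dataclass
class AlignParams:
    """Scoring parameters for the evidence-array aligner.

    s_max / s_min bound the match score (cosine 1 -> s_max, cosine 0 -> s_min).
    Gap costs are affine: a gap of length k costs gap_open + (k-1)*gap_extend.
    band_width is the DP band half-width in columns; None means
    max(16, ceil(0.05 * L)) for the longer array.  free_end_gaps makes leading
    and trailing gaps cost-free (semi-global), for truncated-read data.
    """

    s_max: float = 1.0
    s_min: float = -1.0
    gap_open: float = -1.5
    gap_extend: float = -0.5
    band_width: Optional[int] = None
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if self.s_max <= self.s_min:
            raise ValueError("s_max must exceed s_min")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.band_width is not None and self.band_width < 1:
            raise ValueError("band_width must be >= 1")

    def resolve_band(self, length: int) -> int:
        if self.band_width is not None:
            return self.band_width
        return max(16, math.ceil(0.05 * length))


@dataclass
class AlignmentPath:
    """A global alignment between two evidence arrays.

    ``codes`` is the step sequence (MATCH/DELETE/INSERT) from start to end;
    ``score`` is the DP objective.
    """

    codes: np.ndarray  # int8
    score: float

    def steps(self) -> Iterator[Tuple[int, Optional[int], Optional[int]]]:
        """Yield (op, i, j): 0-based consumed column indices, None when gapped."""
        i = j = 0
        for code in self.codes:
            if code == MATCH:
                yield MATCH, i, j
                i += 1
                j += 1
            elif code == DELETE:
                yield DELETE, i, None
                i += 1
            else:
                yield INSERT, None, j
                j += 1


def match_score(col_a, col_b, params: AlignParams) -> float:
    """Scaled cosine similarity between two columns' similarity vectors."""
    from .evidence import column_similarity_vector

    va = column_similarity_vector(col_a)
    vb = column_similarity_vector(col_b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero similarity vector")
    c = float(va @ vb / (na * nb))
    return params.s_min + (params.s_max - params.s_min) * c


@njit(cache=True)
def _dp_banded(ua, ub, s_min, s_max, gap_open, gap_ext, w, free_ends):
    """Banded 3-state affine DP with traceback.

    ua/ub: unit-normalized (L, 5) similarity vectors.  Returns
    (score, codes, touched_edge) where codes runs start -> end and
    touched_edge flags a traceback cell on the band boundary at an interior
    column (signal to retry with a wider band).
    """
    L1 = ua.shape[0]
    L2 = ub.shape[0]
    W = 2 * w + 1
    span = s_max - s_min

    M = np.full((L1 + 1, W), _NEG)
    X = np.full((L1 + 1, W), _NEG)  # gap in b (last step DELETE)
    Y = np.full((L1 + 1, W), _NEG)  # gap in a (last step INSERT)
    pM = np.full((L1 + 1, W), np.uint8(9))
    pX = np.full((L1 + 1, W), np.uint8(9))
    pY = np.full((L1 + 1, W), np.uint8(9))

    lo = np.empty(L1 + 1, np.int64)
    for i in range(L1 + 1):
        c = (2 * i * L2 + L1) // (2 * L1)  # round(i * L2 / L1)
        lo[i] = c - w

    for i in range(L1 + 1):
        jlo = lo[i]
        if jlo < 0:
            jlo = 0
        jhi = lo[i] + W - 1
        if jhi > L2:
            jhi = L2
        for j in range(jlo, jhi + 1):
            k = j - lo[i]
            if i == 0 and j == 0:
                M[0, k] = 0.0
                continue
            # MATCH: from (i-1, j-1)
            if i > 0 and j > 0:
                kk = (j - 1) - lo[i - 1]
                if 0 <= kk < W:
                    best = M[i - 1, kk]
                    arg = np.uint8(0)
                    if X[i - 1, kk] > best:
                        best = X[i - 1, kk]
                        arg = np.uint8(1)
                    if Y[i - 1, kk] > best:
                        best = Y[i - 1, kk]
                        arg = np.uint8(2)
                    if best > _NEG * 0.5:
                        cos = 0.0
                        for t in range(5):
                            cos += ua[i - 1, t] * ub[j - 1, t]
                        M[i, k] = best + s_min + span * cos
                        pM[i, k] = arg
            # DELETE: consume a_{i-1}, from (i-1, j)
            if i > 0:
                kk = j - lo[i - 1]
                if 0 <= kk < W:
                    if free_ends and (j == 0 or j == L2):
                        op_pen = 0.0
                        ex_pen = 0.0
                    else:
                        op_pen = gap_open
                        ex_pen = gap_ext
                    best = M[i - 1, kk] + op_pen
                    arg = np.uint8(0)
                    if X[i - 1, kk] + ex_pen > best:
                        best = X[i - 1, kk] + ex_pen
                        arg = np.uint8(1)
                    if Y[i - 1, kk] + op_pen > best:
                        best = Y[i - 1, kk] + op_pen
                        arg = np.uint8(2)
                    if best > _NEG * 0.5:
                        X[i, k] = best
                        pX[i, k] = arg
            # INSERT: consume b_{j-1}, from (i, j-1)
            if j > 0:
                kk = (j - 1) - lo[i]
                if kk >= 0:
                    if free_ends and (i == 0 or i == L1):
                        op_pen = 0.0
                        ex_pen = 0.0
                    else:
                        op_pen = gap_open
                        ex_pen = gap_ext
                    best = M[i, kk] + op_pen
                    arg = np.uint8(0)
                    if Y[i, kk] + ex_pen > best:
                        best = Y[i, kk] + ex_pen
                        arg = np.uint8(2)
                    if X[i, kk] + op_pen > best:
                        best = X[i, kk] + op_pen
                        arg = np.uint8(1)
                    if best > _NEG * 0.5:
                        Y[i, k] = best
                        pY[i, k] = arg

    k_end = L2 - lo[L1]
    score = M[L1, k_end]
    state = np.uint8(0)
    if X[L1, k_end] > score:
        score = X[L1, k_end]
        state = np.uint8(1)
    if Y[L1, k_end] > score:
        score = Y[L1, k_end]
        state = np.uint8(2)

    codes = np.empty(L1 + L2, np.int8)
    pos = L1 + L2
    i, j = L1, L2
    touched = False
    while i > 0 or j > 0:
        k = j - lo[i]
        if 0 < j < L2 and 0 < i < L1 and (k == 0 or k == W - 1):
            touched = True
        pos -= 1
        if state == 0:
            codes[pos] = MATCH
            state = pM[i, k]
            i -= 1
            j -= 1
        elif state == 1:
            codes[pos] = DELETE
            state = pX[i, k]
            i -= 1
        else:
            codes[pos] = INSERT
            state = pY[i, k]
            j -= 1
    return score, codes[pos:].copy(), touched


def _unit_rows(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


def align_pair(a: EvidenceArray, b: EvidenceArray,
               params: Optional[AlignParams] = None) -> AlignmentPath:
    """Optimal banded global alignment of two evidence arrays.

    Deterministic tie-break: MATCH preferred over DELETE over INSERT, both at
    the end cell and at every traceback choice.
    """
    params = params or AlignParams()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty evidence array")
    ua = _unit_rows(similarity_matrix(a))
    ub = _unit_rows(similarity_matrix(b))
    w0 = params.resolve_band(max(len(a), len(b)))
    w = w0
    while True:
        score, codes, touched = _dp_banded(
            ua, ub, params.s_min, params.s_max,
            params.gap_open, params.gap_extend, w, params.free_end_gaps)
        if not touched:
            return AlignmentPath(codes=codes, score=float(score))
        if w >= 4 * w0:
            raise BandOverflowError(
                f"alignment path not contained in band (half-width {w})")
        w *= 2


def score_path(a: EvidenceArray, b: EvidenceArray, path: AlignmentPath,
               params: Optional[AlignParams] = None) -> float:
    """Recompute the DP objective along an explicit path (for verification)."""
    params = params or AlignParams()
    ua = _unit_rows(similarity_matrix(a))
    ub = _unit_rows(similarity_matrix(b))
    span = params.s_max - params.s_min
    total = 0.0
    prev = -1
    i = j = 0
    for code in path.codes:
        if code == MATCH:
            total += params.s_min + span * float(ua[i] @ ub[j])
            i += 1
            j += 1
        elif code == DELETE:
            free = params.free_end_gaps and (j == 0 or j == len(b))
            if not free:
                total += params.gap_extend if prev == DELETE else params.gap_open
            i += 1
        else:
            free = params.free_end_gaps and (i == 0 or i == len(a))
            if not free:
                total += params.gap_extend if prev == INSERT else params.gap_open
            j += 1
        prev = code
    if i != len(a) or j != len(b):
        raise ValueError("path does not cover both arrays")
    return total


def merge_aligned(a: EvidenceArray, b: EvidenceArray,
                  path: AlignmentPath) -> EvidenceArray:
    """Combine two arrays along an alignment path into one evidence array.

    MATCH columns add evidence element-wise.  A gap column inside an array's
    aligned span adds that array's read count to the gap and coverage channels;
    gaps outside the span (leading/trailing overhangs) contribute nothing, so
    a short read does not penalize columns it never observed.
    """
    codes = np.asarray(path.codes)
    consumes_a = codes != INSERT
    consumes_b = codes != DELETE
    if int(consumes_a.sum()) != len(a) or int(consumes_b.sum()) != len(b):
        raise ValueError("path length does not match arrays")
    S = codes.size
    ll = np.zeros((S, 4))
    gaps = np.zeros(S, dtype=np.int64)
    cov = np.zeros(S, dtype=np.int64)
    ll[consumes_a] += a.loglik
    gaps[consumes_a] += a.gap_count
    cov[consumes_a] += a.coverage
    ll[consumes_b] += b.loglik
    gaps[consumes_b] += b.gap_count
    cov[consumes_b] += b.coverage

    steps = np.arange(S)
    # At a step where one array is absent, that array's reads sit in a gap —
    # but only if the step falls inside the array's aligned span; overhangs
    # beyond a short read's ends contribute nothing.
    for consumes, n_gapped in ((consumes_b, b.n_reads), (consumes_a, a.n_reads)):
        gap_steps = steps[~consumes]
        if gap_steps.size == 0:
            continue
        idx = steps[consumes]
        first, last = idx[0], idx[-1]
        interior = gap_steps[(gap_steps > first) & (gap_steps < last)]
        gaps[interior] += n_gapped
        cov[interior] += n_gapped
    return EvidenceArray(loglik=ll, gap_count=gaps, coverage=cov,
                         n_reads=a.n_reads + b.n_reads)


def order_by_consensus_similarity(reads: Sequence[SequenceRead]) -> List[int]:
    """Read order for progressive alignment.

    Reads are scored by the fraction of positions agreeing with the hard calls
    of the unaligned consensus, over the overlap length; reads shorter than
    half the consensus go last.  Descending score, ties by input order.
    """
    calls = hard_calls(merge_without_alignment(reads))
    Lc = len(calls)
    scores = []
    for t, read in enumerate(reads):
        if len(read) < 0.5 * Lc:
            scores.append(-1.0)
            continue
        n = min(len(read), Lc)
        matches = sum(1 for x, y in zip(read.bases[:n], calls[:n]) if x == y)
        scores.append(matches / n)
    return sorted(range(len(reads)), key=lambda t: (-scores[t], t))


def progressive_align(reads: Sequence[SequenceRead],
                      params: Optional[AlignParams] = None) -> EvidenceArray:
    """Fold all reads of one barcode into a single evidence array.

    Order: descending similarity to the unaligned consensus (most typical
    reads first, so the early profile is reliable), then pairwise
    align-and-merge of each remaining read into the growing profile.
    """
    if not reads:
        raise ValueError("progressive_align requires at least one read")
    params = params or AlignParams()
    order = order_by_consensus_similarity(reads) if len(reads) > 1 else [0]
    arr = read_to_evidence(reads[order[0]])
    for t in order[1:]:
        ev = read_to_evidence(reads[t])
        path = align_pair(arr, ev, params)
        arr = merge_aligned(arr, ev, path)
    return arr
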