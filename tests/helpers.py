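"""Shared test utilities and independent oracles.

Every oracle here is written from first principles (direct probability
products, exhaustive/memoized path recursion, exact rational arithmetic) and
never calls the code path it is used to check.
"""
from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import List, Sequence, Tuple

import numpy as np

from bcar.fastq_io import SequenceRead

BASES = "ACGT"


def make_read(bases: str, quals=30, rid: str = "r") -> SequenceRead:
    if isinstance(quals, int):
        quals = [quals] * len(bases)
    return SequenceRead(id=rid, bases=bases, quals=bytes(quals))


def random_read(rng: np.random.Generator, length: int,
                qmin: int = 30, qmax: int = 40, rid: str = "r") -> SequenceRead:
    bases = "".join(BASES[i] for i in rng.integers(0, 4, length))
    quals = bytes(int(q) for q in rng.integers(qmin, qmax + 1, length))
    return SequenceRead(id=rid, bases=bases, quals=quals)


# ---------------------------------------------------------------------------
# Bayes oracle: posterior over the four true-base hypotheses by direct
# likelihood product.
# ---------------------------------------------------------------------------

def clamp_error(q: float) -> float:
    return min(max(10.0 ** (-q / 10.0), 1e-6), 0.75)


def posterior_bruteforce(observations: Sequence[Tuple[int, int]]) -> np.ndarray:
    """observations: list of (base_index 0-3 or 4 for N, phred Q).

    Returns the posterior 4-vector under a uniform prior, computed as the
    plain product of per-read likelihoods (no logs).
    """
    lik = np.ones(4, dtype=np.float64)
    for base, q in observations:
        e = clamp_error(q)
        if base == 4:
            lik *= 0.25
        else:
            per = np.full(4, e / 3.0)
            per[base] = 1.0 - e
            lik *= per
    return lik / lik.sum()


# ---------------------------------------------------------------------------
# Alignment oracle: exhaustive scoring of all global paths via memoized
# recursion over (i, j, previous step).
# ---------------------------------------------------------------------------

def single_read_unit_vectors(read: SequenceRead) -> np.ndarray:
    """Unit-norm 5-component similarity vectors for a single read, from
    first principles: (posterior * 1, gap fraction 0), normalized."""
    out = np.zeros((len(read), 5))
    for t, (b, q) in enumerate(zip(read.bases, read.quals)):
        e = clamp_error(q)
        if b == "N":
            p = np.full(4, 0.25)
        else:
            p = np.full(4, e / 3.0)
            p[BASES.index(b)] = 1.0 - e
            p /= p.sum()
        out[t, :4] = p
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def brute_force_align_score(ua: np.ndarray, ub: np.ndarray,
                            s_min: float = -1.0, s_max: float = 1.0,
                            gap_open: float = -1.5,
                            gap_extend: float = -0.5) -> float:
    """Maximum global alignment score over ALL paths (affine gaps).

    Recursion over suffixes with the previous step type as state; a gap step
    costs gap_extend when it continues a gap of the same kind and gap_open
    otherwise (including switching gap direction).
    """
    na, nb = ua.shape[0], ub.shape[0]
    span = s_max - s_min

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: int) -> float:
        if i == na and j == nb:
            return 0.0
        best = -np.inf
        if i < na and j < nb:
            s = s_min + span * float(ua[i] @ ub[j])
            best = max(best, s + rec(i + 1, j + 1, 0))
        if i < na:
            pen = gap_extend if last == 1 else gap_open
            best = max(best, pen + rec(i + 1, j, 1))
        if j < nb:
            pen = gap_extend if last == 2 else gap_open
            best = max(best, pen + rec(i, j + 1, 2))
        return best

    return rec(0, 0, -1)


def enumerate_paths_score(ua: np.ndarray, ub: np.ndarray,
                          s_min: float = -1.0, s_max: float = 1.0,
                          gap_open: float = -1.5,
                          gap_extend: float = -0.5) -> float:
    """Literal enumeration of every global path (tiny inputs only); used to
    cross-check the memoized oracle."""
    na, nb = ua.shape[0], ub.shape[0]
    span = s_max - s_min
    best = [-np.inf]

    def walk(i, j, last, acc):
        if i == na and j == nb:
            best[0] = max(best[0], acc)
            return
        if i < na and j < nb:
            walk(i + 1, j + 1, 0,
                 acc + s_min + span * float(ua[i] @ ub[j]))
        if i < na:
            walk(i + 1, j, 1, acc + (gap_extend if last == 1 else gap_open))
        if j < nb:
            walk(i, j + 1, 2, acc + (gap_extend if last == 2 else gap_open))

    walk(0, 0, -1, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Exact majority bound with rational arithmetic.
# ---------------------------------------------------------------------------

def majority_bound_exact(n: int, e: Fraction, L: int) -> Fraction:
    p = 1 - e  # probability a read is correct at one position
    k = (n + 1) // 2  # ceil(n/2)
    q = sum(Fraction(comb(n, x)) * p ** x * (1 - p) ** (n - x)
            for x in range(k, n + 1))
    return q ** L
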