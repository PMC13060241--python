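"""Consensus calling: evidence array -> sequence with Phred qualities.

Columns where a strict majority of spanning reads are gapped are removed
(they represent insertions carried by a minority of reads, or alignment
artifacts).  At each surviving column the maximum-posterior base is called;
its quality is the Phred encoding of the posterior error probability,
Q = -10 log10(1 - p*).  Positions without a posterior majority (p* < 0.5,
or an exact tie) are emitted as 'N' with a conventional no-call quality of 2.

No filtering is applied on read count or quality: singleton barcodes are
emitted and the caller decides what to keep.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .evidence import N_INDEX, EvidenceArray, indices_to_seq, posterior_matrix

MAJORITY = 0.5
N_QUAL = 2
# complement clamp: 10^-9.3 keeps Q at most 93 (the last printable character)
MIN_COMPLEMENT = 10.0 ** -9.3
MAX_QUAL = 93


@dataclass(frozen=True)
class ConsensusRecord:
    barcode: str
    bases: str
    quals: bytes  # raw integer Phred scores
    n_reads: int

    def __len__(self) -> int:
        return len(self.bases)


def posterior_to_phred(p_err: np.ndarray) -> np.ndarray:
    """Posterior error probability -> integer Phred, round half away from zero."""
    q = -10.0 * np.log10(np.maximum(p_err, MIN_COMPLEMENT))
    return np.minimum(np.floor(q + 0.5), MAX_QUAL).astype(np.int64)


def call_consensus(arr: EvidenceArray, barcode: str) -> ConsensusRecord:
    """Collapse a merged evidence array into one consensus record."""
    if len(arr) == 0:
        raise ValueError("cannot call consensus on an empty evidence array")
    keep = arr.gap_count * 2 <= arr.coverage  # drop strict gap majorities
    ll = arr.loglik[keep]
    p = posterior_matrix(ll)
    pmax = p.max(axis=1)
    best = p.argmax(axis=1).astype(np.int8)
    tie = (p == pmax[:, None]).sum(axis=1) > 1
    no_majority = tie | (pmax < MAJORITY)
    best[no_majority] = N_INDEX
    quals = posterior_to_phred(1.0 - pmax)
    quals[no_majority] = N_QUAL
    return ConsensusRecord(
        barcode=barcode,
        bases=indices_to_seq(best),
        quals=quals.astype(np.uint8).tobytes(),
        n_reads=arr.n_reads,
    )


def summarize_quality(rec: ConsensusRecord) -> Tuple[float, int]:
    """(mean Phred, min Phred) over the consensus positions."""
    if len(rec) == 0:
        raise ValueError("empty consensus record")
    q = np.frombuffer(rec.quals, dtype=np.uint8)
    return float(q.mean()), int(q.min())
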