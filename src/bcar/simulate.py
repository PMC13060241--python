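"""Read simulation with controlled error rates, and reconstruction evaluation.

The simulator emulates barcoded amplicon sequencing: each barcode tags one
random true sequence, and every read of that barcode is the (error-free)
barcode followed by an error-mutated copy of the insert.  Per insert base,
independently: the base is deleted with probability i/2; otherwise substituted
to a uniformly chosen different base with probability m; and before each
position a single uniform random base is inserted with probability i/2 — so
the total per-base indel rate is i, split evenly between insertions and
deletions.  Every insert base carries the constant quality
Q = round(-10 log10 max(m, 1e-6)), clamped to [2, 93]: the quality string is
consistent with the substitution rate, and indels (which Phred scores cannot
express) are left for the aligner to resolve.

The evaluator scores exact reconstruction (any 'N' or length difference is a
failure) and computes the analytic majority bound: the probability that at
every position at least half of the n reads carry the correct base, which is
a soft upper bound on exact-reconstruction accuracy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.stats import binom

from .consensus import ConsensusRecord
from .evidence import indices_to_seq
from .fastq_io import _open_text, encode_quals

BARCODE_QUAL = 40


@dataclass
class SimConfig:
    """Study-condition knobs for one simulated dataset."""

    L: int = 1000                # true insert length (bases)
    n_reads: int = 10            # reads per barcode
    n_barcodes: int = 1000
    m: float = 0.0               # per-base substitution (missense) rate
    i: float = 0.0               # per-base indel rate (split 50/50 ins/del)
    barcode_len: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.m < 1 and 0 <= self.i < 1):
            raise ValueError("error rates must lie in [0, 1)")
        if min(self.L, self.n_reads, self.n_barcodes, self.barcode_len) < 1:
            raise ValueError("all counts must be >= 1")

    @property
    def read_quality(self) -> int:
        q = round(-10.0 * math.log10(max(self.m, 1e-6)))
        return int(min(93, max(2, q)))


@dataclass
class SimulationTruth:
    """Barcode -> true insert sequence, plus realized error tallies."""

    sequences: Dict[str, str]
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    n_reads_total: int = 0

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def mean_indels_per_read(self) -> float:
        if self.n_reads_total == 0:
            return 0.0
        return (self.n_insertions + self.n_deletions) / self.n_reads_total


def expected_indels_per_read(L: int, indel_rate: float) -> float:
    """Mean indel count per read of length L at total per-base indel rate i."""
    return L * indel_rate


def _mutate(seq_idx: np.ndarray, m: float, i: float,
            rng: np.random.Generator) -> Tuple[np.ndarray, int, int, int]:
    """Apply substitution/indel errors to one read; returns (bases, n_sub, n_ins, n_del)."""
    L = seq_idx.size
    ins_mask = rng.random(L) < i / 2.0
    del_mask = rng.random(L) < i / 2.0
    sub_mask = (~del_mask) & (rng.random(L) < m)
    bases = seq_idx.copy()
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        bases[sub_mask] = (bases[sub_mask] + shift) % 4
    # interleave: slot 2p holds an optional inserted base, slot 2p+1 the base
    out = np.full(2 * L, -1, dtype=np.int8)
    if ins_mask.any():
        out[0::2][ins_mask] = rng.integers(0, 4, size=int(ins_mask.sum()))
    out[1::2][~del_mask] = bases[~del_mask]
    return (out[out >= 0], int(sub_mask.sum()),
            int(ins_mask.sum()), int(del_mask.sum()))


def simulate_dataset(cfg: SimConfig, fastq_path: Union[str, Path],
                     truth_path: Optional[Union[str, Path]] = None
                     ) -> SimulationTruth:
    """Write a simulated FASTQ (and optional truth TSV); returns the truth.

    Deterministic: the same config (including seed) produces byte-identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    barcodes = []
    seen = set()
    while len(barcodes) < cfg.n_barcodes:
        bc = indices_to_seq(rng.integers(0, 4, cfg.barcode_len).astype(np.int8))
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    truth = SimulationTruth(sequences={})
    bc_qual = encode_quals(bytes([BARCODE_QUAL]) * cfg.barcode_len)
    with _open_text(fastq_path, "w", None) as out:
        for bi, bc in enumerate(barcodes):
            true_idx = rng.integers(0, 4, cfg.L).astype(np.int8)
            truth.sequences[bc] = indices_to_seq(true_idx)
            for ri in range(cfg.n_reads):
                read_idx, n_sub, n_ins, n_del = _mutate(true_idx, cfg.m, cfg.i, rng)
                truth.n_substitutions += n_sub
                truth.n_insertions += n_ins
                truth.n_deletions += n_del
                truth.n_reads_total += 1
                insert = indices_to_seq(read_idx)
                qual = encode_quals(bytes([cfg.read_quality]) * len(insert))
                out.write(f"@bc{bi:05d}_r{ri:03d}\n{bc}{insert}\n+\n{bc_qual}{qual}\n")
    if truth_path is not None:
        write_truth(truth, truth_path)
    return truth


def write_truth(truth: SimulationTruth, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for bc, seq in truth.sequences.items():
            handle.write(f"{bc}\t{seq}\n")


def load_truth(path: Union[str, Path]) -> SimulationTruth:
    sequences: Dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            bc, seq = line.split("\t")
            sequences[bc] = seq
    return SimulationTruth(sequences=sequences)


def exact_match_rate(consensus: Union[Mapping[str, str], Iterable[ConsensusRecord]],
                     truth: SimulationTruth) -> float:
    """Fraction of truth barcodes reconstructed exactly.

    An 'N', any length difference, or a missing barcode counts as failure.
    """
    if not isinstance(consensus, Mapping):
        consensus = {rec.barcode: rec.bases for rec in consensus}
    if len(truth) == 0:
        return 0.0
    hits = sum(1 for bc, seq in truth.sequences.items()
               if consensus.get(bc) == seq)
    return hits / len(truth)


def majority_bound(n: int, e: float, L: int) -> float:
    """P(at every one of L positions, >= ceil(n/2) of n reads are correct).

    A read is correct at a position with probability 1-e; positions are
    independent.  This is the soft analytic ceiling on exact reconstruction:
    below a majority, no-call ('N') positions become likely.
    """
    if n < 1 or L < 1 or not (0 <= e < 1):
        raise ValueError("need n >= 1, L >= 1, 0 <= e < 1")
    k = math.ceil(n / 2)
    q = float(binom.sf(k - 1, n, 1.0 - e))
    return q ** L
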