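"""FASTQ input/output and barcode extraction.

Reads and writes 4-line FASTQ (plain or gzip, chosen by a ``.gz`` suffix or an
explicit flag) with Sanger/Phred+33 quality encoding, the convention of every
modern short- and long-read platform.  Qualities are held as raw integer Phred
scores in the range [0, 93] so that every score round-trips to a printable
ASCII character.

Barcodes are located either as a fixed-length prefix of each read (the default,
and the convention of the bundled simulator) or as a separate barcode FASTQ
iterated in lockstep with the read file.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("bcar")

PHRED_OFFSET = 33
MAX_QUAL = 93  # '~' is the last printable ASCII character (126 - 33)


class FastqFormatError(ValueError):
    """A FASTQ record violates the 4-line Phred+33 contract."""


@dataclass(frozen=True)
class SequenceRead:
    """One FASTQ record.

    ``quals`` stores raw integer Phred scores, one byte per base, so a
    million-record stream stays compact and conversion to numpy is free.
    """

    id: str
    bases: str
    quals: bytes

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FastqFormatError(
                f"record {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def qual_array(self) -> np.ndarray:
        return np.frombuffer(self.quals, dtype=np.uint8)


@dataclass(frozen=True)
class BarcodedRead:
    """A read split into its barcode and the remaining insert."""

    barcode: str
    insert: SequenceRead


def decode_quals(qual_str: str) -> bytes:
    """Phred+33 ASCII -> raw Phred bytes; rejects characters outside ['!','~']."""
    raw = qual_str.encode("ascii", errors="replace")
    arr = np.frombuffer(raw, dtype=np.uint8)
    if arr.size and (arr.min() < PHRED_OFFSET or arr.max() > PHRED_OFFSET + MAX_QUAL):
        bad = chr(arr[(arr < PHRED_OFFSET) | (arr > PHRED_OFFSET + MAX_QUAL)][0])
        raise FastqFormatError(f"quality character {bad!r} outside Phred+33 range")
    return (arr - PHRED_OFFSET).tobytes()


def encode_quals(quals: Union[bytes, Iterable[int]]) -> str:
    """Raw Phred scores -> Phred+33 ASCII string."""
    arr = np.frombuffer(bytes(quals), dtype=np.uint8)
    if arr.size and arr.max() > MAX_QUAL:
        raise ValueError(f"Phred score {int(arr.max())} exceeds {MAX_QUAL}")
    return (arr + PHRED_OFFSET).tobytes().decode("ascii")


def _open_text(path: Union[str, Path], mode: str, gzipped: Optional[bool]) -> IO[str]:
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: Union[str, Path], gzipped: Optional[bool] = None) -> Iterator[SequenceRead]:
    """Stream SequenceReads from a 4-line FASTQ file.

    Malformed records (base/quality length mismatch, quality characters outside
    the printable Phred+33 range, truncated records) raise
    :class:`FastqFormatError` naming the 1-based record index.
    """
    with _open_text(path, "r", gzipped) as handle:
        index = 0
        parser = FastqGeneralIterator(handle)
        while True:
            index += 1
            try:
                title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython's malformed-record errors
                raise FastqFormatError(f"record {index}: {exc}") from exc
            try:
                yield SequenceRead(id=title, bases=seq.upper(), quals=decode_quals(qual))
            except FastqFormatError as exc:
                raise FastqFormatError(f"record {index}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRead], path: Union[str, Path],
                gzipped: Optional[bool] = None) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "w", gzipped) as handle:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.bases}\n+\n{encode_quals(rec.quals)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Barcode extraction
# ---------------------------------------------------------------------------

def extract_barcode(read: SequenceRead, barcode_length: int) -> Optional[BarcodedRead]:
    """Split off the first ``barcode_length`` bases as the barcode.

    Returns None (caller should count the skip) when the read is not strictly
    longer than the barcode, i.e. there is no insert left to map.
    """
    if len(read) <= barcode_length:
        return None
    insert = SequenceRead(
        id=read.id,
        bases=read.bases[barcode_length:],
        quals=read.quals[barcode_length:],
    )
    return BarcodedRead(barcode=read.bases[:barcode_length], insert=insert)


class BarcodeExtractor:
    """Iterate BarcodedReads from a read stream, counting skipped reads.

    Prefix mode takes the leading ``barcode_length`` bases of each read;
    paired mode takes the full bases of the matching record in a separate
    barcode FASTQ (the insert is then the whole read).
    """

    def __init__(self, barcode_length: int = 16):
        self.barcode_length = barcode_length
        self.skipped = 0

    def from_prefix(self, reads: Iterable[SequenceRead]) -> Iterator[BarcodedRead]:
        for read in reads:
            br = extract_barcode(read, self.barcode_length)
            if br is None:
                self.skipped += 1
                continue
            yield br
        if self.skipped:
            logger.info("skipped %d reads shorter than the %d bp barcode",
                        self.skipped, self.barcode_length)

    def from_pairs(self, reads: Iterable[SequenceRead],
                   barcodes: Iterable[SequenceRead]) -> Iterator[BarcodedRead]:
        reads_it, bc_it = iter(reads), iter(barcodes)
        for read in reads_it:
            try:
                bc = next(bc_it)
            except StopIteration:
                raise FastqFormatError(
                    "barcode FASTQ has fewer records than the read FASTQ")
            yield BarcodedRead(barcode=bc.bases, insert=read)
        if next(bc_it, None) is not None:
            raise FastqFormatError("barcode FASTQ has more records than the read FASTQ")


# ---------------------------------------------------------------------------
# Consensus output
# ---------------------------------------------------------------------------

def write_consensus_fastq(records, path: Union[str, Path],
                          gzipped: Optional[bool] = None) -> int:
    """Write ConsensusRecords as FASTQ: id = barcode, comment ``reads=<n>``."""
    n = 0
    with _open_text(path, "w", gzipped) as handle:
        for rec in records:
            handle.write(
                f"@{rec.barcode} reads={rec.n_reads}\n{rec.bases}\n+\n"
                f"{encode_quals(rec.quals)}\n"
            )
            n += 1
    return n
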