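"""External (disk-based) sort of barcoded reads, and grouping by barcode.

Datasets can exceed memory by orders of magnitude, so reads are sorted in
bounded chunks that are spilled to disk and then k-way merged — the classic
external merge sort.  The sort key is the barcode (lexicographic, bytewise on
A<C<G<N<T is irrelevant: any total order works since grouping only needs equal
barcodes adjacent); ties keep input order so the whole pipeline is
deterministic.

Chunk files use the same 4-line FASTQ dialect with the barcode prepended to
the record id (``@<barcode> <original header>``) so intermediate state is
inspectable with standard tools.
"""
from __future__ import annotations

import heapq
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple

from .fastq_io import BarcodedRead, SequenceRead, read_fastq, write_fastq

logger = logging.getLogger("bcar")

# Upper bound on simultaneously open chunk files during a merge pass; chunk
# counts beyond this trigger cascaded merge passes.
MERGE_FANIN = 256


@dataclass
class SortConfig:
    chunk_size: int = 1_000_000
    tmp_dir: Optional[str] = None
    keep_tmp: bool = False

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


def _chunk_record(br: BarcodedRead) -> SequenceRead:
    return SequenceRead(id=f"{br.barcode} {br.insert.id}",
                        bases=br.insert.bases, quals=br.insert.quals)


def _unchunk_record(rec: SequenceRead) -> BarcodedRead:
    barcode, _, rest = rec.id.partition(" ")
    return BarcodedRead(barcode=barcode,
                        insert=SequenceRead(id=rest, bases=rec.bases, quals=rec.quals))


def write_sorted_chunks(reads: Iterable[BarcodedRead], cfg: SortConfig,
                        workdir: Path) -> List[Path]:
    """Spill the stream into per-chunk FASTQ files, each sorted by barcode."""
    paths: List[Path] = []
    buf: List[BarcodedRead] = []

    def flush() -> None:
        if not buf:
            return
        buf.sort(key=lambda br: br.barcode)  # list.sort is stable
        path = workdir / f"chunk_{len(paths):06d}.fastq"
        write_fastq((_chunk_record(br) for br in buf), path)
        paths.append(path)
        buf.clear()

    for br in reads:
        buf.append(br)
        if len(buf) >= cfg.chunk_size:
            flush()
    flush()
    return paths


def _iter_chunk(path: Path) -> Iterator[BarcodedRead]:
    for rec in read_fastq(path):
        yield _unchunk_record(rec)


def _merge_streams(streams: List[Iterator[BarcodedRead]]) -> Iterator[BarcodedRead]:
    """Stable k-way merge: ties broken by stream index (= chunk order)."""
    heap: List[Tuple[str, int, BarcodedRead]] = []
    for idx, stream in enumerate(streams):
        first = next(stream, None)
        if first is not None:
            heap.append((first.barcode, idx, first))
    heapq.heapify(heap)
    while heap:
        barcode, idx, br = heapq.heappop(heap)
        yield br
        nxt = next(streams[idx], None)
        if nxt is not None:
            heapq.heappush(heap, (nxt.barcode, idx, nxt))


def merge_chunks(paths: List[Path], workdir: Path,
                 fanin: int = MERGE_FANIN) -> Iterator[BarcodedRead]:
    """Merge sorted chunk files; cascades when more than ``fanin`` chunks exist."""
    paths = list(paths)
    passno = 0
    while len(paths) > fanin:
        merged: List[Path] = []
        for start in range(0, len(paths), fanin):
            group = paths[start:start + fanin]
            out = workdir / f"merge_{passno:03d}_{len(merged):06d}.fastq"
            write_fastq((_chunk_record(br)
                         for br in _merge_streams([_iter_chunk(p) for p in group])),
                        out)
            merged.append(out)
        paths = merged
        passno += 1
    yield from _merge_streams([_iter_chunk(p) for p in paths])


def sort_by_barcode(reads: Iterable[BarcodedRead],
                    cfg: Optional[SortConfig] = None) -> Iterator[BarcodedRead]:
    """Yield the input reads in non-decreasing barcode order (stable).

    At most ``cfg.chunk_size`` records are buffered in memory, plus one record
    per chunk during the merge.  The scratch directory must be writable; the
    OSError propagates otherwise.
    """
    cfg = cfg or SortConfig()
    workdir = Path(tempfile.mkdtemp(prefix="bcar_sort_", dir=cfg.tmp_dir))
    try:
        paths = write_sorted_chunks(reads, cfg, workdir)
        logger.debug("external sort: %d chunk files in %s", len(paths), workdir)
        yield from merge_chunks(paths, workdir)
    finally:
        if cfg.keep_tmp:
            logger.info("keeping sort scratch directory %s", workdir)
        else:
            shutil.rmtree(workdir, ignore_errors=True)


def group_by_barcode(sorted_reads: Iterable[BarcodedRead]
                     ) -> Iterator[Tuple[str, List[SequenceRead]]]:
    """Group a barcode-sorted stream into (barcode, [inserts]) batches.

    Raises ValueError if the input turns out not to be sorted.
    """
    current: Optional[str] = None
    batch: List[SequenceRead] = []
    for br in sorted_reads:
        if current is None:
            current = br.barcode
        elif br.barcode != current:
            if br.barcode < current:
                raise ValueError(
                    f"input not sorted by barcode: {br.barcode!r} after {current!r}")
            yield current, batch
            current, batch = br.barcode, []
        batch.append(br.insert)
    if current is not None:
        yield current, batch
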