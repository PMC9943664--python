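"""Adapter and quality trimming of raw CLIP / small-RNA reads.

The 3' quality trimmer implements the partial-sums rule (the BWA-style rule
behind ``cutadapt -q``): subtract the threshold from each base quality, take
cumulative sums from the 3' end, and cut at the position minimising that sum.
The adapter trimmer removes the best semi-global suffix(read)/prefix(adapter)
match with an error budget proportional to the overlap.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    seq: str
    qual: str  # PHRED+33 unless stated otherwise

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    def phred(self, offset: int = 33) -> list[int]:
        return [ord(c) - offset for c in self.qual]


@dataclass
class TrimReport:
    reads_in: int = 0
    reads_out: int = 0
    adapter_trimmed: int = 0
    bases_quality_trimmed: int = 0

    @property
    def mean_bases_quality_trimmed(self) -> float:
        return self.bases_quality_trimmed / self.reads_in if self.reads_in else 0.0


def quality_trim_3prime(read: FastqRead, threshold: int = 30, phred_offset: int = 33) -> FastqRead:
    """Cut the read at the 3' position minimising the running sum of
    (quality - threshold) taken from the 3' end.  Keeping the whole read
    scores 0, so a read is never lengthened and high-quality reads pass
    unchanged; ties prefer the longer read."""
    quals = read.phred(phred_offset)
    best_cut = len(read)  # cut index = retained prefix length
    best_sum = 0
    running = 0
    for i in range(len(read) - 1, -1, -1):
        running += quals[i] - threshold
        if running < best_sum:
            best_sum = running
            best_cut = i
    return replace(read, seq=read.seq[:best_cut], qual=read.qual[:best_cut])


def _adapter_match(seq: str, adapter: str, max_error_rate: float, min_overlap: int) -> int | None:
    """Start position of the best suffix/prefix adapter match, or None.

    Candidates at position p align read[p:] against adapter[:overlap]; a
    candidate is valid when mismatches <= floor(max_error_rate * overlap).
    'Best' maximises matched bases (overlap - mismatches); ties go to the
    leftmost (longest) match.
    """
    n = len(seq)
    best_p: int | None = None
    best_score = -1
    for p in range(0, n - min_overlap + 1):
        overlap = min(n - p, len(adapter))
        window = seq[p : p + overlap]
        mism = sum(a != b for a, b in zip(window, adapter[:overlap]))
        if mism > int(max_error_rate * overlap):
            continue
        score = overlap - mism
        if score > best_score:  # strict: leftmost wins ties via scan order
            best_score = score
            best_p = p
    return best_p


def adapter_trim_3prime(
    read: FastqRead,
    adapter: str = DEFAULT_ADAPTER,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[FastqRead, bool]:
    """Remove a 3' adapter; returns (trimmed read, whether anything was cut)."""
    p = _adapter_match(read.seq.upper(), adapter.upper(), max_error_rate, min_overlap)
    if p is None:
        return read, False
    return replace(read, seq=read.seq[:p], qual=read.qual[:p]), True


def length_filter(reads: Iterable[FastqRead], min_len: int, max_len: int) -> list[FastqRead]:
    """Keep reads with min_len <= length <= max_len (both inclusive)."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse_duplicates(reads: Iterable[FastqRead]) -> list[FastqRead]:
    """Optional exact-sequence deduplication (first occurrence kept)."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def trim_reads(
    reads: Iterable[FastqRead],
    adapter: str | None = DEFAULT_ADAPTER,
    quality_threshold: int = 30,
    min_len: int = 1,
    max_len: int | None = None,
    adapter_first: bool = True,
    phred_offset: int = 33,
) -> tuple[list[FastqRead], TrimReport]:
    """Adapter then quality trimming (order configurable), then length filter."""
    report = TrimReport()
    out: list[FastqRead] = []
    for read in reads:
        report.reads_in += 1
        r = read
        steps = ("adapter", "quality") if adapter_first else ("quality", "adapter")
        for step in steps:
            if step == "adapter" and adapter:
                r, cut = adapter_trim_3prime(r, adapter)
                report.adapter_trimmed += cut
            elif step == "quality":
                before = len(r)
                r = quality_trim_3prime(r, quality_threshold, phred_offset)
                report.bases_quality_trimmed += before - len(r)
        if min_len <= len(r) <= (max_len if max_len is not None else len(r)):
            report.reads_out += 1
            out.append(r)
    return out, report


# ---------------------------------------------------------------------------
# FASTQ I/O (gz-transparent)


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield FastqRead(header.rstrip("\n")[1:].split()[0], seq, qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
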