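"""Ungapped all-best-hit short-read alignment over an ordered tier stack.

The contract is end-to-end Hamming alignment with a global mismatch budget
(bowtie ``-v``-style): for each read, every position on every target where
the whole read aligns with at most ``max_mismatches`` substitutions is a
candidate, and all candidates achieving the *minimum* observed mismatch
count are reported.  ``N`` in the read mismatches every reference base.

Implementation: pigeonhole k-mer seeding.  With budget m, a read of length L
split into m+1 non-overlapping seeds of length floor(L/(m+1)) must place at
least one seed exactly whenever a valid alignment exists, so exact seed
lookups followed by full verification are guaranteed to enumerate the same
hit set as an exhaustive per-position Hamming scan.

Hierarchical mapping applies the same engine tier by tier: a read claimed by
tier i is never aligned to later tiers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .preprocess import FastqRead
from .reference import ReferenceTier

_VALID_READ = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlignmentError(ValueError):
    pass


class Hit(NamedTuple):
    target_id: str
    start: int  # 0-based offset on the forward target sequence
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class ReadHitSet:
    read_id: str
    tier: str
    hits: list[Hit]

    @property
    def min_mismatches(self) -> int:
        return self.hits[0].mismatches if self.hits else -1


@dataclass
class TierAssignment:
    counts: dict[str, int] = field(default_factory=dict)
    unmapped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unmapped


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, or limit+1 on early exit.
    An N on either side counts as a mismatch."""
    mism = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mism += 1
            if mism > limit:
                return mism
    return mism


class _KmerIndex:
    """Exact k-mer positions over a set of target sequences (forward strand).
    k-mers containing N are not indexed (they can never match an exact seed)."""

    def __init__(self, sequences: Mapping[str, str], k: int):
        self.k = k
        self.sequences = sequences
        self.lookup: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self.lookup[kmer].append((tid, i))


def _search_oriented(index: _KmerIndex, oriented: str, max_mismatches: int) -> list[tuple[str, int, int]]:
    """All (target, start, mismatches) placements of ``oriented`` (already in
    target-strand orientation) with mismatches <= budget."""
    L = len(oriented)
    if L <= max_mismatches:
        # pigeonhole needs >= budget+1 seeds; degenerate reads get a full scan
        out = []
        for tid, seq in index.sequences.items():
            for start in range(len(seq) - L + 1):
                mism = _hamming_within(oriented, seq[start : start + L], max_mismatches)
                if mism <= max_mismatches:
                    out.append((tid, start, mism))
        return out
    k = index.k
    n_seeds = max_mismatches + 1
    candidates: set[tuple[str, int]] = set()
    for s in range(n_seeds):
        off = s * k
        seed = oriented[off : off + k]
        if len(seed) < k:
            break
        for tid, pos in index.lookup.get(seed, ()):
            start = pos - off
            if start < 0:
                continue
            if start + L <= len(index.sequences[tid]):
                candidates.add((tid, start))
    out = []
    for tid, start in candidates:
        mism = _hamming_within(oriented, index.sequences[tid][start : start + L], max_mismatches)
        if mism <= max_mismatches:
            out.append((tid, start, mism))
    return out


def align_to_tier(
    reads: Sequence[FastqRead],
    tier: ReferenceTier,
    max_mismatches: int = 2,
    both_strands: bool = False,
) -> list[ReadHitSet]:
    """All equally-best end-to-end hits per read against one tier.

    Targets shorter than a read are skipped for that read.  Hit ordering is
    deterministic: (target_id, start, strand).  Reads with no valid placement
    yield an empty hit list.
    """
    indexes: dict[int, _KmerIndex] = {}
    results = []
    for read in reads:
        seq = read.seq.upper()
        if set(seq) - _VALID_READ:
            raise AlignmentError(f"read {read.read_id} contains non-ACGTN characters")
        L = len(seq)
        hits: list[Hit] = []
        if L:
            k = max(1, L // (max_mismatches + 1))
            if k not in indexes:
                indexes[k] = _KmerIndex(tier.sequences, k)
            index = indexes[k]
            for tid, start, mism in _search_oriented(index, seq, max_mismatches):
                hits.append(Hit(tid, start, "+", mism))
            if both_strands:
                rc = reverse_complement(seq)
                for tid, start, mism in _search_oriented(index, rc, max_mismatches):
                    hits.append(Hit(tid, start, "-", mism))
        if hits:
            best = min(h.mismatches for h in hits)
            hits = sorted(
                (h for h in hits if h.mismatches == best),
                key=lambda h: (h.target_id, h.start, h.strand),
            )
        results.append(ReadHitSet(read.read_id, tier.name, hits))
    return results


# Tiers aligned sense-only by default: CLIP reads are sense to the transcript.
# Genome and mitochondrial tiers search both strands.
DEFAULT_STRAND_MODE = {
    "snRNA_rRNA": False,
    "mature_tRNA": False,
    "immature_tRNA": False,
    "mitochondrial": True,
    "genome": True,
}


def map_hierarchically(
    reads: Sequence[FastqRead],
    tier_stack: Sequence[ReferenceTier],
    max_mismatches: int = 2,
    strand_mode: Mapping[str, bool] | None = None,
) -> tuple[dict[str, ReadHitSet], TierAssignment]:
    """Sequential mapping: each read is claimed by the first tier with >= 1
    hit and never aligned to later tiers; the rest cascade.  Returns per-read
    hit sets (mapped reads only) and the conserved per-tier read counts."""
    strand_mode = dict(DEFAULT_STRAND_MODE, **(strand_mode or {}))
    assignment = TierAssignment(counts={t.name: 0 for t in tier_stack})
    mapped: dict[str, ReadHitSet] = {}
    remaining = list(reads)
    for tier in tier_stack:
        if not remaining:
            break
        hitsets = align_to_tier(remaining, tier, max_mismatches, strand_mode.get(tier.name, False))
        next_round = []
        for read, hs in zip(remaining, hitsets):
            if hs.hits:
                mapped[read.read_id] = hs
                assignment.counts[tier.name] += 1
            else:
                next_round.append(read)
        remaining = next_round
    assignment.unmapped = len(remaining)
    return mapped, assignment


def write_sam(
    hitsets: Iterable[ReadHitSet],
    tier: ReferenceTier,
    reads: Mapping[str, FastqRead],
    path: str | Path,
) -> None:
    """One SAM line per hit; co-optimal hits beyond the first carry the
    secondary flag (0x100)."""
    import pysam

    names = sorted(tier.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(tier.sequences[n])} for n in names],
    }
    ref_index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hs in hitsets:
            read = reads[hs.read_id]
            for i, hit in enumerate(hs.hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = hs.read_id
                flag = 0
                if hit.strand == "-":
                    flag |= 0x10
                if i > 0:
                    flag |= 0x100
                a.flag = flag
                a.reference_id = ref_index[hit.target_id]
                a.reference_start = hit.start
                a.mapping_quality = 255
                a.cigarstring = f"{len(read.seq)}M"
                seq = read.seq if hit.strand == "+" else reverse_complement(read.seq)
                qual = read.qual if hit.strand == "+" else read.qual[::-1]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qual)
                a.set_tag("NM", hit.mismatches)
                out.write(a)


def write_tier_summary(assignment: TierAssignment, path: str | Path) -> None:
    import pandas as pd

    rows = [{"tier": name, "reads": n} for name, n in assignment.counts.items()]
    rows.append({"tier": "unmapped", "reads": assignment.unmapped})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
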