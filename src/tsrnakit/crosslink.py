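"""Crosslink-site inference on mature tRNAs and normalized metaprofiles.

In truncation-based CLIP the reverse transcriptase stops one base 3' of the
crosslinked nucleotide, so the crosslink position is (read start - 1) in
mature-tRNA coordinates.  A uniquely placed read gives the position
directly; a read with several candidate starts within its consensus group
takes the strict mode of the pooled starts; with no strict mode a start is
drawn uniformly (seeded) from the distinct candidates.  Position -1 is legal
and kept: it is the base 5' of the reference start (the appended G is
position 0).

Metaprofile values are per-group, per-position crosslink counts divided by
the total number of tRNA-mapped reads in the sample, so the profile over all
groups sums to (calls / total) <= 1.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ReadHitSet
from .multimap import UNRESOLVED, IsoacceptorGrouping


@dataclass(frozen=True)
class CrosslinkCall:
    read_id: str
    group: str
    position: int  # 0-based on mature tRNA coordinates; -1 allowed
    method: str  # unique | mode | random


@dataclass
class CrosslinkProfile:
    values: dict[str, dict[int, float]]  # group -> position -> normalized value
    sample_total_trna_reads: int

    def total_mass(self) -> float:
        return sum(v for g in self.values.values() for v in g.values())


def _strict_mode(starts: Sequence[int]) -> int | None:
    """Unique most-frequent value, or None on a tie among top counts."""
    counts = Counter(starts)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def call_crosslink(
    read_id: str,
    group: str,
    starts: Sequence[int],
    rng: np.random.Generator,
) -> CrosslinkCall:
    """Crosslink call from the pooled candidate start positions of one read
    (one entry per hit, multiplicity preserved)."""
    if not starts:
        raise ValueError(f"read {read_id}: no candidate starts")
    if len(set(starts)) == 1:
        method = "unique" if len(starts) == 1 else "mode"
        return CrosslinkCall(read_id, group, starts[0] - 1, method)
    mode = _strict_mode(starts)
    if mode is not None:
        return CrosslinkCall(read_id, group, mode - 1, "mode")
    choice = int(rng.choice(sorted(set(starts))))
    return CrosslinkCall(read_id, group, choice - 1, "random")


def call_crosslinks(
    hitsets: Mapping[str, ReadHitSet],
    grouping: IsoacceptorGrouping,
    gene_to_isoacceptor: Mapping[str, str],
    seed: int,
) -> tuple[list[CrosslinkCall], list[str]]:
    """Per-read crosslink calls for reads assigned to a consensus group.

    Candidate starts are pooled across member-gene hits with multiplicity.
    Returns (calls, skipped read ids); calls + skipped = tRNA-assigned reads.
    """
    rng = np.random.default_rng(seed)
    calls: list[CrosslinkCall] = []
    skipped: list[str] = []
    for read_id in sorted(grouping.read_assignment):
        group = grouping.read_assignment[read_id]
        if group == UNRESOLVED:
            skipped.append(read_id)
            continue
        hs = hitsets.get(read_id)
        if hs is None or not hs.hits:
            skipped.append(read_id)
            continue
        starts = [h.start for h in hs.hits if h.target_id in gene_to_isoacceptor]
        if not starts:
            skipped.append(read_id)
            continue
        calls.append(call_crosslink(read_id, group, starts, rng))
    return calls, skipped


def build_metaprofile(
    calls: Iterable[CrosslinkCall], sample_total_trna_reads: int
) -> CrosslinkProfile:
    """Sum calls per (group, position) and normalize by the sample's total
    tRNA-mapped read count."""
    if sample_total_trna_reads < 0:
        raise ValueError("sample_total_trna_reads must be >= 0")
    counts: dict[str, Counter] = defaultdict(Counter)
    for c in calls:
        counts[c.group][c.position] += 1
    total = sample_total_trna_reads
    if total == 0:
        if counts:
            raise ValueError("crosslink calls present but sample total is zero")
        return CrosslinkProfile({}, 0)
    values = {
        g: {pos: n / total for pos, n in sorted(pos_counts.items())}
        for g, pos_counts in counts.items()
    }
    return CrosslinkProfile(values, total)


def positional_metaplot(
    positions: Sequence[int],
    loop_intervals: Mapping[str, tuple[int, int]] | None = None,
    fractional_lengths: Sequence[int] | None = None,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Whole-tRNA positional profile: normalized abundance of 5' positions
    on a common mature-tRNA coordinate scale, with loop labels attached.

    ``loop_intervals`` maps loop names (D / AC / T) to 0-based half-open
    position intervals.  With ``fractional_lengths`` given (one mature-tRNA
    length per call) positions are scaled to [0, 1) and binned instead.
    """
    if len(positions) == 0:
        return pd.DataFrame(columns=["position", "abundance", "loop"])
    if fractional_lengths is not None:
        frac = np.asarray(positions) / np.asarray(fractional_lengths)
        binned = np.floor(frac * n_bins).astype(int)
        counts = Counter(binned)
        total = len(positions)
        return pd.DataFrame(
            [
                {"position": b / n_bins, "abundance": n / total, "loop": ""}
                for b, n in sorted(counts.items())
            ]
        )
    counts = Counter(positions)
    total = len(positions)

    def loop_of(pos: int) -> str:
        for name, (s, e) in (loop_intervals or {}).items():
            if s <= pos < e:
                return name
        return ""

    return pd.DataFrame(
        [
            {"position": pos, "abundance": n / total, "loop": loop_of(pos)}
            for pos, n in sorted(counts.items())
        ]
    )


def iclip_expression_foldchange(
    iclip_abundance: Mapping[str, float],
    rnaseq_abundance: Mapping[str, float],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-isoacceptor (or group) fold change: normalized CLIP abundance over
    normalized RNA-seq abundance.  Zero-denominator entries are reported as
    missing unless a pseudocount is supplied."""
    keys = sorted(set(iclip_abundance) | set(rnaseq_abundance))
    rows = []
    for k in keys:
        num = iclip_abundance.get(k, 0.0) + pseudocount
        den = rnaseq_abundance.get(k, 0.0) + pseudocount
        fc = num / den if den > 0 else np.nan
        rows.append({"group": k, "iclip": iclip_abundance.get(k, 0.0),
                     "rnaseq": rnaseq_abundance.get(k, 0.0), "fold_change": fc})
    return pd.DataFrame(rows)


def profile_table(profile: CrosslinkProfile) -> pd.DataFrame:
    rows = []
    for group in sorted(profile.values):
        for pos, val in sorted(profile.values[group].items()):
            rows.append(
                {
                    "group": group,
                    "position": pos,
                    "count": round(val * profile.sample_total_trna_reads),
                    "normalized": val,
                }
            )
    return pd.DataFrame(rows, columns=["group", "position", "count", "normalized"])
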