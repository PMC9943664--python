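"""Resolution of reads multi-mapping across tRNA genes.

tRNA genes within an isoacceptor are nearly identical, so CLIP reads rarely
pin down a single gene.  The strategy: keep only least-mismatch hits, label
each read with the set of isoacceptors it hits, then greedily merge
isoacceptors into consensus groups until a target fraction of multi-mapping
reads is assignable to a single group.  A read is assigned to group G iff
its isoacceptor set is a subset of G; reads spanning groups stay UNRESOLVED
and are reported but excluded from downstream counts.

The merge rule (the gap the original description leaves open) is greedy
agglomeration: at each step merge the pair of groups that newly resolves the
most reads; when no merge resolves anything (reads spanning >= 3 groups),
merge the pair with the highest co-occurrence among unresolved reads' label
sets.  Ties break on the lexicographic order of the merged group name, so
the merge log is deterministic and independent of input ordering.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import Hit, ReadHitSet

UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class LabelledRead:
    read_id: str
    hit_genes: frozenset[str]
    isoacceptor_set: frozenset[str]
    min_mismatches: int

    def __post_init__(self) -> None:
        if not self.hit_genes:
            raise ValueError(f"read {self.read_id}: empty hit gene set")

    @property
    def is_multimapping(self) -> bool:
        return len(self.hit_genes) > 1


def group_name(labels: Iterable[str]) -> str:
    return "/".join(sorted(labels))


@dataclass
class MergeStep:
    merged: tuple[str, str]  # names of the two groups merged
    result: str  # name of the resulting group
    gain: int  # newly resolved multi-mapping reads
    resolved_fraction: float


@dataclass
class IsoacceptorGrouping:
    groups: list[frozenset[str]]
    read_assignment: dict[str, str]  # read_id -> group name or UNRESOLVED
    resolved_fraction: float
    threshold: float
    merge_log: list[MergeStep] = field(default_factory=list)

    def group_of(self, labels: frozenset[str]) -> str:
        for g in self.groups:
            if labels <= g:
                return group_name(g)
        return UNRESOLVED


def filter_least_mismatch(hits: Sequence[Hit]) -> list[Hit]:
    """Discard hits with more than the read's minimum mismatch count."""
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    return [h for h in hits if h.mismatches == best]


def label_reads(
    hitsets: Iterable[ReadHitSet],
    gene_to_isoacceptor: Mapping[str, str],
) -> list[LabelledRead]:
    """Least-mismatch filtering followed by isoacceptor labelling.  Hit sets
    with no gene present in the annotation map are skipped."""
    out = []
    for hs in hitsets:
        kept = filter_least_mismatch(hs.hits)
        genes = frozenset(h.target_id for h in kept if h.target_id in gene_to_isoacceptor)
        if not genes:
            continue
        labels = frozenset(gene_to_isoacceptor[g] for g in genes)
        best = min(h.mismatches for h in kept)
        out.append(LabelledRead(hs.read_id, genes, labels, best))
    return out


def _resolved_fraction(
    multi_sets: Sequence[frozenset[str]], groups: Sequence[frozenset[str]]
) -> float:
    if not multi_sets:
        return 1.0
    resolved = sum(1 for s in multi_sets if any(s <= g for g in groups))
    return resolved / len(multi_sets)


def derive_consensus_groups(
    labelled_reads: Sequence[LabelledRead],
    threshold: float = 0.90,
) -> IsoacceptorGrouping:
    """Greedy agglomeration until ``resolved_fraction`` >= threshold or a
    single group remains.  The fraction's denominator is the number of
    multi-mapping reads only — uniquely mapping reads are trivially retained.
    With no multi-mapping reads the singleton grouping is returned with
    resolved_fraction 1."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    universe = sorted({label for r in labelled_reads for label in r.isoacceptor_set})
    groups: list[frozenset[str]] = [frozenset([u]) for u in universe]
    multi_sets = [r.isoacceptor_set for r in labelled_reads if r.is_multimapping]
    merge_log: list[MergeStep] = []
    frac = _resolved_fraction(multi_sets, groups)

    while frac < threshold and len(groups) > 1:
        unresolved = [s for s in multi_sets if not any(s <= g for g in groups)]

        def gain_of(g1: frozenset[str], g2: frozenset[str]) -> int:
            union = g1 | g2
            return sum(1 for s in unresolved if s <= union)

        def cooccurrence(g1: frozenset[str], g2: frozenset[str]) -> int:
            return sum(1 for s in unresolved if (s & g1) and (s & g2))

        pairs = list(itertools.combinations(range(len(groups)), 2))
        gains = {ij: gain_of(groups[ij[0]], groups[ij[1]]) for ij in pairs}
        max_gain = max(gains.values())
        if max_gain > 0:
            candidates = [ij for ij in pairs if gains[ij] == max_gain]
        else:
            # no single merge resolves anything (reads span >= 3 groups):
            # fall back to the most co-occurring pair
            cooc = {ij: cooccurrence(groups[ij[0]], groups[ij[1]]) for ij in pairs}
            max_cooc = max(cooc.values())
            candidates = [ij for ij in pairs if cooc[ij] == max_cooc]
        i, j = min(candidates, key=lambda ij: group_name(groups[ij[0]] | groups[ij[1]]))
        g1, g2 = groups[i], groups[j]
        merged = g1 | g2
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)] + [merged]
        groups.sort(key=group_name)
        frac = _resolved_fraction(multi_sets, groups)
        merge_log.append(
            MergeStep(
                merged=tuple(sorted((group_name(g1), group_name(g2)))),
                result=group_name(merged),
                gain=gain_of(g1, g2),
                resolved_fraction=frac,
            )
        )

    grouping = IsoacceptorGrouping(
        groups=groups,
        read_assignment={},
        resolved_fraction=frac,
        threshold=threshold,
        merge_log=merge_log,
    )
    grouping.read_assignment = assign_reads(grouping, labelled_reads)
    return grouping


def assign_reads(
    grouping: IsoacceptorGrouping, labelled_reads: Sequence[LabelledRead]
) -> dict[str, str]:
    """read -> unique group containing its whole isoacceptor set, else
    UNRESOLVED.  Groups partition the label universe, so the containing
    group, when it exists, is unique."""
    return {r.read_id: grouping.group_of(r.isoacceptor_set) for r in labelled_reads}


# ---------------------------------------------------------------------------
# tabular output


def grouping_tables(grouping: IsoacceptorGrouping) -> tuple[pd.DataFrame, pd.DataFrame]:
    groups_df = pd.DataFrame(
        [
            {"group_name": group_name(g), "members": ",".join(sorted(g))}
            for g in grouping.groups
        ]
    )
    assign_df = pd.DataFrame(
        sorted(grouping.read_assignment.items()), columns=["read_id", "group"]
    )
    return groups_df, assign_df


def write_grouping(grouping: IsoacceptorGrouping, prefix: str | Path) -> None:
    prefix = Path(prefix)
    groups_df, assign_df = grouping_tables(grouping)
    groups_df.to_csv(prefix.with_suffix(".groups.tsv"), sep="\t", index=False)
    assign_df.to_csv(prefix.with_suffix(".assignments.tsv"), sep="\t", index=False)
    log = [
        {
            "merged": list(step.merged),
            "result": step.result,
            "gain": step.gain,
            "resolved_fraction": step.resolved_fraction,
        }
        for step in grouping.merge_log
    ]
    with open(prefix.with_suffix(".merge_log.json"), "w") as fh:
        json.dump(
            {
                "threshold": grouping.threshold,
                "resolved_fraction": grouping.resolved_fraction,
                "merges": log,
            },
            fh,
            indent=2,
        )
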