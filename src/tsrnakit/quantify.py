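"""tRNA-cluster abundance in small-RNA-seq libraries and condition fold
changes (tracer-tRNA experiments: helicase-displaced fragments vs the
heat-denatured library of the same replicate)."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ReadHitSet


@dataclass
class ClusterAbundance:
    library_id: str
    counts: dict[str, int]
    depth: int  # reads mapped to the cluster reference (default depth notion)

    @property
    def normalized(self) -> dict[str, float]:
        if self.depth == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / self.depth for c, n in self.counts.items()}


def quantify_clusters(
    assignments: Mapping[str, str] | Iterable[tuple[str, str]],
    cluster_ids: Sequence[str],
    library_id: str = "library",
    depth: int | None = None,
) -> ClusterAbundance:
    """Counts per cluster from read -> cluster assignments.

    ``depth`` defaults to the number of assigned (mapped) reads; pass the
    raw-read count to normalize by total sequencing depth instead.
    Zero-count clusters are retained in the table.
    """
    items = assignments.items() if isinstance(assignments, Mapping) else assignments
    counts = Counter(cluster for _, cluster in items)
    full = {c: counts.get(c, 0) for c in cluster_ids}
    mapped = sum(full.values())
    return ClusterAbundance(library_id, full, depth if depth is not None else mapped)


def condition_foldchange(
    treated: ClusterAbundance, reference: ClusterAbundance
) -> pd.DataFrame:
    """Per-cluster fold change of normalized abundance, treated / reference.
    Pairing is per replicate: callers pass matched libraries.  Zero reference
    abundance yields a missing value."""
    t = treated.normalized
    r = reference.normalized
    clusters = sorted(set(t) | set(r))
    rows = []
    for c in clusters:
        denom = r.get(c, 0.0)
        fc = t.get(c, 0.0) / denom if denom > 0 else np.nan
        rows.append({"cluster_id": c, "treated": t.get(c, 0.0),
                     "reference": r.get(c, 0.0), "fold_change": fc})
    return pd.DataFrame(rows)


def log2_relative_abundance_table(
    abundances: Sequence[ClusterAbundance],
) -> pd.DataFrame:
    """Heat-map-ready matrix: log2 normalized abundance per cluster (rows) per
    library (columns), rows ordered by mean descending.  Zero abundances are
    missing on the log scale."""
    cols = {}
    for ab in abundances:
        norm = ab.normalized
        cols[ab.library_id] = {
            c: (np.log2(v) if v > 0 else np.nan) for c, v in norm.items()
        }
    df = pd.DataFrame(cols)
    order = df.mean(axis=1, skipna=True).sort_values(ascending=False).index
    return df.loc[order]
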