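import itertools

import numpy as np
import pytest

from tsrnakit import simulate as sim
from tsrnakit.reference import TrnaGene, build_mature_trna_tier


@pytest.fixture(scope="session")
def trna_family():
    """Three isoacceptors x two genes, near-identical within a family."""
    genes, ann = sim.simulate_trna_family(
        3, 2, length=72, intra_similarity=0.98, inter_similarity=0.6, seed=7
    )
    return genes, ann


@pytest.fixture(scope="session")
def mature_tier(trna_family):
    genes, _ = trna_family
    return build_mature_trna_tier(genes)


def brute_force_align(seq, sequences, max_mismatches, both_strands=False):
    """Exhaustive per-position Hamming oracle (N mismatches everything).
    Returns the full min-mismatch hit set, ordered like the engine."""
    from tsrnakit.align import reverse_complement

    def ham(a, b):
        return sum(x != y or x == "N" for x, y in zip(a, b))

    hits = []
    queries = [(seq, "+")] + ([(reverse_complement(seq), "-")] if both_strands else [])
    for q, strand in queries:
        for tid, target in sequences.items():
            for start in range(len(target) - len(q) + 1):
                m = ham(q, target[start : start + len(q)])
                if m <= max_mismatches:
                    hits.append((tid, start, strand, m))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return sorted((h for h in hits if h[3] == best), key=lambda h: (h[0], h[1], h[2]))
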