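# tsrnakit

Toolkit for studying how stress-induced tRNA fragments (tsRNAs) are made and
handled: an ncRNA-aware hierarchical CLIP read-mapping pipeline with
tRNA multi-mapping resolution and crosslink-site inference, tsRNA abundance
and fold-change quantification from small-RNA-seq, RNA-helicase unwinding
and binding kinetics fits, and a stress-proteomics enrichment procedure.
Every stage ships with a synthetic-data generator that plants known ground
truth, so the whole pipeline is testable without any external sequencing or
mass-spectrometry data.

## Who this is for

Groups analysing CLIP or small-RNA-seq data over tRNA space (where
near-identical isodecoders make conventional mapping unreliable), and
biochemists quantifying helicase activity on nicked-tRNA substrates or
ranking proteins that co-migrate with tsRNA-containing RNPs under stress.

## The core methods

**Hierarchical mapping with isoacceptor consensus groups.** Reads are
aligned end-to-end (ungapped, ≤ 2 mismatches, all equally-best hits) against
an ordered reference stack — snRNA/rRNA → mature tRNA (spliced body with 5′ G
and 3′ CCA added) → immature tRNA (unspliced + 50 nt flanks) → mitochondrial
→ genome — and each read is claimed by the first tier that hits. Within the
tRNA tier, multi-mapping reads are labelled with the isoacceptors they hit
(after least-mismatch filtering) and isoacceptors are greedily merged into
consensus groups until ≥ 90% of multi-mapping reads are assignable to a
single group. Crosslink positions are called as (read start − 1) — the
truncation signature of iCLIP — using the strict mode of candidate starts for
multi-mapped reads, with a seeded random draw when no mode exists.
Metaprofile values are crosslink counts per group and position divided by the
sample's total tRNA-mapped reads.

**Kinetics.** Unwinding time courses follow the integrated first-order rate
law `Frac_ss = A·(1 − e^(−k·t))`; equilibrium binding follows the one-site
isotherm `B = Bmax·[P]/(Kd + [P])`. Both are fitted by bounded nonlinear
least squares with asymptotic standard errors.

**Proteomics.** Per-sample fraction intensities are summed, anchor-normalized
within each experimental group to the mean of three cytoskeletal proteins
(ACTB, TBA1B, TBB4B), log2-transformed, imputed per column from a
downshifted normal (mean − 1.8 sd, width 0.3 sd), and ranked by
log2 enrichment (mean stress − mean control), keeping proteins with ≥ 2
observed values in at least one group.

## Worked example

Simulate a tRNA family, plant crosslinks, map, resolve, and call sites:

```python
from tsrnakit import simulate as sim
from tsrnakit.align import map_hierarchically
from tsrnakit.crosslink import build_metaprofile, call_crosslinks
from tsrnakit.multimap import derive_consensus_groups, label_reads
from tsrnakit.reference import build_mature_trna_tier

genes, ann = sim.simulate_trna_family(3, 2, seed=7)       # 3 isoacceptors x 2 genes
sites = {g.gene_id: 25 for g in genes}                     # planted crosslinks
reads, truth = sim.simulate_clip_reads(genes, sites, 200, 30, 0.0, seed=1)

tier = build_mature_trna_tier(genes)
hitsets, assignment = map_hierarchically(reads, [tier])
g2i = dict(zip(ann["gene_id"], ann["isoacceptor"]))
grouping = derive_consensus_groups(label_reads(hitsets.values(), g2i), 0.9)
calls, skipped = call_crosslinks(hitsets, grouping, g2i, seed=0)
recovered = sum(c.position == truth.read_origins[c.read_id].crosslink for c in calls)
print(assignment.counts, grouping.resolved_fraction, f"{recovered}/{len(calls)}")
```

prints

```
{'mature_tRNA': 200} 1.0 200/200
```

— all 200 reads land in the mature-tRNA tier, every multi-mapping read is
resolved without any isoacceptor merge (the three families are distinct
enough), and every crosslink call equals its planted position.

Fitting a simulated unwinding curve from the command line:

```
$ tsrnakit kinetics simulate --kind unwinding --k 0.4347 --amplitude 0.4982 --seed 1 --out unw.csv
$ tsrnakit kinetics fit-unwinding unw.csv
{"k_unw_per_min": 0.4228, "amplitude": 0.5025, "se_k": 0.0130, "se_amplitude": 0.0039, ...}
```

The fitted rate (0.423 ± 0.013 min⁻¹) and plateau (50.3 ± 0.4%) recover the
generating parameters (0.4347 min⁻¹, 49.82%) within noise.

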