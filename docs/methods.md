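# Methods

This note records the models implemented in tsrnakit, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
design choices made where the underlying procedures left the design open.

## Reference model

tRNA genes are loaded from a tab-delimited annotation (gene_id, isoacceptor,
chrom, start, end, strand, introns) plus contig FASTA; a BED12 converter is
provided. Coordinates are 0-based half-open; minus-strand genes are
reverse-complemented at load; sequences are stored in the DNA alphabet
(U → T). The mature tier appends a 3′ CCA and a 5′ G to every spliced body.
The G addition is applied unconditionally — canonically only tRNA-His
carries G−1, but the mapping reference treats all tRNAs alike, and a flag
(`add_g=False`) disables it. A body already ending in CCA still receives
another CCA; the rule is a reference-preparation convention, not a repair
step. The immature tier keeps introns and adds up to 50 nt of genomic flank
per side, truncated at contig ends. The collapsed cluster reference for
small-RNA-seq merges genes with byte-identical spliced bodies; the cluster
representative is that sequence plus CCA.

The tier stack is strictly ordered: snRNA/rRNA, mature tRNA, immature tRNA,
mitochondrial, genome. Missing tiers are skipped; a missing or empty mature
tier is an error because every downstream tRNA analysis depends on it.

## Read preprocessing

3′ quality trimming uses the partial-sums rule (the algorithm behind
`cutadapt -q` / BWA): subtract the threshold (default Q30, PHRED+33) from
each quality, accumulate from the 3′ end, and cut where the running sum is
minimal; ties keep the longer read, so trimming is idempotent and never
lengthens a read. Adapter trimming removes the best semi-global
suffix(read)/prefix(adapter) match (default adapter: the standard Illumina
TruSeq R1 sequence) with mismatches ≤ 0.1 × overlap and overlap ≥ 3;
"best" maximises matched bases, ties going to the leftmost (longest) match.
Adapter runs before quality trimming by default — the upstream tools take
both flags in one invocation without specifying an order, so the order is
exposed as a parameter. Length filtering is inclusive on both bounds
(tsRNA-sized cDNAs: 20–40 nt). An optional exact-duplicate collapser exists
and is off by default; UMI handling is out of scope (reanalysed CLIP
libraries are treated as already demultiplexed and deduplicated).

## Alignment engine

The contract is end-to-end ungapped alignment with a global mismatch budget
(default 2): for a read of length L, every placement on every target with
Hamming distance ≤ 2 is a candidate, and all placements achieving the
minimum distance are reported, in deterministic (target, start, strand)
order. `N` mismatches everything, on either side. Indels and partial
(local) alignments are deliberately unsupported — short tsRNA-sized reads
against a compact ncRNA reference do not need them, and the all-best-hits
semantics is what the multi-mapping resolution downstream consumes.

Implementation: pigeonhole seeding. The read is split into
`budget + 1` non-overlapping seeds of length `floor(L/(budget+1))`; any
valid placement must place at least one seed exactly, so exact k-mer lookup
plus full verification enumerates exactly the brute-force hit set (property-
and acceptance-tested against an exhaustive per-position scan). Reads no
longer than the budget fall back to a full scan, where the pigeonhole
guarantee does not apply. Mature/immature tRNA and snRNA/rRNA tiers are
searched sense-only by default (CLIP reads are sense to the transcript);
genome and mitochondrial tiers search both strands.

Hierarchical mapping assigns each read to the first tier with ≥ 1 hit;
later tiers never see it. Tier counts plus the unmapped count always sum to
the input reads.

## Multi-mapping resolution

Per read, hits above the minimum mismatch count are dropped, then the hit
genes are mapped to isoacceptor labels. A read is *resolved* when its label
set fits inside one group of the current partition. The retention target
(default 90%) is the fraction of multi-mapping reads (reads hitting > 1
gene) that are resolved; uniquely-mapping reads are trivially retained and
excluded from the denominator, and with no multi-mapping reads the fraction
is defined as 1.

The grouping algorithm is greedy agglomeration, chosen because the
published description specifies the goal (groups of genes that commonly
multi-map, data-driven, per sample) but not the algorithm. Starting from
singleton isoacceptor groups, repeatedly merge the pair of groups whose
union newly resolves the most reads; if no pair resolves anything (reads
spanning ≥ 3 groups), merge the pair with the highest co-occurrence among
unresolved reads' label sets; all ties break on the lexicographic order of
the merged group name. The merge log is therefore deterministic and
independent of input order, and the resolved fraction is non-decreasing
along it (merges only coarsen the partition). Iteration stops at the
threshold or when one group remains. Unresolved reads are reported and
excluded from downstream counts rather than fractionally allocated —
EM-style allocation is a non-goal. Grouping operates at isoacceptor level
only; isodecoder-level splitting is not attempted.

## Crosslink analysis

The truncation convention: the reverse transcriptase stops one base 3′ of
the crosslinked nucleotide, so crosslink = read start − 1 in mature-tRNA
coordinates. Position −1 (upstream of the added 5′ G) is legal and
reported, not clipped. For reads with several candidate starts within their
group, starts are pooled across member-gene hits with multiplicity and the
strict mode is taken; a tie among top counts means "no mode" and a start is
drawn uniformly at random (seeded) from the distinct candidates — the
existence of a random fallback implies the mode must be strict.

Metaprofiles divide per-(group, position) call counts by the sample's total
tRNA-mapped reads, so the total profile mass equals calls/total ≤ 1 exactly.
Profiles are indexed in absolute mature-tRNA coordinates by default
(shorter group members are simply right-padded); a fractional-coordinate
mode (position/length, binned) exists for whole-tRNA metaplots, where
D-/AC-/T-loop interval labels can be attached. CLIP-vs-expression fold
changes are ratios of normalized abundances; zero denominators are reported
as missing rather than infinite (a pseudocount option exists, off by
default).

## tsRNA quantification

Cluster abundance is count / depth, where depth defaults to reads mapped to
the cluster reference; normalising by raw-read depth instead is a flag,
since the depth notion is a convention rather than something the procedure
pins down. Fold changes are computed per replicate pair (treated library
over the matched heat-denatured reference library) on normalized
abundances; zero-reference clusters give missing values. The heat-map table
is log2 of normalized abundance with rows ordered by descending mean; zero
abundances are missing on the log scale, never −inf.

## Kinetics

Unwinding: Frac_ss(t) = A·(1 − e^(−kt)), with k in min⁻¹ and A the plateau
fraction in [0, 1]. Fraction single-stranded from band intensities is
I_ss/(I_ds + I_ss). Baseline subtraction (for assays with spontaneous
displacement at t = 0) is frac(t) ← max(0, frac(t) − frac(0)) per
replicate. Technical duplicates are averaged before fitting; biological
replicates are pooled into one residual vector (per-replicate fits are
available by subsetting). Fits use scipy's bounded trust-region
least squares with A ∈ [0, 1.5] (soft upper bound beyond the physical 1 to
avoid boundary artefacts), k > 0, initialised at A₀ = max observed fraction
and k₀ from a log-linear regression of −ln(1 − y/A₀) on t. Standard errors
are asymptotic (from the scaled covariance). Non-convergence is flagged on
the result, never silently replaced. At least 3 distinct timepoints are
required.

Binding: B([P]) = Bmax·[P]/(Kd + [P]), nM scale, fitted the same way with
Bmax ∈ (0, 1.5]; the nonspecific linear term is omitted (one-site *specific*
binding taken literally). Amplitudes and bound fractions are handled as
fractions internally throughout; percent is a display scale.

Parameter recovery at the assay design (8 timepoints over 0–30 min, 3
replicates, noise sd 0.02; 8 concentrations over 0.1×–10× Kd, noise sd
0.03) is unbiased to within a few percent in the median; note that ±2
estimated-SE intervals at ~22 residual degrees of freedom cover the truth
slightly below the Gaussian nominal rate, as expected for
estimated-variance intervals.

## Proteomics enrichment

Five steps, in order: (i) sum the 4 fraction intensities per sample;
(ii) within each group (3 control, 3 stress), rescale each sample by
(its anchor mean / the group's grand anchor mean), equalising the mean of
ACTB/TBA1B/TBB4B across the group's samples — cross-group anchor levels are
*not* forced equal, so a residual between-group scale survives by design;
(iii) log2, zeros → missing; (iv) per-column imputation from
Normal(mean − 1.8·sd, (0.3·sd)²) — the distribution family is given by the
procedure, the downshift/width are the conventional defaults and are
exposed as parameters; (v) enrichment = mean(stress) − mean(control) on the
log2 scale, keeping proteins with ≥ 2 observed (pre-imputation) values in
at least one group. Imputed values participate in the means (imputation
would otherwise be purposeless) but never count toward validity, and rows
containing any imputed value are flagged.

Known limitation: downshifted-normal imputation draws from a distribution
whose sd is the whole column's spread, so a low-abundance protein missing
in several samples of one group can acquire a spurious enrichment of the
same order as a genuine 2–4-fold effect. The flags make such rows easy to
segregate; the ranking property of the enrichment statistic itself is
tested in the no-dropout regime.

## Synthetic data: what it emulates, and what it does not

Generators are seeded per operation (no global RNG state); a fixed seed
gives byte-identical outputs.

- **tRNA families**: ~72 nt bodies, pairwise identity ≥ 0.98 within an
  isoacceptor and ≤ 0.60 between (defaults), both verified empirically
  after generation with bounded retries. Very low inter-family similarity
  (< 0.3) uses a rotation construction limited to ≤ 4 families. Not
  emulated: cloverleaf secondary structure, modification-induced
  misincorporation patterns, isodecoder phylogeny.
- **CLIP reads**: hard truncation exactly one base 3′ of the planted
  crosslink, substitution-only errors (the alignment contract is ungapped),
  constant Q40 qualities except for an optional planted low-quality 3′ tail
  used to exercise the quality trimmer. No RT drop-off distribution beyond
  the hard stop, no ligation biases.
- **Kinetic/binding curves**: exact model plus Gaussian noise, clipped to
  [0, 1] as measured fractions are; defaults match the assay design above.
- **Proteomics**: log-normal base abundances (log2 ~ N(25, 2.5)), three
  anchors at constant high abundance (never missing, no measurement noise —
  they are the normalizers), per-sample day/machine scale factors
  (sd 0.3 log2), planted log2 effects in the stress group, and dropout
  driven by the measurement's own intensity (30% in the bottom abundance
  quartile, one tenth elsewhere, defaults). Each sample intensity is split
  over 4 fractions by a Dirichlet draw so fraction summation is exact.

Passing tests on these fixtures demonstrate the pipeline's correctness
under its stated contracts (exact truncation, substitution-only errors,
one-site binding, first-order unwinding, missing-at-low-intensity), not
robustness to structure-dependent cleavage preferences, modification
chemistry, gapped alignments or peptide-level quantification artefacts.

## Numerical conventions

Ties and degenerate inputs are resolved deterministically everywhere:
lexicographic tie-breaks in grouping, longest-read ties in trimming,
sorted-candidate seeded draws in crosslink calling, sorted hit ordering in
alignment. Zero denominators produce missing values, not infinities
(fold changes, log2 of zero). Empty inputs return empty outputs where
meaningful and raise explicit errors where analysis would be vacuous
(empty gene set, empty mature tier, both band intensities zero).
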