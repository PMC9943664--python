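"""Tiered ncRNA reference construction.

Hierarchical CLIP mapping claims each read with the first reference tier it
hits, in a fixed order: abundant snRNA/rRNA species first, then mature tRNAs
(spliced body with the 3' CCA tail and a 5' G appended), then immature tRNAs
(unspliced gene plus genomic flanks), then the mitochondrial chromosome, and
finally the (toy-scale) genome.  Small-RNA-seq quantification instead uses a
*collapsed* tRNA reference in which genes with identical genomic sequence are
merged into one cluster whose representative carries the CCA tail.

Coordinates are 0-based half-open throughout; minus-strand genes are
reverse-complemented at load; references are stored in the DNA alphabet
(U -> T at load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TIER_ORDER = ("snRNA_rRNA", "mature_tRNA", "immature_tRNA", "mitochondrial", "genome")

_DNA = set("ACGT")


class ReferenceError(ValueError):
    """Raised for malformed reference inputs."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _check_dna(seq: str, what: str) -> str:
    seq = _normalize(seq)
    bad = set(seq) - _DNA
    if bad:
        raise ReferenceError(f"{what} contains non-ACGT(U) characters: {sorted(bad)}")
    return seq


@dataclass
class TrnaGene:
    """One tRNA gene with enough context to build every reference tier.

    ``body`` is the spliced gene body (mature sense, DNA alphabet);
    ``unspliced`` retains introns; ``upstream``/``downstream`` are genomic
    flank sequences already oriented to the gene's strand.
    """

    gene_id: str
    isoacceptor: str
    body: str
    unspliced: str | None = None
    upstream: str = ""
    downstream: str = ""

    def __post_init__(self) -> None:
        self.body = _check_dna(self.body, f"gene {self.gene_id}")
        if self.unspliced is None:
            self.unspliced = self.body
        else:
            self.unspliced = _check_dna(self.unspliced, f"gene {self.gene_id} (unspliced)")
        self.upstream = _normalize(self.upstream)
        self.downstream = _normalize(self.downstream)

    @property
    def has_intron(self) -> bool:
        return self.unspliced != self.body

    def mature_sequence(self, add_g: bool = True) -> str:
        """Spliced body with 3' CCA appended and (by default) a 5' G.

        The CCA/G additions are unconditional: a body already ending in CCA
        still receives another CCA, mirroring the mature-tRNA preparation
        rule applied before mapping.
        """
        prefix = "G" if add_g else ""
        return prefix + self.body + "CCA"

    def immature_sequence(self, flank: int = 50) -> str:
        """Unspliced gene with up to ``flank`` nt of genomic context per side."""
        if flank < 0:
            raise ReferenceError("flank must be >= 0")
        up = self.upstream[-flank:] if flank else ""
        down = self.downstream[:flank] if flank else ""
        return up + self.unspliced + down


@dataclass
class ReferenceTier:
    tier_index: int
    name: str
    sequences: dict[str, str]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class TrnaCluster:
    cluster_id: str
    member_gene_ids: frozenset[str]
    representative_sequence: str


def build_mature_trna_tier(genes: Sequence[TrnaGene], add_g: bool = True) -> ReferenceTier:
    """Mature-tRNA tier: per gene, ``G + spliced body + CCA``."""
    if not genes:
        raise ReferenceError("cannot build a mature tRNA tier from zero genes")
    seqs = {g.gene_id: g.mature_sequence(add_g=add_g) for g in genes}
    return ReferenceTier(TIER_ORDER.index("mature_tRNA"), "mature_tRNA", seqs)


def build_immature_trna_tier(genes: Sequence[TrnaGene], flank: int = 50) -> ReferenceTier:
    """Immature-tRNA tier: unspliced gene plus genomic flanks (truncated at
    contig ends — a gene at a contig start simply has a shorter upstream)."""
    if not genes:
        raise ReferenceError("cannot build an immature tRNA tier from zero genes")
    seqs = {g.gene_id: g.immature_sequence(flank=flank) for g in genes}
    return ReferenceTier(TIER_ORDER.index("immature_tRNA"), "immature_tRNA", seqs)


def fasta_tier(name: str, sequences: Mapping[str, str]) -> ReferenceTier:
    if name not in TIER_ORDER:
        raise ReferenceError(f"unknown tier name {name!r}; expected one of {TIER_ORDER}")
    seqs = {sid: _check_dna(s, f"{name} record {sid}") for sid, s in sequences.items()}
    return ReferenceTier(TIER_ORDER.index(name), name, seqs)


def assemble_tier_stack(
    snrna_rrna: Mapping[str, str] | None = None,
    mature: ReferenceTier | None = None,
    immature: ReferenceTier | None = None,
    mito: Mapping[str, str] | None = None,
    genome: Mapping[str, str] | None = None,
) -> list[ReferenceTier]:
    """Ordered tier stack; missing tiers are skipped, but the mature-tRNA tier
    is mandatory (without it no tRNA analysis is possible)."""
    if mature is None or len(mature) == 0:
        raise ReferenceError("mature tRNA tier is required and must be non-empty")
    stack: list[ReferenceTier] = []
    if snrna_rrna:
        stack.append(fasta_tier("snRNA_rRNA", snrna_rrna))
    stack.append(mature)
    if immature is not None and len(immature):
        stack.append(immature)
    if mito:
        stack.append(fasta_tier("mitochondrial", mito))
    if genome:
        stack.append(fasta_tier("genome", genome))
    stack.sort(key=lambda t: t.tier_index)
    return stack


def collapse_trna_clusters(genes: Sequence[TrnaGene]) -> list[TrnaCluster]:
    """Merge genes with identical (spliced) genomic sequence; the cluster
    representative is that sequence with CCA appended."""
    by_seq: dict[str, list[str]] = {}
    for g in genes:
        by_seq.setdefault(g.body, []).append(g.gene_id)
    clusters = []
    for i, (seq, members) in enumerate(sorted(by_seq.items(), key=lambda kv: sorted(kv[1])[0])):
        name = sorted(members)[0] if len(members) == 1 else f"cluster{i + 1}"
        clusters.append(TrnaCluster(name, frozenset(members), seq + "CCA"))
    return clusters


# ---------------------------------------------------------------------------
# annotation / FASTA I/O

ANNOTATION_COLUMNS = ["gene_id", "isoacceptor", "chrom", "start", "end", "strand", "introns"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Tab-delimited gene annotation.

    Columns: gene_id, isoacceptor, chrom, start, end, strand, introns.
    ``introns`` lists 0-based half-open intervals *relative to the oriented
    gene body* as ``s-e`` joined by ``;`` ('' or '.' for none).
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(ANNOTATION_COLUMNS[:6]) - set(ann.columns)
    if missing:
        raise ReferenceError(f"annotation is missing columns: {sorted(missing)}")
    if "introns" not in ann.columns:
        ann["introns"] = ""
    ann["start"] = ann["start"].astype(int)
    ann["end"] = ann["end"].astype(int)
    ann["introns"] = ann["introns"].fillna("")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def _parse_introns(text: str) -> list[tuple[int, int]]:
    text = (text or "").strip()
    if text in ("", "."):
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return sorted(out)


def genes_from_annotation(ann: pd.DataFrame, contigs: Mapping[str, str]) -> list[TrnaGene]:
    """Materialise TrnaGene objects from an annotation table plus contig
    sequences.  Minus-strand genes are reverse-complemented; flank sequences
    are extracted oriented to the gene and truncated at contig ends."""
    genes = []
    for row in ann.itertuples(index=False):
        contig = _normalize(contigs[row.chrom])
        if not (0 <= row.start < row.end <= len(contig)):
            raise ReferenceError(f"gene {row.gene_id} exceeds contig {row.chrom} bounds")
        unspliced = contig[row.start : row.end]
        up = contig[: row.start]
        down = contig[row.end :]
        if row.strand == "-":
            unspliced = str(Seq(unspliced).reverse_complement())
            up, down = (
                str(Seq(down).reverse_complement()),
                str(Seq(up).reverse_complement()),
            )
        introns = _parse_introns(getattr(row, "introns", ""))
        body = unspliced
        for s, e in reversed(introns):
            body = body[:s] + body[e:]
        genes.append(
            TrnaGene(
                gene_id=row.gene_id,
                isoacceptor=row.isoacceptor,
                body=body,
                unspliced=unspliced,
                upstream=up,
                downstream=down,
            )
        )
    return genes


def bed12_to_annotation(path: str | Path, isoacceptors: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Convert a BED12 file of tRNA genes to the annotation table.

    Gaps between BED blocks become introns (relative, oriented coordinates).
    ``isoacceptors`` maps gene names to isoacceptor labels; missing names get
    the label 'NA'.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            introns: list[tuple[int, int]] = []
            for i in range(len(sizes) - 1):
                gap_s = starts[i] + sizes[i]
                gap_e = starts[i + 1]
                introns.append((gap_s, gap_e))
            if strand == "-":
                total = end - start
                introns = sorted((total - e, total - s) for s, e in introns)
            intron_txt = ";".join(f"{s}-{e}" for s, e in introns)
            iso = (isoacceptors or {}).get(name, "NA")
            rows.append((name, iso, chrom, start, end, strand, intron_txt))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: _normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_tier(tier: ReferenceTier, path: str | Path) -> None:
    write_fasta(tier.sequences, path)


def read_tier(name: str, path: str | Path) -> ReferenceTier:
    return fasta_tier(name, read_fasta(path))
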