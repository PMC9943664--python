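"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the salient statistical features of the study's
inputs: tRNA gene families whose high within-isoacceptor sequence identity
induces multi-mapping; CLIP reads truncating one base 3' of a planted
crosslink; noisy first-order unwinding time courses and hyperbolic binding
curves; and 3+3-replicate proteomics intensity matrices with
missing-at-low-intensity dropout and three constant-abundance anchor
proteins.  All randomness is per-operation and explicitly seeded; fixed
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import FastqRead
from .reference import TrnaGene

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReadOrigin:
    gene_id: str
    start: int  # true start on the mature tRNA sequence
    crosslink: int  # = start - 1


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar for a simulated experiment."""

    gene_isoacceptors: dict[str, str] = field(default_factory=dict)
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)
    kinetic_params: dict[str, float] = field(default_factory=dict)
    binding_params: dict[str, float] = field(default_factory=dict)
    proteomics_effects: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["read_origins"] = {k: asdict(v) for k, v in self.read_origins.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped fractional identity between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_trna_family(
    n_isoacceptors: int,
    genes_per_isoacceptor: int,
    length: int = 72,
    intra_similarity: float = 0.98,
    inter_similarity: float = 0.60,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[list[TrnaGene], pd.DataFrame]:
    """Gene families with controlled sequence similarity structure.

    Within an isoacceptor every gene pair has identity >= intra_similarity;
    between isoacceptors identity is <= inter_similarity (both verified
    empirically after generation, with bounded retries).  Default lengths
    and similarities mirror cytoplasmic tRNA bodies: ~72 nt, near-identical
    isodecoders, ~60% identity across isoacceptors.
    """
    if not 0 <= inter_similarity <= intra_similarity <= 1:
        raise ValueError("require 0 <= inter_similarity <= intra_similarity <= 1")
    if length < 60:
        raise ValueError("tRNA body length must be >= 60 nt")
    rng = np.random.default_rng(seed)

    def make_ancestors() -> list[str]:
        if inter_similarity < 0.3:
            # rotation construction: any two ancestors differ everywhere
            if n_isoacceptors > 4:
                raise SimulationError(
                    "inter-isoacceptor similarity < 0.3 is unsatisfiable for > 4 families"
                )
            perm = rng.integers(0, 4, size=length)
            return [
                "".join(_BASES[(perm + j) % 4]) for j in range(n_isoacceptors)
            ]
        root = "".join(rng.choice(_BASES, size=length))
        # identity between two mutants of the root is ~ (1-p)^2; aim below the cap
        p = 1.0 - np.sqrt(max(inter_similarity * 0.8, 0.25))
        return [_mutate(root, p, rng) for _ in range(n_isoacceptors)]

    q = (1.0 - intra_similarity) / 2 * 0.7  # within-family divergence rate

    for _ in range(max_retries):
        ancestors = make_ancestors()
        genes: list[TrnaGene] = []
        for a, anc in enumerate(ancestors):
            iso = f"Iso{a + 1}"
            for g in range(genes_per_isoacceptor):
                body = _mutate(anc, q, rng) if q > 0 else anc
                genes.append(TrnaGene(f"{iso}-gene{g + 1}", iso, body))
        ok = True
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                ident = pairwise_identity(genes[i].body, genes[j].body)
                same = genes[i].isoacceptor == genes[j].isoacceptor
                if same and ident < intra_similarity:
                    ok = False
                if not same and ident > inter_similarity:
                    ok = False
        if ok:
            ann = pd.DataFrame(
                {
                    "gene_id": [g.gene_id for g in genes],
                    "isoacceptor": [g.isoacceptor for g in genes],
                    "seq_class": "tRNA",
                }
            )
            return genes, ann
    raise SimulationError(
        "could not satisfy similarity constraints "
        f"(intra >= {intra_similarity}, inter <= {inter_similarity}) "
        f"after {max_retries} attempts"
    )


def simulate_clip_reads(
    genes: Sequence[TrnaGene],
    crosslink_sites: Mapping[str, int],
    n_reads: int = 1000,
    read_length: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
    low_quality_tail: int = 0,
    tail_quality: int = 2,
) -> tuple[list[FastqRead], SyntheticTruth]:
    """CLIP reads truncating at planted crosslinks.

    Each read starts one base 3' of its gene's crosslink position on the
    mature sequence (G + body + CCA), carries per-base substitution errors at
    ``error_rate`` and constant Q40 qualities ('I'); ``low_quality_tail``
    optionally appends random bases with a planted low quality to exercise
    the 3' quality trimmer.
    """
    if not genes:
        raise SimulationError("empty gene set")
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    source_ids = sorted(crosslink_sites)
    for gid in source_ids:
        mature = by_id[gid].mature_sequence()
        xl = crosslink_sites[gid]
        if not 0 <= xl < len(mature) - read_length:
            raise SimulationError(
                f"crosslink {xl} on {gid} leaves no room for a {read_length} nt read"
            )
    truth = SyntheticTruth(gene_isoacceptors={g.gene_id: g.isoacceptor for g in genes})
    reads: list[FastqRead] = []
    for i in range(n_reads):
        gid = source_ids[rng.integers(len(source_ids))]
        xl = crosslink_sites[gid]
        start = xl + 1
        seq = by_id[gid].mature_sequence()[start : start + read_length]
        if error_rate > 0:
            seq = _mutate(seq, error_rate, rng)
        qual = "I" * len(seq)
        if low_quality_tail > 0:
            tail = "".join(rng.choice(_BASES, size=low_quality_tail))
            seq += tail
            qual += chr(33 + tail_quality) * low_quality_tail
        rid = f"read{i:06d}"
        reads.append(FastqRead(rid, seq, qual))
        truth.read_origins[rid] = ReadOrigin(gid, start, xl)
    return reads, truth


def simulate_unwinding_curve(
    k: float,
    amplitude: float,
    timepoints: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0, 15.0, 22.0, 30.0),
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """First-order unwinding time course, Frac = A(1 - e^{-kt}) + N(0, sd),
    clipped to [0, 1].  Defaults match the assay design: 8 timepoints over
    0-30 min, 3 replicates, sd 0.02 on the fraction scale."""
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        clean = amplitude * (1.0 - np.exp(-k * t))
        noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=t.size), 0.0, 1.0) \
            if noise_sd > 0 else clean
        for ti, yi in zip(t, noisy):
            rows.append({"time_min": ti, "replicate": rep, "frac_ss": yi})
    return pd.DataFrame(rows)


def simulate_binding_curve(
    kd: float,
    bmax: float = 1.0,
    protein_concs: Sequence[float] | None = None,
    noise_sd: float = 0.03,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """One-site binding curve, B = Bmax [P]/(Kd + [P]) + N(0, sd), clipped to
    [0, 1].  Default concentrations: 8 points log-spaced over 0.1x-10x Kd."""
    rng = np.random.default_rng(seed)
    if protein_concs is None:
        protein_concs = np.geomspace(0.1 * kd, 10 * kd, 8)
    conc = np.asarray(protein_concs, dtype=float)
    rows = []
    for rep in range(1, replicates + 1):
        clean = bmax * conc / (kd + conc)
        noisy = np.clip(clean + rng.normal(0.0, noise_sd, size=conc.size), 0.0, 1.0) \
            if noise_sd > 0 else clean
        for ci, yi in zip(conc, noisy):
            rows.append({"conc_nM": ci, "replicate": rep, "fraction_bound": yi})
    return pd.DataFrame(rows)


def simulate_intensity_matrix(
    n_proteins: int = 400,
    n_enriched: int = 100,
    effect_log2: float = 2.0,
    missing_rate_low_intensity: float = 0.3,
    seed: int = 0,
    noise_sd_log2: float = 0.25,
    sample_scale_sd_log2: float = 0.3,
    anchors: Sequence[str] = ("ACTB", "TBA1B", "TBB4B"),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-fraction proteomics intensities (3 control + 3 stress samples,
    4 fractions each) with planted enrichment and dropout.

    Protein base abundances are log-normal (log2 ~ N(25, 2.5)); the three
    anchor proteins sit at a constant high abundance in every sample.
    Enriched proteins gain ``effect_log2`` in the stress group.  Per-sample
    scale factors (sd ``sample_scale_sd_log2`` log2 units) emulate day and
    machine effects that anchor normalization must remove.  A protein-sample
    measurement drops out (all four fractions empty) with probability
    ``missing_rate_low_intensity`` when the protein's base abundance lies in
    the bottom quartile, one tenth of that otherwise.  Each sample intensity
    is split over 4 fractions by a Dirichlet draw, so summing fractions
    recovers it exactly.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    names = [f"P{i:04d}" for i in range(n_proteins)]
    base = rng.normal(25.0, 2.5, size=n_proteins)
    prot_ids = list(anchors) + names
    base = np.concatenate([np.full(len(anchors), 28.0), base])
    enriched = set(rng.choice(names, size=n_enriched, replace=False)) if n_enriched else set()

    samples = [f"control_{i}" for i in (1, 2, 3)] + [f"stress_{i}" for i in (1, 2, 3)]
    scales = (
        rng.normal(0.0, sample_scale_sd_log2, size=6)
        if sample_scale_sd_log2 > 0
        else np.zeros(6)
    )
    low_cut = np.quantile(base[len(anchors):], 0.25) if n_proteins else -np.inf

    truth = SyntheticTruth(
        proteomics_effects={p: (effect_log2 if p in enriched else 0.0) for p in prot_ids},
        missingness={s: [] for s in samples},
    )
    data: dict[str, np.ndarray] = {}
    intensity = np.zeros((len(prot_ids), 6))
    for j, sample in enumerate(samples):
        stress = sample.startswith("stress")
        log2_int = base.copy()
        for i, p in enumerate(prot_ids):
            if stress and p in enriched:
                log2_int[i] += effect_log2
        if noise_sd_log2 > 0:
            noise = rng.normal(0.0, noise_sd_log2, size=log2_int.size)
            noise[: len(anchors)] = 0.0  # anchors: constant true abundance
            log2_int = log2_int + noise
        log2_int = log2_int + scales[j]
        vals = np.power(2.0, log2_int)
        # dropout driven by the measurement's own intensity (low intensity ->
        # high dropout probability); anchors never drop
        for i, p in enumerate(prot_ids):
            if p in anchors:
                continue
            rate = (
                missing_rate_low_intensity
                if log2_int[i] - scales[j] <= low_cut
                else missing_rate_low_intensity / 10
            )
            if rate > 0 and rng.random() < rate:
                vals[i] = 0.0
                truth.missingness[sample].append(p)
        intensity[:, j] = vals
    # split each sample intensity over 4 fractions
    for j, sample in enumerate(samples):
        if noise_sd_log2 > 0 or sample_scale_sd_log2 > 0:
            weights = rng.dirichlet(np.ones(4), size=len(prot_ids))
        else:
            weights = np.full((len(prot_ids), 4), 0.25)
        for f in range(4):
            data[f"{sample}__f{f + 1}"] = intensity[:, j] * weights[:, f]
    table = pd.DataFrame(data, index=pd.Index(prot_ids, name="protein_id"))
    return table, truth
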