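"""Stress-proteomics enrichment: the five-step intensity pipeline.

Samples are chromatographic pools: each of the six samples (3 control, 3
arsenite stress) is the sum of four fraction intensities per protein.
Within each experimental group, sample columns are rescaled so the mean
intensity of three cytoskeletal anchor proteins (ACTB, TBA1B, TBB4B) is
constant across the group's samples; intensities are then log2-transformed
(zeros become missing), missing values are imputed per column from a
downshifted normal distribution (defaults: mean - 1.8 sd, width 0.3 sd, the
Perseus convention — the distribution family is fixed, its parameters are a
declared choice), and enrichment is the mean log2 stress intensity minus the
mean log2 control intensity.  Only proteins with at least two valid
(non-imputed) values in at least one group are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_ANCHORS = ("ACTB", "TBA1B", "TBB4B")
CONTROL_SAMPLES = ("control_1", "control_2", "control_3")
STRESS_SAMPLES = ("stress_1", "stress_2", "stress_3")


class ProteomicsError(ValueError):
    pass


def combine_fractions(fraction_table: pd.DataFrame) -> pd.DataFrame:
    """Sum per-fraction intensities into one column per sample.

    Input: one row per protein, columns ``<sample>__f<k>`` for the four
    fractions of each sample (index = protein_id).  Missing fractions count
    as zero; a protein absent from every fraction of a sample gets 0.
    """
    samples: dict[str, list[str]] = {}
    for col in fraction_table.columns:
        if "__f" not in col:
            raise ProteomicsError(f"unexpected fraction column name: {col!r}")
        sample = col.split("__f")[0]
        samples.setdefault(sample, []).append(col)
    out = pd.DataFrame(index=fraction_table.index)
    for sample, cols in samples.items():
        out[sample] = fraction_table[cols].fillna(0).sum(axis=1)
    return out[sorted(out.columns)]


def _check_matrix(matrix: pd.DataFrame, groups: dict[str, Sequence[str]]) -> None:
    all_samples = [s for g in groups.values() for s in g]
    missing = set(all_samples) - set(matrix.columns)
    if missing:
        raise ProteomicsError(f"matrix is missing sample columns: {sorted(missing)}")
    if len(all_samples) != 6:
        raise ProteomicsError("expected exactly 6 sample columns (3 control + 3 stress)")


def default_groups() -> dict[str, list[str]]:
    return {"control": list(CONTROL_SAMPLES), "stress": list(STRESS_SAMPLES)}


def anchor_normalize(
    matrix: pd.DataFrame,
    anchor_ids: Sequence[str] = DEFAULT_ANCHORS,
    groups: dict[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Within each group, divide each sample column by (its anchor mean /
    the group's grand anchor mean), equalising anchor means across the
    group's samples.  Cross-group anchor levels are not forced equal."""
    groups = groups or default_groups()
    _check_matrix(matrix, groups)
    anchors = [a for a in anchor_ids if a in matrix.index]
    if not anchors:
        raise ProteomicsError("no anchor proteins present in the matrix")
    out = matrix.copy().astype(float)
    for samples in groups.values():
        sample_means = out.loc[anchors, list(samples)].mean(axis=0)
        if (sample_means <= 0).any():
            raise ProteomicsError("anchor mean is zero in a sample; cannot normalize")
        grand = sample_means.mean()
        out[list(samples)] = out[list(samples)] / (sample_means / grand)
    return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 intensities; zeros and absences become missing, never -inf."""
    out = matrix.astype(float).where(matrix > 0)
    return np.log2(out)


def impute_missing(
    matrix: pd.DataFrame,
    seed: int,
    downshift: float = 1.8,
    width: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column downshifted-normal imputation of missing log2 intensities.

    Each column's missing entries are drawn from
    Normal(mean_col - downshift * sd_col, (width * sd_col)^2), emulating the
    missing-at-low-intensity mechanism.  Returns (matrix, imputed flags).
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    flags = matrix.isna()
    for col in matrix.columns:
        vals = matrix[col]
        missing = vals.isna()
        if not missing.any():
            continue
        mu, sd = vals.mean(skipna=True), vals.std(skipna=True, ddof=1)
        if not np.isfinite(mu) or not np.isfinite(sd) or sd == 0:
            raise ProteomicsError(f"column {col!r} has too few observed values to impute")
        draws = rng.normal(mu - downshift * sd, width * sd, size=int(missing.sum()))
        out.loc[missing, col] = draws
    return out, flags


def enrichment(
    log2_matrix: pd.DataFrame,
    valid_counts: pd.DataFrame | None = None,
    groups: dict[str, Sequence[str]] | None = None,
    imputed_flags: pd.DataFrame | None = None,
    min_valid: int = 2,
) -> pd.DataFrame:
    """log2 enrichment = mean(stress) - mean(control) per protein.

    ``valid_counts``: per-protein observed-value counts per group *before
    imputation*; imputed values never count as valid.  Proteins failing the
    >= ``min_valid``-in-one-group rule are dropped.
    """
    groups = groups or default_groups()
    _check_matrix(log2_matrix, groups)
    control, stress = list(groups["control"]), list(groups["stress"])
    if valid_counts is None:
        valid_counts = pd.DataFrame(
            {
                "control": log2_matrix[control].notna().sum(axis=1),
                "stress": log2_matrix[stress].notna().sum(axis=1),
            }
        )
    keep = (valid_counts["control"] >= min_valid) | (valid_counts["stress"] >= min_valid)
    sub = log2_matrix.loc[keep]
    table = pd.DataFrame(
        {
            "log2_enrichment": sub[stress].mean(axis=1) - sub[control].mean(axis=1),
            "n_valid_control": valid_counts.loc[keep, "control"],
            "n_valid_stress": valid_counts.loc[keep, "stress"],
        }
    )
    if imputed_flags is not None:
        table["contains_imputed"] = imputed_flags.loc[keep].any(axis=1)
    return table.sort_values("log2_enrichment", ascending=False)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    normalized: pd.DataFrame
    imputed_flags: pd.DataFrame


def enrich_pipeline(
    fraction_table: pd.DataFrame,
    anchor_ids: Sequence[str] = DEFAULT_ANCHORS,
    seed: int = 0,
    downshift: float = 1.8,
    width: float = 0.3,
    groups: dict[str, Sequence[str]] | None = None,
) -> EnrichmentResult:
    """The full five-step procedure from per-fraction intensities to the
    ranked enrichment table."""
    groups = groups or default_groups()
    combined = combine_fractions(fraction_table)
    normalized = anchor_normalize(combined, anchor_ids, groups)
    logged = log2_transform(normalized)
    valid_counts = pd.DataFrame(
        {
            name: logged[list(samples)].notna().sum(axis=1)
            for name, samples in groups.items()
        }
    )
    if logged.isna().any().any():
        imputed, flags = impute_missing(logged, seed, downshift, width)
    else:
        imputed, flags = logged, logged.isna()
    table = enrichment(imputed, valid_counts, groups, flags)
    return EnrichmentResult(table, normalized, flags)
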