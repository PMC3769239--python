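"""Cross-platform harmonization of log2 expression matrices.

Three stages, applied to the combined data from all platforms:

1. :func:`merge_platforms` — union of canonical gene ids across platforms;
   a gene absent from a platform is missing for all of that platform's
   samples; multiple source probes mapping to one canonical id are averaged.
2. :func:`filter_missingness` — drop genes observed in fewer than 40 % of
   samples (threshold inclusive: exactly 40 % is kept).
3. :func:`standardize_genes` — per gene, subtract the median of the observed
   values and divide by their standard deviation (n−1 denominator).  This
   gene-wise location/scale normalization is what absorbs additive
   per-platform intensity offsets so that samples from different array
   generations become comparable.

Standardization is computed once on the complete combined matrix, not per
platform.  Genes with zero variance or fewer than two observed values cannot
be standardized and are dropped with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix
from .errors import ValidationError

__all__ = [
    "HarmonizedMatrix",
    "merge_platforms",
    "filter_missingness",
    "standardize_genes",
    "harmonize",
]

DEFAULT_MIN_FRAC = 0.40


@dataclass
class HarmonizedMatrix(ExpressionMatrix):
    """Standardized expression matrix plus a provenance log of dropped genes.

    ``provenance`` records ``(gene_id, stage, reason)`` triples for every
    gene removed on the way to this matrix.
    """

    provenance: list[tuple[str, str, str]] = field(default_factory=list)


def merge_platforms(
    matrices: Mapping[str, ExpressionMatrix] | Sequence[ExpressionMatrix],
    gene_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Combine per-platform matrices into one matrix on canonical gene ids.

    Parameters
    ----------
    matrices
        The per-platform inputs; sample ids must be disjoint.
    gene_map
        Optional source-label -> canonical-id map.  Labels absent from the
        map keep their own id.  Several labels mapping to one canonical id
        (within or across platforms sharing samples) are collapsed by the
        per-sample mean of their observed values.
    """
    if isinstance(matrices, Mapping):
        parts = list(matrices.values())
    else:
        parts = list(matrices)
    if not parts:
        raise ValidationError("no matrices to merge")

    seen: set[str] = set()
    frames = []
    for m in parts:
        overlap = seen.intersection(m.sample_ids)
        if overlap:
            raise ValidationError(f"duplicate sample id across platforms: {sorted(overlap)[0]!r}")
        seen.update(m.sample_ids)
        df = m.values
        if gene_map:
            df = df.rename(index=lambda g: gene_map.get(g, g))
        if df.index.has_duplicates:
            df = df.groupby(level=0, sort=False).mean()
        frames.append(df)

    merged = pd.concat(frames, axis=1)  # outer join on gene ids
    # deterministic gene order: first-seen order across platforms
    order: list[str] = []
    known: set[str] = set()
    for df in frames:
        for g in df.index:
            if g not in known:
                known.add(g)
                order.append(g)
    merged = merged.reindex(order)
    return ExpressionMatrix(merged)


def filter_missingness(
    matrix: ExpressionMatrix,
    min_frac: float = DEFAULT_MIN_FRAC,
    provenance: list[tuple[str, str, str]] | None = None,
) -> ExpressionMatrix:
    """Keep genes observed in at least ``min_frac`` of the samples."""
    if not 0.0 < min_frac <= 1.0:
        raise ValidationError(f"min_frac must be in (0, 1], got {min_frac}")
    n_samples = len(matrix.sample_ids)
    frac = matrix.values.notna().sum(axis=1) / n_samples
    keep = frac >= min_frac
    if provenance is not None:
        for gene in matrix.values.index[~keep]:
            provenance.append((str(gene), "filter_missingness", f"observed fraction < {min_frac:g}"))
    return ExpressionMatrix(matrix.values.loc[keep])


def standardize_genes(
    matrix: ExpressionMatrix,
    provenance: list[tuple[str, str, str]] | None = None,
) -> HarmonizedMatrix:
    """Gene-wise (x − median) / sd over observed values; missing propagates.

    Constant genes and genes with fewer than two observed values are dropped
    (the scale is undefined) and logged in the provenance.
    """
    prov = list(provenance) if provenance is not None else []
    values = matrix.values
    n_obs = values.notna().sum(axis=1)
    med = values.median(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)

    too_few = n_obs < 2
    constant = (~too_few) & ((sd == 0.0) | sd.isna())
    for gene in values.index[too_few]:
        prov.append((str(gene), "standardize_genes", "fewer than 2 observed values"))
    for gene in values.index[constant]:
        prov.append((str(gene), "standardize_genes", "zero variance"))

    keep = ~(too_few | constant)
    kept = values.loc[keep]
    out = kept.sub(med.loc[keep], axis=0).div(sd.loc[keep], axis=0)
    return HarmonizedMatrix(out, provenance=prov)


def harmonize(
    matrices: Mapping[str, ExpressionMatrix] | Sequence[ExpressionMatrix],
    gene_map: Mapping[str, str] | None = None,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> tuple[ExpressionMatrix, HarmonizedMatrix]:
    """Full harmonization: merge, missingness filter, standardize.

    Returns ``(merged, standardized)`` — the merged-and-filtered log2 matrix
    (used for fold changes and MDS, where the log2 scale is meaningful) and
    the median/SD-standardized matrix, sharing gene and sample sets.
    """
    merged = merge_platforms(matrices, gene_map)
    prov: list[tuple[str, str, str]] = []
    filtered = filter_missingness(merged, min_frac, provenance=prov)
    standardized = standardize_genes(filtered, provenance=prov)
    filtered = ExpressionMatrix(filtered.values.loc[standardized.values.index])
    return filtered, standardized
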