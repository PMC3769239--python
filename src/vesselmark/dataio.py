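"""Readers and writers for the tabular formats the pipeline exchanges.

The central in-memory containers are:

* :class:`ExpressionMatrix` — genes x samples log2 intensities; a pandas
  DataFrame with ``NaN`` marking missing values.
* :class:`SampleAnnotation` — one record per array sample (platform, cell
  class, dataset membership, source study).
* :class:`MarkerList` — a study's published set of BEC- or LEC-specific
  gene symbols.

File formats are deliberately plain: tab-separated expression matrices with
the literal token ``NA`` for a missing cell, a tab-separated annotation
manifest, and comma-separated marker lists.  Parsing is strict — empty cells
and unknown category tokens are errors, never silently coerced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

PLATFORMS = frozenset({"GPL570", "GPL571", "GPL5188"})
CELL_CLASSES = frozenset({"BEC", "LEC", "HMEC1", "TIME", "CONTROL"})
VESSEL_CLASSES = frozenset({"BEC", "LEC"})
DATASETS = frozenset({"A", "B"})

MISSING_TOKEN = "NA"


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities with explicit missingness.

    ``values`` is a float DataFrame indexed by gene id with sample ids as
    columns; ``NaN`` means the value is missing (either not measured on the
    sample's platform or filtered upstream).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ValidationError("non-finite (infinite) expression value")
        if v.values.dtype != np.float64:
            self.values = v.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_observed(self) -> pd.Series:
        """Number of non-missing values per gene."""
        return self.values.notna().sum(axis=1)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values)


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: platform, cell class, dataset membership, study."""

    sample_id: str
    platform: str
    cell_class: str
    dataset_membership: frozenset[str] = frozenset()
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform: {self.platform!r}")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"unknown cell_class: {self.cell_class!r}")
        bad = set(self.dataset_membership) - DATASETS
        if bad:
            raise ValidationError(f"unknown dataset membership: {sorted(bad)!r}")


@dataclass(frozen=True)
class MarkerList:
    """A study's set of vessel-type-specific gene symbols."""

    study_id: str
    vessel_class: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValidationError(f"vessel_class must be BEC or LEC, got {self.vessel_class!r}")


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace-trimmed, upper-case."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header of sample ids, first column gene
    ids, ``NA`` for missing).

    Raises :class:`FormatError` for duplicate ids, non-numeric cells, empty
    cells, or a header-only file.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.rstrip("\n").split("\t")
        if len(columns) < 2:
            raise FormatError(f"{path}: header must name at least one sample")
        sample_ids = columns[1:]
        seen_s = set()
        for s in sample_ids:
            if s in seen_s:
                raise FormatError(f"{path}: duplicate sample id {s!r}")
            seen_s.add(s)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen_g = set()
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(columns):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(columns)} columns, got {len(cells)}"
                )
            gene = cells[0]
            if gene in seen_g:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen_g.add(gene)
            gene_ids.append(gene)
            row = []
            for j, cell in enumerate(cells[1:], start=2):
                if cell == MISSING_TOKEN:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: column {j}: non-numeric cell {cell!r}"
                    ) from None
            rows.append(row)
    if not gene_ids:
        raise FormatError(f"{path}: no data rows (header only)")
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(values)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the format :func:`read_expression_tsv` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in matrix.values.iterrows():
            cells = [
                MISSING_TOKEN if pd.isna(x) else repr(float(x)) for x in row.to_numpy()
            ]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# annotations


def _parse_membership(token: str) -> frozenset[str]:
    token = token.strip()
    if token == "":
        return frozenset()
    return frozenset(part.strip() for part in token.split("|"))


def _format_membership(membership: Iterable[str]) -> str:
    return "|".join(sorted(membership))


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the sample-annotation manifest (TSV: sample_id, platform,
    cell_class, dataset_membership, study_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "platform", "cell_class", "dataset_membership", "study_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    seen = set()
    out = []
    for rec in df.itertuples(index=False):
        if rec.sample_id in seen:
            raise FormatError(f"{path}: duplicate sample id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        out.append(
            SampleAnnotation(
                sample_id=rec.sample_id,
                platform=rec.platform,
                cell_class=rec.cell_class,
                dataset_membership=_parse_membership(rec.dataset_membership),
                study_id=rec.study_id,
            )
        )
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "platform": a.platform,
            "cell_class": a.cell_class,
            "dataset_membership": _format_membership(a.dataset_membership),
            "study_id": a.study_id,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["sample_id", "platform", "cell_class", "dataset_membership", "study_id"]).to_csv(
        path, sep="\t", index=False
    )


def annotation_index(annotations: Iterable[SampleAnnotation]) -> dict[str, SampleAnnotation]:
    return {a.sample_id: a for a in annotations}


# ---------------------------------------------------------------------------
# marker lists


def read_marker_lists(path: str | Path) -> list[MarkerList]:
    """Read marker CSV (columns study_id, vessel_class, gene) into one
    :class:`MarkerList` per (study, vessel class); symbols canonicalized and
    duplicates collapsed."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["study_id", "vessel_class", "gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    grouped: dict[tuple[str, str], set[str]] = {}
    order: list[tuple[str, str]] = []
    for rec in df.itertuples(index=False):
        if rec.vessel_class not in VESSEL_CLASSES:
            raise ValidationError(f"{path}: unknown vessel_class {rec.vessel_class!r}")
        key = (rec.study_id, rec.vessel_class)
        if key not in grouped:
            grouped[key] = set()
            order.append(key)
        grouped[key].add(canonical_symbol(rec.gene))
    return [
        MarkerList(study_id=s, vessel_class=v, genes=frozenset(grouped[(s, v)]))
        for s, v in order
    ]


def write_marker_lists(lists: Sequence[MarkerList], path: str | Path) -> None:
    rows = [
        {"study_id": ml.study_id, "vessel_class": ml.vessel_class, "gene": g}
        for ml in lists
        for g in sorted(ml.genes)
    ]
    pd.DataFrame(rows, columns=["study_id", "vessel_class", "gene"]).to_csv(path, index=False)


def load_table1_markers(vessel_class: str) -> list[MarkerList]:
    """Load the packaged transcription of the three published marker-gene
    lists (pooled meta-analysis, Petrova, Hirakawa) for one vessel class.

    The two single-study columns were printed truncated after their top 20
    genes, so the Petrova-only and Hirakawa-only lists here are incomplete;
    region sizes involving only those studies must come from the printed
    totals, not from counting these fixtures.
    """
    if vessel_class not in VESSEL_CLASSES:
        raise ValidationError(f"vessel_class must be BEC or LEC, got {vessel_class!r}")
    name = f"table1_{vessel_class.lower()}.csv"
    ref = resources.files("vesselmark.data").joinpath(name)
    with resources.as_file(ref) as p:
        return read_marker_lists(p)


# ---------------------------------------------------------------------------
# gene-id maps


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a probe/label -> canonical gene id map (TSV: source_id, gene_id).

    Many-to-one is allowed; a source label appearing twice with different
    targets is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["source_id", "gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    mapping: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        if not rec.gene_id:
            raise ValidationError(f"{path}: empty canonical gene id for {rec.source_id!r}")
        if rec.source_id in mapping and mapping[rec.source_id] != rec.gene_id:
            raise ValidationError(
                f"{path}: source {rec.source_id!r} maps to both "
                f"{mapping[rec.source_id]!r} and {rec.gene_id!r}"
            )
        mapping[rec.source_id] = rec.gene_id
    return mapping


# ---------------------------------------------------------------------------
# reports


def write_report(partition, path: str | Path) -> None:
    """Write a Venn partition as a JSON report:
    ``{"regions": [{"label": [...], "size": n, "genes": [...]}]}``."""
    regions = [
        {"label": list(label), "size": len(genes), "genes": sorted(genes)}
        for label, genes in partition.ordered_regions()
    ]
    payload = {"regions": regions}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
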