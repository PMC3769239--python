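"""n-way Venn partitions of per-study marker gene sets.

Several studies each publish a set of BEC- or LEC-specific genes; the
comparison of interest is the exact disjoint decomposition of those sets by
study membership — which genes every study agrees on, which are private to
one analysis, and so on.  Gene symbols are compared exactly (after the
canonicalization applied at read time); no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .dataio import MarkerList
from .errors import ValidationError

__all__ = ["VennPartition", "venn", "venn_from_lists", "study_total", "concordance_report"]


@dataclass
class VennPartition:
    """Disjoint regions of an n-way gene-set intersection.

    ``regions`` maps a membership label — the sorted tuple of exactly the
    studies containing a gene — to that region's gene set.  Only non-empty
    labels exist; every label combination is present (possibly empty) so
    that printed reports are complete.
    """

    inputs: dict[str, frozenset[str]]
    regions: dict[tuple[str, ...], frozenset[str]]

    def ordered_regions(self) -> list[tuple[tuple[str, ...], frozenset[str]]]:
        """Regions ordered by membership cardinality (desc), then label."""
        return sorted(self.regions.items(), key=lambda kv: (-len(kv[0]), kv[0]))

    def region(self, *studies: str) -> frozenset[str]:
        label = tuple(sorted(studies))
        if label not in self.regions:
            raise ValidationError(f"unknown region label: {label!r}")
        return self.regions[label]


def _all_labels(studies: list[str]) -> list[tuple[str, ...]]:
    labels: list[tuple[str, ...]] = []
    n = len(studies)
    ordered = sorted(studies)
    for mask in range(1, 2**n):
        labels.append(tuple(s for i, s in enumerate(ordered) if mask >> i & 1))
    return labels


def venn(inputs: Mapping[str, Iterable[str]]) -> VennPartition:
    """Exact disjoint partition of the input gene sets by study membership."""
    if not inputs:
        raise ValidationError("venn needs at least one input set")
    sets = {study: frozenset(genes) for study, genes in inputs.items()}
    studies = list(sets)
    regions: dict[tuple[str, ...], set[str]] = {label: set() for label in _all_labels(studies)}
    for gene in frozenset().union(*sets.values()):
        label = tuple(sorted(s for s in studies if gene in sets[s]))
        regions[label].add(gene)
    return VennPartition(
        inputs=sets, regions={label: frozenset(genes) for label, genes in regions.items()}
    )


def venn_from_lists(lists: Iterable[MarkerList], vessel_class: str) -> VennPartition:
    """Venn partition of all marker lists of one vessel class, keyed by
    study id."""
    inputs: dict[str, frozenset[str]] = {}
    for ml in lists:
        if ml.vessel_class != vessel_class:
            continue
        if ml.study_id in inputs:
            raise ValidationError(f"duplicate study {ml.study_id!r} for class {vessel_class}")
        inputs[ml.study_id] = ml.genes
    if not inputs:
        raise ValidationError(f"no marker lists of class {vessel_class!r}")
    return venn(inputs)


def study_total(partition: VennPartition, study_id: str) -> int:
    """Total genes attributed to a study = sum of its region sizes."""
    if study_id not in partition.inputs:
        raise ValidationError(f"unknown study: {study_id!r}")
    return sum(len(genes) for label, genes in partition.regions.items() if study_id in label)


def concordance_report(partitions: Mapping[str, VennPartition]) -> pd.DataFrame:
    """Cross-class summary table of region sizes, per-study totals, and
    pairwise overlaps.

    ``partitions`` maps a vessel class (e.g. ``BEC``/``LEC``) to its
    partition; all partitions must share the same study ids.  Returns a
    tidy DataFrame with columns ``vessel_class, kind, label, size``, where
    ``kind`` is ``region``, ``study_total`` or ``pairwise_overlap``.
    """
    classes = list(partitions)
    if classes:
        studysets = {frozenset(p.inputs) for p in partitions.values()}
        if len(studysets) > 1:
            raise ValidationError("partitions do not share study ids")
    rows = []
    for vclass, part in partitions.items():
        for label, genes in part.ordered_regions():
            rows.append(
                {"vessel_class": vclass, "kind": "region", "label": "&".join(label), "size": len(genes)}
            )
        for study in sorted(part.inputs):
            rows.append(
                {
                    "vessel_class": vclass,
                    "kind": "study_total",
                    "label": study,
                    "size": study_total(part, study),
                }
            )
        studies = sorted(part.inputs)
        for i, s1 in enumerate(studies):
            for s2 in studies[i + 1 :]:
                overlap = len(part.inputs[s1] & part.inputs[s2])
                rows.append(
                    {
                        "vessel_class": vclass,
                        "kind": "pairwise_overlap",
                        "label": f"{s1}&{s2}",
                        "size": overlap,
                    }
                )
    return pd.DataFrame(rows, columns=["vessel_class", "kind", "label", "size"])
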