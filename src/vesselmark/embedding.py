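"""Euclidean distances and classical (Torgerson) multidimensional scaling.

Classical MDS double-centers the squared-distance matrix,
``B = -1/2 J D^2 J`` with ``J = I - 11'/n``, and embeds samples on the top-k
eigenvectors of ``B`` scaled by the square roots of their eigenvalues.  For
a genuinely Euclidean distance matrix of rank <= k the embedding reproduces
the distances exactly; dimensions with negative eigenvalues (possible for
non-Euclidean inputs such as pairwise-complete distances) are zeroed and
reported.  The procedure is deterministic — no seeds, no iterative stress
minimization.

Missing expression values are handled by two policies: ``complete_genes``
(default) restricts to genes observed in every sample, which keeps the
geometry exactly Euclidean; ``pairwise_complete`` computes each pair's
distance over mutually observed genes, rescaled by sqrt(n_total/n_observed)
to keep magnitudes comparable, at the cost of only approximate Euclideanness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, SampleAnnotation, annotation_index
from .errors import ValidationError

__all__ = [
    "DistanceMatrix",
    "EmbeddingResult",
    "euclidean_distances",
    "classical_mds",
    "cluster_separation",
    "plot_embedding",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if (np.diag(d) != 0).any():
            raise ValidationError("distance matrix diagonal not zero")
        if (d < 0).any():
            raise ValidationError("negative distances")
        self.values = d


@dataclass
class EmbeddingResult:
    """k-dimensional coordinates per sample plus the MDS eigenvalues.

    Coordinates are centered per dimension; eigenvalues are non-increasing.
    ``negative_dims`` lists embedding dimensions whose eigenvalue was
    negative (their coordinates are zero).
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # n_samples x k
    eigenvalues: np.ndarray  # length k
    negative_dims: list[int] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def euclidean_distances(
    matrix: ExpressionMatrix, gene_policy: str = "complete_genes"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples over the gene axis."""
    if gene_policy not in ("complete_genes", "pairwise_complete"):
        raise ValidationError(f"unknown gene_policy: {gene_policy!r}")
    if len(matrix.sample_ids) < 2:
        raise ValidationError("need at least 2 samples")
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n_total = x.shape[1]
    if gene_policy == "complete_genes":
        complete = ~np.isnan(x).any(axis=0)
        if not complete.any():
            raise ValidationError("no genes observed in every sample")
        xc = x[:, complete]
        sq = np.sum(xc**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * xc @ xc.T
        d = np.sqrt(np.maximum(d2, 0.0))
    else:
        obs = ~np.isnan(x)
        x0 = np.where(obs, x, 0.0)
        obs_f = obs.astype(float)
        n_shared = obs_f @ obs_f.T
        if (n_shared == 0).any():
            raise ValidationError("a sample pair shares no observed genes")
        # sum over shared genes of (xi - xj)^2
        sq = x0**2
        cross = x0 @ x0.T
        d2 = (sq @ obs_f.T) + (obs_f @ sq.T) - 2.0 * cross
        d2 = d2 * (n_total / n_shared)
        d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(sample_ids=list(matrix.sample_ids), values=d)


def classical_mds(d: DistanceMatrix, k: int = 3) -> EmbeddingResult:
    """Torgerson MDS: top-k eigenpairs of the double-centered squared
    distance matrix."""
    n = len(d.sample_ids)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k = {k} must be smaller than the number of samples ({n})")
    d2 = d.values**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:k]
    lam = eigval[idx]
    vec = eigvec[:, idx]
    coords = np.zeros((n, k))
    negative = []
    for i in range(k):
        if lam[i] > 0:
            coords[:, i] = vec[:, i] * np.sqrt(lam[i])
        elif lam[i] < 0:
            negative.append(i)
    coords -= coords.mean(axis=0, keepdims=True)
    return EmbeddingResult(
        sample_ids=list(d.sample_ids),
        coordinates=coords,
        eigenvalues=lam,
        negative_dims=negative,
    )


def cluster_separation(
    emb: EmbeddingResult, annotations: Iterable[SampleAnnotation]
) -> dict:
    """Centroid geometry of the embedding by cell class.

    Reports per-class centroids, each class's hull radius (the maximum
    distance of a member sample to its own centroid; undefined for classes
    with a single sample), the distances of every cell-line (HMEC1/TIME)
    sample to the BEC, LEC and CONTROL centroids, and whether each cell-line
    sample lies outside the hull radius of both BEC and LEC.
    """
    idx = annotation_index(annotations)
    missing = [s for s in emb.sample_ids if s not in idx]
    if missing:
        raise ValidationError(f"unannotated embedded sample: {missing[0]!r}")
    coords = {s: emb.coordinates[i] for i, s in enumerate(emb.sample_ids)}
    by_class: dict[str, list[str]] = {}
    for s in emb.sample_ids:
        by_class.setdefault(idx[s].cell_class, []).append(s)

    centroids = {
        c: np.mean([coords[s] for s in members], axis=0) for c, members in by_class.items()
    }
    hull_radius = {}
    for c, members in by_class.items():
        if len(members) < 2:
            hull_radius[c] = None  # undefined, flagged
        else:
            hull_radius[c] = float(
                max(np.linalg.norm(coords[s] - centroids[c]) for s in members)
            )

    cell_lines = {}
    for c in ("HMEC1", "TIME"):
        for s in by_class.get(c, []):
            dists = {
                target: float(np.linalg.norm(coords[s] - centroids[target]))
                for target in ("BEC", "LEC", "CONTROL")
                if target in centroids
            }
            outside = None
            if "BEC" in centroids and "LEC" in centroids:
                rb, rl = hull_radius.get("BEC"), hull_radius.get("LEC")
                if rb is not None and rl is not None:
                    outside = dists["BEC"] > rb and dists["LEC"] > rl
            cell_lines[s] = {
                "cell_class": c,
                "centroid_distances": dists,
                "outside_primary_hulls": outside,
            }

    return {
        "centroids": {c: v.tolist() for c, v in centroids.items()},
        "hull_radius": hull_radius,
        "cell_lines": cell_lines,
    }


def plot_embedding(
    emb: EmbeddingResult,
    annotations: Iterable[SampleAnnotation],
    path: str | None = None,
):
    """Optional static scatter of the first two embedding dimensions,
    colored by cell class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = annotation_index(annotations)
    fig, ax = plt.subplots(figsize=(6, 5))
    classes = sorted({idx[s].cell_class for s in emb.sample_ids if s in idx})
    for c in classes:
        pts = np.array(
            [emb.coordinates[i, :2] for i, s in enumerate(emb.sample_ids) if idx[s].cell_class == c]
        )
        ax.scatter(pts[:, 0], pts[:, 1], label=c, s=25)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
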