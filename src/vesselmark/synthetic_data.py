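"""Synthetic multi-platform endothelial expression datasets.

Emulates the statistical structure of a pooled collection of public
microarray profiles of primary blood-endothelial (BEC) and
lymphatic-endothelial (LEC) cells plus two immortalized microvascular cell
lines (HMEC-1, TIME) and a non-endothelial control tissue, measured on three
Affymetrix platforms with different gene coverage:

* per-gene baselines drawn once and shared by all classes;
* planted marker genes with a symmetric BEC/LEC group difference
  (``+effect/2`` in the up-class, ``-effect/2`` in the other);
* cell lines as convex BEC/LEC mixtures plus line-specific drift genes —
  the minimal mechanism for a hybrid phenotype that clusters near, but not
  among, primary endothelial cells;
* additive per-gene per-platform offsets (batch structure that the
  downstream median/SD harmonization must absorb);
* structural missingness (a platform carries only a fraction of the genes)
  and additional missing-completely-at-random dropout.

Everything is driven by one integer seed; identical configs produce
bitwise-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dataio import ExpressionMatrix, SampleAnnotation, write_annotations, write_expression_tsv
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "default_pooled_study_config",
]

_PLATFORM_ORDER = ("GPL570", "GPL571", "GPL5188")
_CLASS_ORDER = ("BEC", "LEC", "HMEC1", "TIME", "CONTROL")
_CELL_LINES = ("HMEC1", "TIME")


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    All expression quantities are on the log2 scale.  ``samples_per_platform``
    maps a platform id to ``{cell_class: count}``; ``gene_coverage`` and
    ``missing_rate`` may be a single float (shared by all platforms) or a
    per-platform mapping.
    """

    n_genes: int = 2000
    n_marker_bec: int = 100
    n_marker_lec: int = 100
    effect_log2: float = 2.0
    samples_per_platform: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {"GPL570": {"BEC": 14, "LEC": 10}}
    )
    platform_offset_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd_mean: float = 1.5
    noise_sd: float = 0.5
    missing_rate: float | Mapping[str, float] = 0.02
    gene_coverage: float | Mapping[str, float] = 1.0
    hybrid_mix: float = 0.5
    drift_n_genes: int = 50
    drift_log2: float = 2.0
    control_shift_sd: float = 1.5
    seed: int | None = None

    def rate_for(self, name: str, platform: str) -> float:
        value = getattr(self, name)
        if isinstance(value, Mapping):
            return float(value[platform])
        return float(value)

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is required; reproducibility is mandatory")
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_marker_bec < 0 or self.n_marker_lec < 0:
            raise ValidationError("marker counts must be non-negative")
        if self.n_marker_bec + self.n_marker_lec > self.n_genes:
            raise ValidationError("more markers requested than genes")
        for platform in self.samples_per_platform:
            if platform not in _PLATFORM_ORDER:
                raise ValidationError(f"unknown platform: {platform!r}")
            for name in ("missing_rate", "gene_coverage"):
                r = self.rate_for(name, platform)
                if not 0.0 <= r <= 1.0:
                    raise ValidationError(f"{name} for {platform} outside [0, 1]: {r}")
        if not 0.0 <= self.hybrid_mix <= 1.0:
            raise ValidationError("hybrid_mix outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, for recovery testing."""

    bec_markers: frozenset[str]
    lec_markers: frozenset[str]
    drift_genes: dict[str, frozenset[str]]
    platform_offsets: pd.DataFrame  # genes x platforms
    group_means: pd.DataFrame  # genes x cell classes


def default_pooled_study_config(seed: int = 0) -> SimulationConfig:
    """Configuration mirroring the pooled study design: 47 primary profiles
    (33 BEC + 14 LEC) over three platforms, of which the 24 GPL570 primary
    samples (14 BEC + 10 LEC) form the restricted Dataset A; plus four
    replicates of each cell line and three control-tissue samples."""
    return SimulationConfig(
        n_genes=2000,
        n_marker_bec=100,
        n_marker_lec=100,
        effect_log2=2.0,
        samples_per_platform={
            "GPL570": {"BEC": 14, "LEC": 10, "HMEC1": 4, "TIME": 4, "CONTROL": 3},
            "GPL571": {"BEC": 10, "LEC": 2},
            "GPL5188": {"BEC": 9, "LEC": 2},
        },
        platform_offset_sd=0.5,
        baseline_mean=7.0,
        baseline_sd_mean=1.5,
        noise_sd=0.5,
        missing_rate=0.02,
        gene_coverage={"GPL570": 1.0, "GPL571": 0.65, "GPL5188": 0.85},
        hybrid_mix=0.5,
        drift_n_genes=50,
        drift_log2=2.0,
        control_shift_sd=1.5,
        seed=seed,
    )


def _gene_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], list[SampleAnnotation], SyntheticTruth]:
    """Draw one dataset from the generative model.

    Returns per-platform expression matrices (each restricted to the genes
    that platform covers), the sample annotations, and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = _gene_ids(n)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd_mean, size=n)

    # disjoint marker and drift gene sets, drawn without replacement
    n_special = config.n_marker_bec + config.n_marker_lec + len(_CELL_LINES) * config.drift_n_genes
    if n_special > n:
        raise ValidationError("marker + drift genes exceed n_genes")
    special = rng.choice(n, size=n_special, replace=False)
    pos = 0
    bec_idx = special[pos : pos + config.n_marker_bec]
    pos += config.n_marker_bec
    lec_idx = special[pos : pos + config.n_marker_lec]
    pos += config.n_marker_lec
    drift_idx: dict[str, np.ndarray] = {}
    for line in _CELL_LINES:
        drift_idx[line] = special[pos : pos + config.drift_n_genes]
        pos += config.drift_n_genes

    half = config.effect_log2 / 2.0
    mean_bec = baseline.copy()
    mean_lec = baseline.copy()
    mean_bec[bec_idx] += half
    mean_lec[bec_idx] -= half
    mean_lec[lec_idx] += half
    mean_bec[lec_idx] -= half

    mix = config.hybrid_mix
    group_means = {"BEC": mean_bec, "LEC": mean_lec}
    for line in _CELL_LINES:
        m = mix * mean_bec + (1.0 - mix) * mean_lec
        m[drift_idx[line]] += config.drift_log2
        group_means[line] = m
    group_means["CONTROL"] = baseline + rng.normal(0.0, config.control_shift_sd, size=n)

    platforms = [p for p in _PLATFORM_ORDER if p in config.samples_per_platform]
    offsets = pd.DataFrame(
        rng.normal(0.0, config.platform_offset_sd, size=(n, len(platforms))),
        index=genes,
        columns=platforms,
    )

    matrices: dict[str, ExpressionMatrix] = {}
    annotations: list[SampleAnnotation] = []
    for platform in platforms:
        counts = config.samples_per_platform[platform]
        coverage = config.rate_for("gene_coverage", platform)
        n_cov = int(round(coverage * n))
        covered = np.sort(rng.choice(n, size=n_cov, replace=False))

        sample_ids: list[str] = []
        columns: list[np.ndarray] = []
        for cell_class in _CLASS_ORDER:
            count = counts.get(cell_class, 0)
            means = group_means.get(cell_class)
            for r in range(count):
                sid = f"{platform}_{cell_class}_{r:02d}"
                sample_ids.append(sid)
                noise = rng.normal(0.0, config.noise_sd, size=n_cov)
                col = (
                    means[covered]
                    + offsets[platform].to_numpy()[covered]
                    + noise
                )
                columns.append(col)
                if cell_class in ("BEC", "LEC"):
                    membership = frozenset("AB") if platform == "GPL570" else frozenset("B")
                else:
                    membership = frozenset()
                annotations.append(
                    SampleAnnotation(
                        sample_id=sid,
                        platform=platform,
                        cell_class=cell_class,
                        dataset_membership=membership,
                        study_id="synthetic",
                    )
                )
        values = pd.DataFrame(
            np.column_stack(columns) if columns else np.empty((n_cov, 0)),
            index=[genes[i] for i in covered],
            columns=sample_ids,
        )
        miss = config.rate_for("missing_rate", platform)
        if miss > 0 and values.size:
            dropout = rng.random(values.shape) < miss
            values = values.mask(dropout)
        matrices[platform] = ExpressionMatrix(values)

    truth = SyntheticTruth(
        bec_markers=frozenset(genes[i] for i in bec_idx),
        lec_markers=frozenset(genes[i] for i in lec_idx),
        drift_genes={line: frozenset(genes[i] for i in idx) for line, idx in drift_idx.items()},
        platform_offsets=offsets,
        group_means=pd.DataFrame(group_means, index=genes),
    )
    return matrices, annotations, truth


def write_dataset(
    matrices: Mapping[str, ExpressionMatrix],
    annotations: list[SampleAnnotation],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> list[Path]:
    """Write one simulated dataset to a directory: one expression TSV per
    platform, the annotation manifest, and the planted truth as JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for platform, matrix in matrices.items():
        p = out / f"expression_{platform}.tsv"
        write_expression_tsv(matrix, p)
        written.append(p)
    p = out / "annotations.tsv"
    write_annotations(annotations, p)
    written.append(p)
    payload = {
        "bec_markers": sorted(truth.bec_markers),
        "lec_markers": sorted(truth.lec_markers),
        "drift_genes": {k: sorted(v) for k, v in truth.drift_genes.items()},
    }
    p = out / "truth.json"
    p.write_text(json.dumps(payload, indent=2) + "\n")
    written.append(p)
    return written
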