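"""End-to-end orchestration: simulate -> harmonize -> differential
expression -> marker-set comparison -> MDS.

The pipeline mirrors the pooled-analysis design: all platform matrices are
merged and standardized once per defined dataset (a dataset is a named
sample filter, e.g. dataset A = samples with membership ``A``), BEC vs LEC
differential tables are computed per dataset, the resulting per-dataset
marker sets are intersected with a Venn partition per vessel class, and a
classical MDS embedding is produced for a configurable sample subset
(by default the single-platform subset including cell lines and controls,
on the merged log2 matrix).

Every run writes a manifest recording the seed, thresholds, stage status,
and a SHA-256 content hash of every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .dataio import (
    ExpressionMatrix,
    SampleAnnotation,
    read_annotations,
    read_expression_tsv,
    read_gene_map,
    read_marker_lists,
    write_expression_tsv,
    write_report,
)
from .diffexpr import differential_table, significant_genes
from .embedding import classical_mds, cluster_separation, euclidean_distances
from .errors import VesselmarkError, ValidationError
from .harmonize import harmonize
from .markersets import venn
from .synthetic_data import SimulationConfig, generate_dataset, write_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(VesselmarkError):
    """A stage failed; the message names the stage."""


@dataclass
class DatasetDef:
    """A named sample filter over the annotations."""

    membership: str | None = None  # dataset letter the sample must belong to
    platforms: list[str] | None = None
    cell_classes: list[str] | None = None

    def matches(self, ann: SampleAnnotation) -> bool:
        if self.membership is not None and self.membership not in ann.dataset_membership:
            return False
        if self.platforms is not None and ann.platform not in self.platforms:
            return False
        if self.cell_classes is not None and ann.cell_class not in self.cell_classes:
            return False
        return True


@dataclass
class PipelineConfig:
    out_dir: str = "vesselmark_run"
    seed: int = 0
    # either simulate, or read expression TSVs + annotations from input_dir
    simulate: bool = True
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    gene_map: str | None = None
    min_frac: float = 0.40
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    k: int = 3
    datasets: dict[str, DatasetDef] = field(
        default_factory=lambda: {"A": DatasetDef(membership="A"), "B": DatasetDef(membership="B")}
    )
    mds_platforms: list[str] | None = field(default_factory=lambda: ["GPL570"])
    external_marker_lists: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "simulation" in payload and payload["simulation"] is not None:
            payload["simulation"] = SimulationConfig(**payload["simulation"])
        if "datasets" in payload:
            payload["datasets"] = {
                name: DatasetDef(**spec) for name, spec in payload["datasets"].items()
            }
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subset(matrix: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    cols = [s for s in matrix.sample_ids if s in set(sample_ids)]
    return ExpressionMatrix(matrix.values[cols])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to
    ``<out_dir>/manifest.json``).  Any stage failure aborts with the stage
    named and that stage's partial outputs removed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_frac": config.min_frac,
            "fc_threshold": config.fc_threshold,
            "q_threshold": config.q_threshold,
            "k": config.k,
        },
        "stages": {},
        "outputs": {},
    }

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    def run_stage(name, fn):
        written: list[Path] = []
        try:
            result = fn(written)
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"status": "ok"}
        for p in written:
            record(p)
        return result

    # ------------------------------------------------------------------ input
    def stage_input(written):
        if config.simulate:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            if sim.seed is None:
                sim.seed = config.seed
            matrices, annotations, truth = generate_dataset(sim)
            written.extend(write_dataset(matrices, annotations, truth, out / "sim"))
            return matrices, annotations
        if config.input_dir is None:
            raise ValidationError("neither simulation nor input_dir configured")
        indir = Path(config.input_dir)
        matrices = {
            p.stem.replace("expression_", ""): read_expression_tsv(p)
            for p in sorted(indir.glob("expression_*.tsv"))
        }
        if not matrices:
            raise ValidationError(f"no expression_*.tsv files in {indir}")
        annotations = read_annotations(indir / "annotations.tsv")
        return matrices, annotations

    matrices, annotations = run_stage("input", stage_input)
    gene_map = read_gene_map(config.gene_map) if config.gene_map else None

    # ------------------------------------------------------- per-dataset DE
    marker_sets: dict[str, dict[str, set[str]]] = {"BEC": {}, "LEC": {}}

    def make_de_stage(name: str, ds: DatasetDef):
        def stage(written):
            keep = [a.sample_id for a in annotations if ds.matches(a)]
            if not keep:
                raise ValidationError(f"dataset {name!r} selects no samples")
            sub = {p: _subset(m, keep) for p, m in matrices.items()}
            sub = {p: m for p, m in sub.items() if m.shape[1] > 0}
            merged, standardized = harmonize(sub, gene_map, config.min_frac)
            mp = out / f"merged_{name}.tsv"
            write_expression_tsv(merged, mp)
            written.append(mp)
            # test and fold change on the merged log2 matrix (log2 scale is
            # what makes the 2-fold threshold meaningful)
            table = differential_table(
                merged,
                annotations,
                class_a="BEC",
                class_b="LEC",
                fc_threshold=config.fc_threshold,
                q_threshold=config.q_threshold,
            )
            tp = out / f"de_{name}.tsv"
            table.to_csv(tp, sep="\t", index_label="gene_id")
            written.append(tp)
            marker_sets["BEC"][name] = significant_genes(table, "A_UP")
            marker_sets["LEC"][name] = significant_genes(table, "B_UP")
            return table

        return stage

    for name, ds in config.datasets.items():
        run_stage(f"de_{name}", make_de_stage(name, ds))

    # ------------------------------------------------------------- markersets
    def stage_markers(written):
        partitions = {}
        external = [read_marker_lists(p) for p in config.external_marker_lists]
        for vclass in ("BEC", "LEC"):
            inputs = dict(marker_sets[vclass])
            for lists in external:
                for ml in lists:
                    if ml.vessel_class == vclass:
                        inputs[ml.study_id] = set(ml.genes)
            part = venn(inputs)
            partitions[vclass] = part
            rp = out / f"venn_{vclass.lower()}.json"
            write_report(part, rp)
            written.append(rp)
        return partitions

    partitions = run_stage("markers", stage_markers)

    # -------------------------------------------------------------------- mds
    def stage_mds(written):
        if config.mds_platforms is not None:
            keep = [a.sample_id for a in annotations if a.platform in config.mds_platforms]
            use = {p: m for p, m in matrices.items() if p in config.mds_platforms}
        else:
            keep = [a.sample_id for a in annotations]
            use = matrices
        merged, _ = harmonize(
            {p: _subset(m, keep) for p, m in use.items()}, gene_map, config.min_frac
        )
        dist = euclidean_distances(merged, gene_policy="complete_genes")
        emb = classical_mds(dist, k=config.k)
        frame = emb.as_frame()
        cp = out / "mds_coords.tsv"
        with cp.open("w") as fh:
            fh.write("# eigenvalues: " + " ".join(repr(float(e)) for e in emb.eigenvalues) + "\n")
            frame.to_csv(fh, sep="\t", index_label="sample_id")
        written.append(cp)
        sep = cluster_separation(emb, annotations)
        sp = out / "mds_separation.json"
        sp.write_text(json.dumps(sep, indent=2) + "\n")
        written.append(sp)
        return emb

    run_stage("mds", stage_mds)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
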