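"""Configured end-to-end runs with a machine-readable report.

A run executes the requested stages in dependency order — synthetic data,
scaffold segmentation, nuclei segmentation, phenotyping, crosstalk — writing
every intermediate artifact under the output directory and a ``report.json``
recording package version, seed, parameters, per-stage counts and SHA-256
checksums of all outputs. Runs with identical configuration are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .crosstalk import (
    cross_reference,
    de_gene_directions,
    filter_bmsc_genes,
    interactions_to_frame,
    read_ppi_table,
)
from .nucseg import SegParams, read_labels, segment_nuclei, write_labels
from .phenotype import (
    DEFAULT_PERCENTILES,
    classify_cells,
    count_colocalized,
    extract_mask_intensities,
    normalize_intensities,
    pool_and_threshold,
)
from .scaffold import FilterParams, segment_scaffold
from .simdata import (
    SimParams,
    generate_coculture_stack,
    generate_omics_bundle,
    write_ground_truth,
    write_omics_bundle,
)
from .stack import ImageStack3D, read_stack, write_stack

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simdata", "scaffold", "nucseg", "phenotype", "crosstalk")


@dataclass
class RunConfig:
    """Per-stage parameter blocks plus stage selection and paths."""

    out_dir: str | Path = "nichequant_run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_stacks: int = 3
    simdata: dict = field(default_factory=dict)
    scaffold: dict = field(default_factory=dict)
    nucseg: dict = field(default_factory=dict)
    phenotype: dict = field(default_factory=dict)
    crosstalk: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # stack/labels paths when simdata is off
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; known: {list(ALL_STAGES)}")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")
        needs_images = {"scaffold", "nucseg", "phenotype"} & set(self.stages)
        if needs_images and "simdata" not in self.stages and "stacks" not in self.inputs:
            raise ValueError(
                "scaffold/nucseg/phenotype need input stacks: enable the simdata "
                "stage or provide inputs.stacks"
            )
        if (
            "phenotype" in self.stages
            and "nucseg" not in self.stages
            and "labels" not in self.inputs
            and not (
                "simdata" in self.stages
                and self.phenotype.get("use_ground_truth_labels", False)
            )
        ):
            raise ValueError(
                "phenotype needs labels: enable nucseg, provide inputs.labels, or "
                "set phenotype.use_ground_truth_labels with the simdata stage"
            )
        for path in self.inputs.get("stacks", []) + [
            p for k, p in self.inputs.items() if k != "stacks"
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "simdata": dict(config.simdata),
            "scaffold": dict(config.scaffold),
            "nucseg": dict(config.nucseg),
            "phenotype": dict(config.phenotype),
            "crosstalk": dict(config.crosstalk),
        },
        "counts": {},
        "outputs": {},
    }

    stacks: list[tuple[str, ImageStack3D]] = []
    label_volumes: dict[str, np.ndarray] = {}
    truth_labels: dict[str, np.ndarray] = {}
    current = "setup"
    try:
        if "simdata" in config.stages:
            current = "simdata"
            sim_kwargs = dict(config.simdata)
            sim_kwargs.pop("seed", None)
            truths = {}
            for i in range(config.n_stacks):
                params = SimParams(**sim_kwargs, seed=config.seed + i)
                if "shape" in sim_kwargs:
                    params = dataclasses.replace(
                        params, shape=tuple(sim_kwargs["shape"])
                    )
                stack, labels, truth = generate_coculture_stack(params)
                sid = f"stack_{i:02d}"
                stacks.append((sid, stack))
                label_volumes[sid] = labels
                truth_labels[sid] = labels
                truths[sid] = truth
                write_stack(stack, out_dir / f"{sid}.tif")
                write_labels(labels, out_dir / f"{sid}_truth_labels.tif")
                write_ground_truth(truth, out_dir / f"{sid}_truth.json")
            report["counts"]["simdata"] = {
                sid: {
                    "n_b": t.count("B"),
                    "n_t": t.count("T"),
                    "n_other": t.count("other"),
                    "n_coloc_pairs": t.n_coloc_pairs,
                }
                for sid, t in truths.items()
            }
        elif "stacks" in config.inputs:
            for i, p in enumerate(config.inputs["stacks"]):
                stacks.append((f"stack_{i:02d}", read_stack(p)))

        if "scaffold" in config.stages:
            current = "scaffold"
            params = FilterParams(**{
                k: tuple(v) if k == "channels" else v
                for k, v in config.scaffold.items()
            })
            voxels = {}
            for sid, stack in stacks:
                mask = segment_scaffold(stack, params)
                import tifffile

                tifffile.imwrite(
                    out_dir / f"{sid}_scaffold.tif",
                    (mask.astype(np.uint8) * 255),
                )
                voxels[sid] = int(mask.sum())
            report["counts"]["scaffold"] = {"foreground_voxels": voxels}

        if "nucseg" in config.stages:
            current = "nucseg"
            params = SegParams(**config.nucseg.get("params", config.nucseg))
            channel = config.nucseg.get("channel", "nuc")
            n_labels = {}
            for sid, stack in stacks:
                labels = segment_nuclei(stack[channel], params)
                label_volumes[sid] = labels
                write_labels(labels, out_dir / f"{sid}_labels.tif")
                n_labels[sid] = int(labels.max())
            report["counts"]["nucseg"] = {"n_labels": n_labels}
        elif "labels" in config.inputs:
            labels, _ = read_labels(config.inputs["labels"])
            label_volumes[stacks[0][0] if stacks else "stack_00"] = labels

        if "phenotype" in config.stages:
            current = "phenotype"
            ph = config.phenotype
            markers = list(ph.get("markers", ["CD19", "CD3", "CASP3"]))
            percentiles = dict(ph.get("percentiles", DEFAULT_PERCENTILES))
            mode = ph.get("mode", "double_pos_or_adjacent")
            source = (
                truth_labels
                if ph.get("use_ground_truth_labels", False) and truth_labels
                else label_volumes
            )
            tables = []
            for sid, stack in stacks:
                table = extract_mask_intensities(
                    source[sid], stack, markers, stack_id=sid
                )
                tables.append(normalize_intensities(table, markers))
            thresholds = pool_and_threshold(tables, percentiles)
            stack_counts = {}
            classified = []
            for (sid, _stack), table in zip(stacks, tables):
                cls = classify_cells(table, thresholds)
                counts, cls = count_colocalized(source[sid], cls, mode=mode)
                classified.append(cls)
                stack_counts[sid] = {
                    "n_total_masks": counts.n_total_masks,
                    "n_cd19": counts.n_cd19,
                    "n_cd3": counts.n_cd3,
                    "n_double_pos": counts.n_double_pos,
                    "n_coloc": counts.n_coloc,
                }
            import pandas as pd

            cells = pd.concat(classified, ignore_index=True)
            cells.to_csv(out_dir / "cells.csv", index=False)
            (out_dir / "thresholds.json").write_text(
                json.dumps(
                    {
                        "percentiles": thresholds.percentiles,
                        "thresholds": thresholds.thresholds,
                        "n_pooled": thresholds.n_pooled,
                    },
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
            report["counts"]["phenotype"] = {
                "per_stack": stack_counts,
                "n_coloc_total": int(sum(c["n_coloc"] for c in stack_counts.values())),
            }

        if "crosstalk" in config.stages:
            current = "crosstalk"
            ct = dict(config.crosstalk)
            if ct.get("from_simdata", "ppi" not in ct):
                bundle = generate_omics_bundle(
                    n_genes=int(ct.get("n_genes", 120)),
                    n_clusters=int(ct.get("n_clusters", 8)),
                    n_planted=int(ct.get("n_planted", 6)),
                    seed=config.seed,
                )
                omics_dir = out_dir / "omics"
                paths = write_omics_bundle(bundle, omics_dir)
                ppi = read_ppi_table(paths["ppi"], dialect="generic_tsv")
                b_de, cluster_de = bundle.b_de_table, bundle.cluster_de_table
            else:
                import pandas as pd

                ppi = read_ppi_table(
                    ct["ppi"],
                    dialect=ct.get("dialect", "generic_tsv"),
                    min_confidence=float(ct.get("min_confidence", 0.0)),
                )
                b_de = pd.read_csv(ct["b_de"], sep="\t")
                cluster_de = pd.read_csv(ct["bmsc_de"], sep="\t")
            alpha = float(ct.get("alpha", 0.05))
            bmsc_map = filter_bmsc_genes(
                cluster_de, min_pct=float(ct.get("min_pct", 0.10)), alpha=alpha
            )
            records = cross_reference(
                ppi,
                de_gene_directions(b_de, alpha),
                bmsc_map,
                b_bmsc_only=bool(ct.get("b_bmsc_only", False)),
            )
            frame = interactions_to_frame(records)
            frame.to_csv(out_dir / "interactions.csv", index=False)
            frame[["gene_a", "gene_b", "class", "confidence"]].to_csv(
                out_dir / "interaction_edges.tsv", sep="\t", index=False
            )
            report["counts"]["crosstalk"] = {
                "n_interactions": len(records),
                "by_class": frame["class"].value_counts().to_dict(),
            }
    except Exception as exc:
        # partial outputs remain alongside the FAILED marker
        (out_dir / "FAILED").write_text(f"stage: {current}\n")
        log.error("pipeline failed in stage %r", current)
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            report["outputs"][str(path.relative_to(out_dir))] = _sha256(path)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
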