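"""Pipeline orchestration: config validation, stage sequencing, manifest.

Stages run in a fixed order — simulate (optional) -> call-islands ->
annotate -> profile -> predict — each writing its outputs under the
configured directory and recording them, with parameters and seed, in a
manifest JSON. One global seed governs all randomness; each stage
derives a stable sub-seed from (stage name, seed) so toggling one stage
never perturbs another's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (
    genome_model,
    island_calling,
    island_predictor,
    profiles,
    signal_io,
    synthetic_data,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call_islands", "annotate", "profile", "predict")


def stage_seed(stage: str, seed: int) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    out_dir: str = "axisislands_out"
    seed: int = 0
    bin_size: int = 5000
    k: float = 1.75
    threshold_mode: str = "sd"
    n_boot: int = 1000
    flank: int = 2000
    train_fraction: float = 0.8
    prob_threshold: float = 0.5
    exclude_chroms: list[str] = field(default_factory=list)
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # input paths (unused when the simulate stage provides them)
    track: str | None = None
    chrom_sizes: str | None = None
    annotation: str | None = None
    anchors: str | None = None
    feature_type: str = "gene"
    sim: dict = field(default_factory=dict)  # SimParams overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needs_inputs = any(
            self.stages.get(s) for s in ("call_islands", "annotate", "profile")
        )
        if needs_inputs and not self.stages.get("simulate"):
            for name in ("track", "chrom_sizes", "annotation"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"stage inputs require config key {name!r}")
                if not Path(p).exists():
                    raise ValueError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return (and write) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "bin_size": config.bin_size,
            "k": config.k,
            "threshold_mode": config.threshold_mode,
            "n_boot": config.n_boot,
            "flank": config.flank,
            "train_fraction": config.train_fraction,
            "exclude_chroms": config.exclude_chroms,
        },
        "stages": {},
        "files": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = True
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    annotation = None
    track = None
    truth = None

    try:
        if config.stages.get("simulate"):
            params = synthetic_data.SimParams(**config.sim)
            sseed = stage_seed("simulate", config.seed)
            annotation, truth = synthetic_data.simulate_genome(params, sseed)
            track = synthetic_data.simulate_axis_track(
                annotation, truth, params, stage_seed("simulate.track", config.seed)
            )
            expr = synthetic_data.simulate_expression(
                annotation, truth, params, stage_seed("simulate.expr", config.seed)
            )
            gff = out / "annotation.gff3"
            sizes = out / "chrom.sizes"
            bg = out / "axis.bedgraph"
            tb = out / "truth_islands.bed"
            ex = out / "expression.tsv"
            synthetic_data.write_annotation_gff3(annotation, gff)
            synthetic_data.write_chrom_sizes(annotation.chrom_lengths, sizes)
            signal_io.write_track(track, bg)
            genome_model.write_regions_bed(
                tb, [(iv, "island") for iv in truth.islands]
            )
            expr.to_csv(ex, sep="\t", index=False)
            record("simulate", gff, sizes, bg, tb, ex)
        else:
            if config.chrom_sizes and config.annotation:
                annotation = genome_model.read_annotation(
                    config.annotation, config.chrom_sizes, config.feature_type
                )
            if config.track and config.chrom_sizes:
                track = signal_io.read_track(config.track, config.chrom_sizes)

        partition = None
        binned = None
        if config.stages.get("call_islands"):
            if track is None:
                raise RuntimeError("call_islands requires a signal track")
            binned = signal_io.bin_signal(track, config.bin_size)
            partition = island_calling.call_islands(
                binned, config.k, config.threshold_mode
            )
            regions_bed = out / "regions.bed"
            island_calling.write_partition_bed(partition, regions_bed, track)
            stats = island_calling.region_summary(partition, track=track)
            stats_tsv = out / "region_stats.tsv"
            stats.per_region.to_csv(stats_tsv, sep="\t", index=False)
            group_tsv = out / "region_group_summary.tsv"
            stats.group_summary.to_csv(group_tsv, sep="\t", index=False)
            record("call_islands", regions_bed, stats_tsv, group_tsv)

        bins_labeled = None
        if config.stages.get("annotate"):
            if annotation is None or binned is None or partition is None:
                raise RuntimeError(
                    "annotate requires an annotation and a completed call_islands stage"
                )
            density = genome_model.coding_density(annotation, binned.intervals)
            bins_labeled = island_predictor.label_bins(
                partition, binned.intervals, density
            )
            bins_tsv = out / "bins.tsv"
            bins_labeled.to_tsv(bins_tsv)
            pairs = genome_model.gene_pairs(annotation)
            import pandas as pd

            pairs_df = pd.DataFrame(
                {
                    "left": [p.left.id for p in pairs],
                    "right": [p.right.id for p in pairs],
                    "pair_class": [p.pair_class for p in pairs],
                    "intergenic_length": [p.intergenic_length for p in pairs],
                    "overlapping": [p.intergenic is None for p in pairs],
                }
            )
            pairs_tsv = out / "gene_pairs.tsv"
            pairs_df.to_csv(pairs_tsv, sep="\t", index=False)
            record("annotate", bins_tsv, pairs_tsv)

        if config.stages.get("profile"):
            if track is None or annotation is None:
                raise RuntimeError("profile requires a track and an annotation")
            if config.anchors:
                anchors = profiles.read_anchors_bed(config.anchors)
            else:  # default anchors: gene starts (ATGs)
                anchors = profiles.AnchorSet(
                    [
                        profiles.Anchor(
                            g.id,
                            g.interval.chrom,
                            g.interval.start
                            if g.interval.strand == "+"
                            else g.interval.end - 1,
                            g.interval.strand,
                        )
                        for g in annotation.genes
                    ],
                    kind="ATG",
                )
            labels = None
            if partition is not None:
                labels = [
                    partition.label_at(a.chrom, a.pos) for a in anchors.anchors
                ]
            matrix = profiles.anchor_matrix(
                track, anchors, config.flank, strand_aware=True, region_labels=labels
            )
            pseed = stage_seed("profile", config.seed)
            written = []
            groups = (
                [(lab, matrix.subset(matrix.row_meta["region"] == lab))
                 for lab in ("island", "desert")]
                if labels is not None
                else [("all", matrix)]
            )
            for name, sub in groups:
                if sub.n_rows == 0:
                    continue
                ci = profiles.mean_profile_ci(sub, config.n_boot, seed=pseed)
                p = out / f"profile_{name}.tsv"
                ci.to_frame().to_csv(p, sep="\t", index=False)
                written.append(p)
            record("profile", *written)

        if config.stages.get("predict"):
            if bins_labeled is None:
                raise RuntimeError("predict requires the annotate stage")
            model, report = island_predictor.train_and_evaluate(
                bins_labeled,
                config.train_fraction,
                stage_seed("predict", config.seed),
                prob_threshold=config.prob_threshold,
                exclude_chroms=config.exclude_chroms,
            )
            model_json = out / "model.json"
            model.to_json(model_json)
            report_json = out / "report.json"
            with open(report_json, "w") as fh:
                json.dump(
                    {
                        "accuracy": report.accuracy,
                        "auc": report.auc,
                        "n_test": report.n_test,
                        "prob_threshold": report.prob_threshold,
                        "note": report.note,
                    },
                    fh,
                    indent=2,
                )
            written = [model_json, report_json]
            if report.roc is not None:
                import pandas as pd

                roc_tsv = out / "roc.tsv"
                pd.DataFrame(report.roc, columns=["fpr", "tpr"]).to_csv(
                    roc_tsv, sep="\t", index=False
                )
                written.append(roc_tsv)
            record("predict", *written)
    except Exception as e:
        logger.error("pipeline stage failed: %s", e)
        raise

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
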