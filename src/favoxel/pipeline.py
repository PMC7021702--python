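"""Whole-study orchestration: regions x contrasts accuracy report.

Runs the whole-brain analysis and the eight per-region analyses for the
three binary contrasts, producing a JSON report, an accuracy table
(regions x contrasts TSV), descriptive Fisher-score maps and a run log.
Everything is deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import favoxel
from favoxel.classification import (
    CONTRASTS,
    SelectionRule,
    discriminative_map,
    loocv,
)
from favoxel.roi_features import AtlasLabels, extract_features, region_mask
from favoxel.synthetic_data import TOY_REGIONS
from favoxel.volume_io import read_manifest, write_volume

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: str
    atlas_volume: str
    atlas_names: str
    out_dir: str
    regions: list[str] = field(default_factory=lambda: ["whole_brain", *TOY_REGIONS])
    fisher_threshold: float | None = None
    direction: str = "any"
    map_threshold: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in (self.manifest, self.atlas_volume, self.atlas_names):
            if not Path(p).exists():
                raise FileNotFoundError(f"pipeline input not found: {p}")

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def run_dir(self) -> Path:
        digest = hashlib.sha256(self.to_yaml_str().encode()).hexdigest()[:12]
        return Path(self.out_dir) / f"run-{digest}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis plan and write the report bundle.

    Returns the report dict; writes ``results.json``, ``accuracy.tsv``,
    per-region Fisher maps and ``run.log`` under a config-hash-named
    directory so identical configs land in identical places.
    """
    config.validate()
    run_dir = config.run_dir()
    run_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setLevel(config.log_level)
    root = logging.getLogger("favoxel")
    root.addHandler(handler)
    try:
        manifest = read_manifest(config.manifest)
        atlas = AtlasLabels.load(config.atlas_volume, config.atlas_names)
        logger.info("pipeline start: %d subjects, atlas=%s", len(manifest.table), atlas.provenance)

        report = {
            "version": favoxel.__version__,
            "config": asdict(config),
            "cells": [],
        }
        acc_table = pd.DataFrame(
            index=config.regions, columns=["_vs_".join(p) for p in CONTRASTS], dtype=float
        )
        for region in config.regions:
            mask = region_mask(atlas, region)
            features = extract_features(manifest, mask)
            for pair in CONTRASTS:
                rule = SelectionRule(
                    fisher_threshold=config.fisher_threshold,
                    direction=config.direction,
                    class_pair=pair,
                )
                try:
                    result = loocv(features, rule)
                except Exception as exc:
                    raise RuntimeError(
                        f"classification stage failed for region {region!r}, "
                        f"contrast {pair}: {exc}"
                    ) from exc
                logger.info(
                    "%s %s: accuracy %.3f (%d folds)",
                    region, "_vs_".join(pair), result.accuracy, result.n,
                )
                report["cells"].append(
                    {"region": region, "contrast": "_vs_".join(pair), **result.to_dict()}
                )
                acc_table.loc[region, "_vs_".join(pair)] = result.accuracy
            score_vol, mask_vol = discriminative_map(
                features, mask.grid, CONTRASTS[0], config.map_threshold
            )
            write_volume(score_vol, run_dir / f"fisher_{region}.nii.gz")
            write_volume(mask_vol, run_dir / f"fisher_{region}_suprathreshold.nii.gz")

        (run_dir / "results.json").write_text(json.dumps(report, indent=2))
        acc_table.to_csv(run_dir / "accuracy.tsv", sep="\t", index_label="region")
        (run_dir / "config.yaml").write_text(config.to_yaml_str())
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def aggregate_report(run_dir) -> pd.DataFrame:
    """Re-read a prior run's results.json into the accuracy table without
    recomputation."""
    report = json.loads((Path(run_dir) / "results.json").read_text())
    rows = {}
    for cell in report["cells"]:
        rows.setdefault(cell["region"], {})[cell["contrast"]] = cell["accuracy"]
    return pd.DataFrame.from_dict(rows, orient="index")
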