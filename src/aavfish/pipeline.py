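"""Configured, file-mediated pipeline runs.

A YAML run configuration validates into :class:`RunConfig` (unknown keys
rejected). ``run_pipeline`` executes simulate -> segment -> detect ->
assign -> count (-> colocalize, -> dilution statistics) with every stage
boundary on disk, so any stage can be re-run from its files, and writes
a manifest of checksums for reproducibility audits. Stage seeds are
substreams of the master seed derived from stage names, so stages are
reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

import aavfish
from aavfish import io as aio
from aavfish.detect import (
    DetectionParams, assign_puncta, detect_puncta, per_cell_counts,
)
from aavfish.coloc import coloc_probability, match_puncta
from aavfish.segment import build_cell_table, enhance_membranes, segment_cells, segment_nuclei
from aavfish.simulate import (
    ExpressionModel, InfectionModel, RenderParams, TissueParams,
    render_volume, simulate_expression, simulate_genomes, simulate_tissue,
    tissue_mask_for,
)
from aavfish.stats import count_distribution, dilution_fit, expression_by_count
from aavfish.volumes import LabelVolume

log = logging.getLogger(__name__)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissueBlock(_Block):
    shape: tuple[int, int, int] = (40, 192, 192)
    voxel_size: tuple[float, float, float] = (0.4, 0.2, 0.2)
    n_cells: int = 200
    nucleus_radius: float = 1.0
    membrane_thickness: int = 1
    slab_fraction: float = 0.8
    margin_um: tuple[float, float, float] | None = None

    def to_params(self) -> TissueParams:
        return TissueParams(**self.model_dump())


class InfectionBlock(_Block):
    lam: float = 2.1
    titer_scale: float = 1.0
    nuclear_fraction: float = 0.8
    coloc_mode: str = "single"
    detection_efficiency: dict[str, float] = Field(
        default_factory=lambda: {"punctaA": 1.0, "punctaB": 1.0}
    )
    coloc_offset_sigma: float = 0.05

    def to_params(self) -> InfectionModel:
        return InfectionModel(**self.model_dump())


class RenderBlock(_Block):
    psf_sigma: tuple[float, float, float] = (0.4, 0.15, 0.15)
    punctum_amplitude: float = 800.0
    membrane_amplitude: float = 400.0
    nuclear_amplitude: float = 300.0
    background: float = 10.0
    noise: str = "poisson"
    gaussian_sigma: float = 5.0

    def to_params(self) -> RenderParams:
        return RenderParams(**self.model_dump())


class ExpressionBlock(_Block):
    baseline: float = 50.0
    increment: float = 100.0
    saturation: float = 8.0
    noise_sigma: float = 20.0
    threshold: float = 120.0

    def to_params(self) -> ExpressionModel:
        return ExpressionModel(**self.model_dump())


class DetectionBlock(_Block):
    psf_sigma_lateral: float = 0.15
    scales: tuple[float, ...] | None = None
    axial_ratio: float = 0.4 / 0.15
    k: float = 5.0
    min_separation: float = 0.3

    def to_params(self) -> DetectionParams:
        from aavfish.detect import default_scales

        scales = self.scales or default_scales(self.psf_sigma_lateral)
        return DetectionParams(
            scales=tuple(scales), axial_ratio=self.axial_ratio,
            k=self.k, min_separation=self.min_separation,
        )


class ColocBlock(_Block):
    radius: float = 0.3


class StatsBlock(_Block):
    count_bins: tuple[int, ...] = (0, 1, 2, 3, 4)
    power_exponent: float = 2.0


class SegmentationBlock(_Block):
    sigma_smooth: float = 0.3
    plateness: bool = False
    nucleus_min_volume: float = 1.0


class RunConfig(_Block):
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 0
    out: str = "aavfish_run"
    titer_groups: list[float] | None = None
    tissue: TissueBlock = Field(default_factory=TissueBlock)
    infection: InfectionBlock = Field(default_factory=InfectionBlock)
    render: RenderBlock = Field(default_factory=RenderBlock)
    expression: ExpressionBlock | None = None
    segmentation: SegmentationBlock = Field(default_factory=SegmentationBlock)
    detection: DetectionBlock = Field(default_factory=DetectionBlock)
    coloc: ColocBlock = Field(default_factory=ColocBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def stage_seed(master: int, stage: str) -> np.random.Generator:
    """Independent substream for one named stage of one run."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_group(cfg: RunConfig, gdir: Path, titer_scale: float, tag: str):
    """Simulate one condition and write its files; returns file dict."""
    gdir.mkdir(parents=True, exist_ok=True)
    tissue = cfg.tissue.to_params()
    infection = InfectionModel(**{
        **cfg.infection.to_params().__dict__, "titer_scale": titer_scale,
    })
    labels, nuclei, cells = simulate_tissue(tissue, stage_seed(cfg.seed, f"tissue/{tag}"))
    truth = simulate_genomes(labels, nuclei, infection,
                             stage_seed(cfg.seed, f"genomes/{tag}"), cells)
    img = render_volume(labels, nuclei, truth, cfg.render.to_params(),
                        stage_seed(cfg.seed, f"render/{tag}"),
                        membrane_thickness=tissue.membrane_thickness)
    if cfg.expression is not None:
        simulate_expression(truth, cfg.expression.to_params(),
                            stage_seed(cfg.seed, f"expression/{tag}"))
    files = {
        "image": gdir / "image.tif",
        "mask": gdir / "tissue_mask.tif",
        "true_cells": gdir / "true_cells.tif",
        "true_nuclei": gdir / "true_nuclei.tif",
        "truth_puncta": gdir / "truth_puncta.csv",
        "truth_counts": gdir / "truth_counts.csv",
    }
    aio.write_image(img, files["image"])
    aio.write_mask(tissue_mask_for(tissue), tissue.voxel_size, files["mask"])
    aio.write_labels(labels, files["true_cells"])
    aio.write_labels(nuclei, files["true_nuclei"])
    truth.puncta.to_csv(files["truth_puncta"], index=False)
    truth.cell_counts.to_csv(files["truth_counts"], index=False)
    if truth.expression is not None:
        files["truth_expression"] = gdir / "truth_expression.csv"
        truth.expression.to_csv(files["truth_expression"], index=False)
    return files


def _analyze_group(cfg: RunConfig, gdir: Path, files: dict) -> dict:
    """Segment, detect, assign and count from the on-disk group files."""
    img = aio.read_image(files["image"])
    mask = aio.read_mask(files["mask"])
    seg = cfg.segmentation
    nuclei = segment_nuclei(img, min_volume=seg.nucleus_min_volume,
                            sigma_smooth=seg.sigma_smooth)
    enhanced = enhance_membranes(img, sigma_smooth=seg.sigma_smooth,
                                 plateness=seg.plateness)
    cells = segment_cells(enhanced, img.voxel_size, seeds=nuclei, tissue_mask=mask)
    cell_table = build_cell_table(cells, tissue_mask=mask)
    aio.write_labels(cells, gdir / "cells.tif")
    aio.write_labels(nuclei, gdir / "nuclei.tif")
    cell_table.to_csv(gdir / "cells.csv", index=False)
    files.update({"cells": gdir / "cells.tif", "nuclei": gdir / "nuclei.tif",
                  "cell_table": gdir / "cells.csv"})

    dparams = cfg.detection.to_params()
    puncta_channels = [c for c in img.channels if c.startswith("puncta")]
    counts = {}
    for ch in puncta_channels:
        raw = detect_puncta(img, ch, dparams, tissue_mask=mask)
        assigned = assign_puncta(raw, cells, nuclei, cell_table)
        assigned.to_csv(gdir / f"puncta_{ch}.csv", index=False)
        files[f"puncta_{ch}"] = gdir / f"puncta_{ch}.csv"
        cc = per_cell_counts(assigned, cell_table, channel=ch)
        cc.to_csv(gdir / f"counts_{ch}.csv", index=False)
        files[f"counts_{ch}"] = gdir / f"counts_{ch}.csv"
        counts[ch] = cc
    result = {"cell_table": cell_table, "counts": counts,
              "puncta_channels": puncta_channels}
    if len(puncta_channels) == 2:
        a = pd.read_csv(files[f"puncta_{puncta_channels[0]}"])
        b = pd.read_csv(files[f"puncta_{puncta_channels[1]}"])
        a, b = a[a["retained"]], b[b["retained"]]
        if len(a) == 0 and len(b) == 0:
            log.warning("no retained puncta in either channel; "
                        "colocalization skipped")
        else:
            pairs = match_puncta(a, b, cfg.coloc.radius)
            res = coloc_probability(pairs, len(a), len(b), cfg.coloc.radius)
            res.to_json(gdir / "coloc.json")
            pairs.to_csv(gdir / "coloc_pairs.csv", index=False)
            files["coloc"] = gdir / "coloc.json"
            result["coloc"] = res
    return result


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute a full configured run; returns the manifest dict.

    With ``titer_groups`` set, one simulated volume per relative titer
    is generated and analyzed, and the limiting-dilution regression is
    fit over the recovered per-cell counts. Without it a single
    condition is simulated and analyzed (plus colocalization when two
    puncta channels exist, and the count distribution / expression
    trend when configured).
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    t0 = time.time()
    config_text = json.dumps(config.model_dump(), indent=2, default=list)
    (out / "config.json").write_text(config_text)
    files: dict[str, Path] = {"config": out / "config.json"}
    results: dict = {}

    groups = config.titer_groups or [None]
    all_counts = []
    for gi, titer in enumerate(groups):
        tag = f"group{gi}" if titer is not None else "run"
        scale = titer if titer is not None else config.infection.titer_scale
        gdir = out / tag
        log.info("simulating %s (relative titer %s)", tag, scale)
        gfiles = _simulate_group(config, gdir, scale, tag)
        ana = _analyze_group(config, gdir, gfiles)
        files.update({f"{tag}/{k}": v for k, v in gfiles.items()})
        ch = ana["puncta_channels"][0]
        all_counts.append(ana["counts"][ch]["count"].to_numpy())
        results[tag] = ana

    if config.titer_groups is not None:
        fit = dilution_fit(config.titer_groups, all_counts,
                           power_exponent=config.stats.power_exponent)
        fit.to_json(out / "dilution_fit.json")
        files["dilution_fit"] = out / "dilution_fit.json"
        results["dilution_fit"] = fit
    else:
        dist = count_distribution(all_counts[0], bins=config.stats.count_bins)
        (out / "count_distribution.json").write_text(json.dumps(dist, indent=2))
        files["count_distribution"] = out / "count_distribution.json"
        results["count_distribution"] = dist
        if config.expression is not None:
            truth_expr = pd.read_csv(out / "run" / "truth_expression.csv")
            ana = results["run"]
            ch = ana["puncta_channels"][0]
            merged = ana["counts"][ch].merge(truth_expr, on="cell_id")
            trend = expression_by_count(
                merged["count"], merged["expression"],
                bins=config.stats.count_bins, seed=config.seed,
            )
            (out / "expression_trend.json").write_text(json.dumps(trend, indent=2))
            files["expression_trend"] = out / "expression_trend.json"
            results["expression_trend"] = trend

    manifest = {
        "package_version": aavfish.__version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "started": t0,
        "finished": time.time(),
        "files": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                  for k, v in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
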