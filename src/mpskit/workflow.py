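"""Orchestration: configuration, end-to-end demo runs and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mpskit import __version__
from mpskit.errors import ConfigurationError
from mpskit.fixtures import (
    SlideSpec,
    StackSpec,
    gen_fov_stacks,
    gen_slide,
)
from mpskit.imaging import (
    compare_conditions,
    detect_scaffolds,
    measure_intensity,
    place_rois,
    segment_microtissues,
    select_focus,
    stitch_tiles,
    summarize,
)

log = logging.getLogger(__name__)

DEFAULT_CONDITION_FOLDS: dict[str, dict[str, float]] = {
    "control": {},
    "nash": {"asma": 6.0, "collagen1": 8.0},
}


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end demo run."""

    seed: int = 0
    out_dir: str = "mpskit_out"
    stages: tuple[str, ...] = ("fixtures", "imaging", "comparison")
    slide: dict = field(default_factory=dict)
    stack: dict = field(default_factory=dict)
    condition_folds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITION_FOLDS.items()}
    )
    n_scaffolds_per_condition: int = 3
    fovs_per_scaffold: int = 3
    reference_condition: str = "control"
    log_level: str = "INFO"

    KNOWN_STAGES = ("fixtures", "imaging", "comparison")

    def __post_init__(self) -> None:
        problems = []
        for s in self.stages:
            if s not in self.KNOWN_STAGES:
                problems.append(f"unknown stage {s!r}")
        if self.n_scaffolds_per_condition < 1:
            problems.append("n_scaffolds_per_condition must be >= 1")
        if self.fovs_per_scaffold < 1:
            problems.append("fovs_per_scaffold must be >= 1")
        if self.reference_condition not in self.condition_folds:
            problems.append(
                f"reference_condition {self.reference_condition!r} missing from condition_folds"
            )
        if "comparison" in self.stages and "imaging" not in self.stages:
            problems.append("comparison stage requires the imaging stage")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: list[str]
    outputs: list[str]
    wall_time_s: float
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    fixtures: seeded slide + per-condition FOV stacks; imaging: stitch,
    detect scaffolds, place ROIs, focus, segment, measure, aggregate;
    comparison: condition fold changes against the reference.  All result
    tables are CSV; the manifest lists every output exactly once.
    """
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    warnings_seen: list[str] = []

    slide_spec = _slide_spec(config)
    rng = np.random.default_rng(config.seed)

    tiles, slide_truth = gen_slide(slide_spec)
    if "fixtures" in config.stages:
        truth_path = out / "slide_truth.json"
        truth_path.write_text(json.dumps(slide_truth.to_jsonable(), indent=2, default=float))
        outputs.append(str(truth_path))

    records_rows: list[dict] = []
    scaffold_rows: list[dict] = []
    comparison_rows: list[dict] = []

    if "imaging" in config.stages:
        mosaic = stitch_tiles(tiles, slide_spec.overlap_frac)
        detections = detect_scaffolds(mosaic, slide_spec.scaffold_radius_px)
        log.info("imaging: %d scaffolds detected on the slide mosaic", len(detections))

        roi_rows = []
        for sid, det in enumerate(detections):
            roi_set = place_rois(
                det, slide_spec.roi_template, roi_size_px=64,
                mosaic_shape=mosaic.pixels.shape, scaffold_id=sid,
            )
            for ridx, (r, c) in enumerate(roi_set.centres):
                roi_rows.append(
                    {"scaffold_id": sid, "roi_idx": ridx, "row_px": r, "col_px": c}
                )
        roi_path = out / "roi_coordinates.csv"
        pd.DataFrame(roi_rows).to_csv(roi_path, index=False)
        outputs.append(str(roi_path))

        fov_to_scaffold: dict[str, str] = {}
        scaffold_to_condition: dict[str, str] = {}
        all_records = []
        for condition, folds in config.condition_folds.items():
            for s in range(config.n_scaffolds_per_condition):
                scaffold_id = f"{condition}_s{s}"
                scaffold_to_condition[scaffold_id] = condition
                stack_spec = _stack_spec(config, folds, seed=int(rng.integers(0, 2**31 - 1)))
                fovs = gen_fov_stacks(
                    stack_spec,
                    config.fovs_per_scaffold,
                    count_range=slide_spec.microtissues_per_fov_range,
                    radius_range=slide_spec.microtissue_radius_px_range,
                    fov_prefix=f"{scaffold_id}_fov",
                )
                for stack, truth in fovs:
                    fov_id = truth.microtissues[0].fov_id if truth.microtissues else "empty"
                    fov_to_scaffold[fov_id] = scaffold_id
                    focus = select_focus(stack)
                    labels, recs = segment_microtissues(
                        stack.channel("nuclei")[focus.plane_idx], fov_id=fov_id
                    )
                    recs = measure_intensity(labels, stack, focus, recs)
                    all_records.extend(recs)
                    log.info(
                        "imaging: %s focus plane %d, %d microtissues",
                        fov_id, focus.plane_idx, len(recs),
                    )

        fov_summaries, scaffold_summaries = summarize(
            all_records, fov_to_scaffold, scaffold_to_condition
        )
        for rec in all_records:
            row = {
                "fov_id": rec.fov_id,
                "label": rec.label,
                "area_px": rec.area_px,
                "centroid_row": rec.centroid[0],
                "centroid_col": rec.centroid[1],
            }
            row.update({f"total_{ch}": v for ch, v in rec.total_intensity.items()})
            records_rows.append(row)
        micro_path = out / "microtissues.csv"
        pd.DataFrame(records_rows).to_csv(micro_path, index=False)
        outputs.append(str(micro_path))

        for s in scaffold_summaries:
            row = {
                "scaffold_id": s.scaffold_id,
                "condition": s.condition,
                "n_fovs": s.n_fovs,
                "n_microtissues": s.n_microtissues,
            }
            row.update({f"mean_{ch}": v for ch, v in s.mean_intensity.items()})
            scaffold_rows.append(row)
        scaffold_path = out / "scaffolds.csv"
        pd.DataFrame(scaffold_rows).to_csv(scaffold_path, index=False)
        outputs.append(str(scaffold_path))

        if "comparison" in config.stages:
            comparisons = compare_conditions(scaffold_summaries, config.reference_condition)
            for cmp_row in comparisons:
                comparison_rows.append(
                    {
                        "channel": cmp_row.channel,
                        "condition": cmp_row.condition,
                        "reference": cmp_row.reference,
                        "fold_change": cmp_row.fold_change,
                        "percent_change": cmp_row.percent_change,
                        "p_value": cmp_row.p_value,
                    }
                )
            cmp_path = out / "comparisons.csv"
            pd.DataFrame(comparison_rows).to_csv(cmp_path, index=False)
            outputs.append(str(cmp_path))

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        stages=list(config.stages),
        outputs=outputs,
        wall_time_s=round(time.monotonic() - t0, 3),
        warnings=warnings_seen,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _slide_spec(config: RunConfig) -> SlideSpec:
    defaults = dict(
        grid_rows=2,
        grid_cols=2,
        tile_size_px=256,
        overlap_frac=0.1,
        scaffold_centers=[(230.0, 230.0)],
        scaffold_radius_px=80.0,
        seed=config.seed,
    )
    defaults.update(config.slide)
    return SlideSpec(**defaults)


def _stack_spec(config: RunConfig, folds: dict[str, float], seed: int) -> StackSpec:
    defaults = dict(condition_fold=dict(folds), seed=seed)
    defaults.update(config.stack)
    defaults["condition_fold"] = dict(folds)
    return StackSpec(**defaults)
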