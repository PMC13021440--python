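"""End-to-end workflow: priors → centerlines → prompting/segmentation → quantification.

Given a CTA-like volume plus rectus muscle masks (or a self-generated
phantom), the pipeline derives the anatomical priors, extracts candidate
centerlines, drives a promptable backend slice-wise, evaluates the stacked
segmentation against ground truth when available, re-extracts centerlines
from the prediction and reports the clinical descriptors per perforator.
Every run directory is self-describing: the config echo and seed suffice to
reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import anatomy, centerline as cl, evaluate, prompting, quantify
from .anatomy import AnatomyPriors
from .phantom import PhantomCase, PhantomConfig, export_case, generate_phantom
from .volume_io import Mask, Volume, read_landmark, read_mask, read_volume, write_volume

__all__ = ["RunConfig", "ValidationError", "run_pipeline", "match_centerlines"]

log = logging.getLogger("perfmap")


class ValidationError(ValueError):
    """Configuration or input problem detected before any computation."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs; loadable from one YAML file."""

    out_dir: str = "perfmap_run"
    seed: int = 0
    phantom: bool = False

    # input paths (ignored when phantom=True)
    image: Optional[str] = None
    muscle_left: Optional[str] = None
    muscle_right: Optional[str] = None
    landmark: Optional[str] = None
    gt_vessels: Optional[str] = None

    # anatomy stage
    enhance_window: tuple[float, float] = (150.0, 450.0)
    tophat_radius: Optional[int] = None
    air_threshold: float = -500.0
    fascia_thickness_voxels: int = 2
    candidate_threshold: float = 0.5
    min_component_voxels: int = 30
    posterior_margin_mm: float = 12.0

    # centerline stage
    min_length_mm: float = 10.0

    # prompting stage
    backend: str = "region-grow"
    refine_radius_voxels: int = 5
    ring_inner: int = 4
    ring_outer: int = 8
    n_negatives: int = 4
    max_intensity_fraction: float = 0.6
    region_grow_low_fraction: float = 0.6

    # quantification stage
    y_threshold_voxels: int = 20
    centrality_radius_mm: float = 80.0
    split_at_gaps: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.enhance_window
        if not lo < hi:
            raise ValidationError(f"degenerate enhancement window {self.enhance_window}")
        if not 0 < self.candidate_threshold <= 1:
            raise ValidationError("candidate_threshold must be in (0, 1]")
        if self.refine_radius_voxels < 0:
            raise ValidationError("refine_radius_voxels must be >= 0")
        if self.ring_inner >= self.ring_outer:
            raise ValidationError("ring_inner must be < ring_outer")
        if self.y_threshold_voxels < 0:
            raise ValidationError("y_threshold_voxels must be >= 0")
        if self.backend not in ("oracle", "region-grow"):
            raise ValidationError(f"unknown backend {self.backend!r}")
        if not self.phantom:
            missing = [
                k for k in ("image", "muscle_left", "muscle_right") if getattr(self, k) is None
            ]
            if missing:
                raise ValidationError(f"missing required inputs: {', '.join(missing)}")
        if self.backend == "oracle" and not self.phantom and self.gt_vessels is None:
            raise ValidationError("the oracle backend needs gt_vessels (or --phantom)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "enhance_window" in data:
            data["enhance_window"] = tuple(data["enhance_window"])
        return cls(**data)

    def prompt_params(self) -> prompting.PromptParams:
        return prompting.PromptParams(
            refine_radius_voxels=self.refine_radius_voxels,
            ring_inner=self.ring_inner,
            ring_outer=self.ring_outer,
            n_negatives=self.n_negatives,
            max_intensity_fraction=self.max_intensity_fraction,
        )


def compute_priors(
    image: Volume,
    muscle_left: Mask,
    muscle_right: Mask,
    cfg: RunConfig,
    landmark=None,
) -> tuple[AnatomyPriors, Volume]:
    """Anatomy stage: enhanced volume plus all prior structures."""
    enhanced = anatomy.enhance_vessels(image, cfg.enhance_window, cfg.tophat_radius)
    skin = anatomy.segment_skin(image, cfg.air_threshold)
    if landmark is not None:
        umbilicus = landmark
    else:
        umbilicus = anatomy.detect_umbilicus(skin)
    fascia = anatomy.derive_fascia(muscle_left, muscle_right, cfg.fascia_thickness_voxels)
    priors = AnatomyPriors(
        geometry=image.geometry,
        skin=skin,
        umbilicus=umbilicus,
        muscle_left=muscle_left,
        muscle_right=muscle_right,
        fascia=fascia,
    )
    priors.candidates = anatomy.extract_candidates(
        enhanced,
        priors,
        cfg.candidate_threshold,
        cfg.min_component_voxels,
        cfg.posterior_margin_mm,
    )
    return priors, enhanced


def match_centerlines(
    predicted: list[cl.Centerline], reference: list[cl.Centerline]
) -> list[tuple[int, int, float]]:
    """Greedy 1–1 matching of predicted to reference centerlines.

    Returns (pred index, ref index, mean mm distance of predicted points to
    the reference curve) triples, best matches first.
    """
    if not predicted or not reference:
        return []
    trees = [cKDTree(r.world_points()) for r in reference]
    cost = np.full((len(predicted), len(reference)), np.inf)
    for i, p in enumerate(predicted):
        w = p.world_points()
        for j, t in enumerate(trees):
            d, _ = t.query(w)
            cost[i, j] = d.mean()
    pairs: list[tuple[int, int, float]] = []
    used_p: set[int] = set()
    used_r: set[int] = set()
    for _ in range(min(len(predicted), len(reference))):
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        if not np.isfinite(cost[i, j]):
            break
        pairs.append((int(i), int(j), float(cost[i, j])))
        used_p.add(int(i))
        used_r.add(int(j))
        cost[i, :] = np.inf
        cost[:, j] = np.inf
    return pairs


def _make_backend(cfg: RunConfig, gt: Optional[Mask]) -> prompting.SegmentationBackend:
    if cfg.backend == "oracle":
        if gt is None:
            raise ValidationError("oracle backend requires a ground-truth vessel mask")
        return prompting.OracleBackend(gt)
    return prompting.ThresholdRegionGrowBackend(cfg.region_grow_low_fraction)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    stage_times: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *a):
                stage_times[name] = time.perf_counter() - self.t0
                log.info("stage %s: %.2f s", name, stage_times[name])

        return _T()

    gt_mask: Optional[Mask] = None
    case: Optional[PhantomCase] = None
    landmark = None
    with timed("inputs"):
        if cfg.phantom:
            pcfg = PhantomConfig(seed=cfg.seed)
            case = generate_phantom(pcfg)
            (out / "inputs").mkdir(exist_ok=True)
            export_case(case, out / "inputs")
            image = case.image
            muscle_left, muscle_right = case.muscle_mask_left, case.muscle_mask_right
            gt_mask = case.vessel_mask
        else:
            image = read_volume(cfg.image)
            muscle_left = read_mask(cfg.muscle_left)
            muscle_right = read_mask(cfg.muscle_right)
            if cfg.gt_vessels:
                gt_mask = read_mask(cfg.gt_vessels)
            if cfg.landmark:
                landmark = read_landmark(cfg.landmark)

    with timed("priors"):
        priors, enhanced = compute_priors(image, muscle_left, muscle_right, cfg, landmark)
        write_volume(priors.candidates, out / "candidates.nrrd")
        write_volume(priors.fascia, out / "fascia.nrrd")

    with timed("centerlines"):
        centerlines = cl.extract_centerlines(priors.candidates, cfg.min_length_mm)
        _dump_centerlines(centerlines, out / "centerlines.json")

    with timed("segmentation"):
        backend = _make_backend(cfg, gt_mask)
        seg_input = enhanced if cfg.backend == "region-grow" else image
        timings: list[tuple[str, float]] = []
        pred = np.zeros(image.geometry.shape, dtype=np.uint8)
        params = cfg.prompt_params()
        for c in centerlines:
            ps = prompting.build_prompts(seg_input, c, params)
            m = prompting.run_prompted_segmentation(backend, seg_input, ps, timings)
            pred |= m.values
        pred_mask = Mask(geometry=image.geometry, values=pred)
        write_volume(pred_mask, out / "prediction.nrrd")

    metrics = {}
    if gt_mask is not None:
        with timed("evaluation"):
            rec = evaluate.evaluate_case(
                pred_mask, gt_mask, case_id="run", model_id=cfg.backend, timings=timings
            )
            metrics = {k: v for k, v in dataclasses.asdict(rec).items()}
    with open(out / "metrics.json", "w") as fh:
        json.dump({"metrics": metrics, "stage_seconds": stage_times}, fh, indent=1)

    with timed("quantification"):
        final_cls = cl.extract_centerlines(pred_mask, cfg.min_length_mm)
        reports = quantify.build_report(
            final_cls,
            priors,
            centrality_radius_mm=cfg.centrality_radius_mm,
            y_threshold_voxels=cfg.y_threshold_voxels,
            split_at_gaps=cfg.split_at_gaps,
        )
        with open(out / "report.json", "w") as fh:
            json.dump([r.to_dict() for r in reports], fh, indent=1)
        _dump_centerlines(final_cls, out / "final_centerlines.json")

    echo = dataclasses.asdict(cfg)
    echo["enhance_window"] = list(cfg.enhance_window)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh)
    with open(out / "log.txt", "w") as fh:
        fh.write(f"seed={cfg.seed}\n")
        for k, v in stage_times.items():
            fh.write(f"{k}: {v:.3f} s\n")
    return out


def _dump_centerlines(centerlines: list[cl.Centerline], path: Path) -> None:
    recs = [
        {
            "id": c.id,
            "voxels": c.as_array().tolist(),
            "length_mm": cl.path_length_mm(c),
            "straight_mm": cl.straight_line_length_mm(c),
        }
        for c in centerlines
    ]
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)
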