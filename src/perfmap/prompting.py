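"""Centerline-guided prompting and slice-wise promptable segmentation.

Each axial slice a centerline traverses receives positive point prompts at
the projected centerline locations, refined to the brightest voxel within a
small 3D ball (the vessel lumen is the local intensity maximum on CTA), plus
negative prompts sampled on a ring just outside the expected vessel boundary.
A pluggable backend then segments each slice independently in single-mask
mode and the 2D predictions are stacked back into a 3D mask.

Foundation-model backends (SAM-family, nnInteractive) plug in behind the
same :class:`SegmentationBackend` interface; the package ships an oracle
backend (ground-truth lookup, for pipeline validation) and a deterministic
threshold region-grow backend.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy import ndimage

from .centerline import Centerline
from .volume_io import Mask, Volume, VoxelPoint

__all__ = [
    "SlicePrompt",
    "PromptSet",
    "PromptParams",
    "SegmentationBackend",
    "OracleBackend",
    "ThresholdRegionGrowBackend",
    "refine_positive_point",
    "generate_negative_points",
    "build_prompts",
    "run_prompted_segmentation",
]


@dataclass
class SlicePrompt:
    z: int
    positives: list[tuple[int, int]]
    negatives: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError("a slice prompt needs at least one positive point")
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive and negative points overlap")


@dataclass
class PromptSet:
    centerline_id: str
    slice_prompts: list[SlicePrompt]

    def __post_init__(self) -> None:
        zs = [sp.z for sp in self.slice_prompts]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slice indices must be strictly increasing")


@dataclass(frozen=True)
class PromptParams:
    """Tunables of the prompting stage (all in voxel units)."""

    refine_radius_voxels: int = 5
    # Prompts are refined within their own axial slice: a 3D search ball can
    # snap an oblique vessel's prompt to a voxel that is bright at z±k but
    # background at z, starving the backend of valid positives.
    refine_in_slice: bool = True
    ring_inner: int = 4
    ring_outer: int = 8
    n_negatives: int = 4
    max_intensity_fraction: float = 0.6


class SegmentationBackend(Protocol):
    """Single-mask promptable slice segmentation contract."""

    def segment_slice(self, image_slice: np.ndarray, prompt: SlicePrompt) -> np.ndarray:
        """Return one binary mask with the same shape as ``image_slice``."""
        ...


def _ball_offsets(radius: int, in_slice: bool = False) -> np.ndarray:
    """Integer offsets within Euclidean voxel distance ``radius``, sorted by
    (distance, z, y, x) so argmax tie-breaks follow the documented rule."""
    r = int(radius)
    rng = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(rng if not in_slice else np.array([0]), rng, rng, indexing="ij")
    off = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    d2 = (off**2).sum(axis=1)
    off = off[d2 <= r * r]
    d2 = (off**2).sum(axis=1)
    order = np.lexsort((off[:, 2], off[:, 1], off[:, 0], d2))
    return off[order]


def refine_positive_point(
    image: Volume, p: VoxelPoint, radius_voxels: int = 5, in_slice: bool = False
) -> VoxelPoint:
    """Snap a centerline point to the brightest voxel within a small ball.

    The search ball has Euclidean radius ``radius_voxels`` in voxel units
    (3D by default), clipped at the grid bounds.  Ties go to the candidate
    closest to ``p``, then lexicographically smallest (z, y, x).  Radius 0
    returns ``p`` unchanged.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    if not p.in_bounds(image.geometry):
        raise IndexError(f"{p} out of bounds")
    if radius_voxels == 0:
        return p
    cand = np.asarray(p.as_tuple()) + _ball_offsets(radius_voxels, in_slice)
    ok = np.all((cand >= 0) & (cand < np.asarray(image.geometry.shape)), axis=1)
    cand = cand[ok]
    vals = image.values[cand[:, 0], cand[:, 1], cand[:, 2]]
    # candidates are pre-sorted by (distance, z, y, x); argmax takes the first max
    best = cand[int(np.argmax(vals))]
    return VoxelPoint(*(int(v) for v in best))


def generate_negative_points(
    image: Volume,
    refined: VoxelPoint,
    ring_inner: int = 4,
    ring_outer: int = 8,
    n_points: int = 4,
    max_intensity_fraction: float = 0.6,
) -> list[VoxelPoint]:
    """Background prompts on an in-plane ring around a refined positive.

    Candidates lie in the same axial slice at radial (in-plane Euclidean,
    voxel units) distance within ``[ring_inner, ring_outer]``; only voxels
    whose intensity is at most ``max_intensity_fraction`` times the refined
    point's intensity qualify — i.e. regions near, but outside, the bright
    vessel.  Selection is deterministic: angularly equispaced starting at +X,
    scanning radii outwards and skipping angles with no qualifying voxel.
    May return fewer than ``n_points``.
    """
    if ring_inner >= ring_outer:
        raise ValueError("ring_inner must be < ring_outer")
    if n_points <= 0:
        return []
    g = image.geometry
    nz, ny, nx = g.shape
    ref_val = float(image.values[refined.z, refined.y, refined.x])
    limit = max_intensity_fraction * ref_val
    out: list[VoxelPoint] = []
    taken: set[tuple[int, int]] = set()
    n_angles = max(8 * n_points, 32)
    for k in range(n_angles):
        theta = 2 * np.pi * k / n_angles
        found = None
        for r in np.arange(ring_inner, ring_outer + 0.25, 0.5):
            y = int(round(refined.y + r * np.sin(theta)))
            x = int(round(refined.x + r * np.cos(theta)))
            if not (0 <= y < ny and 0 <= x < nx) or (y, x) in taken:
                continue
            d = np.hypot(y - refined.y, x - refined.x)
            if not ring_inner <= d <= ring_outer:
                continue
            if image.values[refined.z, y, x] <= limit:
                found = (y, x)
                break
        if found is not None:
            taken.add(found)
            out.append(VoxelPoint(z=refined.z, y=found[0], x=found[1]))
            if len(out) == n_points:
                break
    return out


def build_prompts(image: Volume, c: Centerline, params: PromptParams = PromptParams()) -> PromptSet:
    """Per-slice prompts for one centerline.

    Every axial slice the centerline traverses appears exactly once.  Each
    centerline voxel of a slice is refined (3D ball by default); the prompt
    keeps the originating slice index with the refined (y, x), so refinement
    never empties a slice.  Duplicate refined positives are merged, and any
    negative colliding with a positive is dropped.
    """
    by_slice: dict[int, list[VoxelPoint]] = {}
    for p in c.points:
        by_slice.setdefault(p.z, []).append(p)
    prompts: list[SlicePrompt] = []
    for z in sorted(by_slice):
        positives: list[tuple[int, int]] = []
        negatives: list[tuple[int, int]] = []
        for p in by_slice[z]:
            rp = refine_positive_point(
                image, p, params.refine_radius_voxels, in_slice=params.refine_in_slice
            )
            pos = (rp.y, rp.x)
            if pos in positives:
                continue
            positives.append(pos)
            anchor = VoxelPoint(z=z, y=rp.y, x=rp.x)
            for np_ in generate_negative_points(
                image,
                anchor,
                params.ring_inner,
                params.ring_outer,
                params.n_negatives,
                params.max_intensity_fraction,
            ):
                negatives.append((np_.y, np_.x))
        negatives = [n for n in dict.fromkeys(negatives) if n not in set(positives)]
        prompts.append(SlicePrompt(z=z, positives=positives, negatives=negatives))
    return PromptSet(centerline_id=c.id or "cl", slice_prompts=prompts)


def run_prompted_segmentation(
    backend: SegmentationBackend,
    image: Volume,
    ps: PromptSet,
    timings: list[tuple[str, float]] | None = None,
) -> Mask:
    """Segment each prompted slice independently and stack to 3D.

    Non-prompted slices stay all-zero.  Wall-clock duration is appended to
    ``timings`` as ``(centerline_id, seconds)`` for the ITpC metric.
    """
    g = image.geometry
    out = np.zeros(g.shape, dtype=np.uint8)
    t0 = time.perf_counter()
    for sp in ps.slice_prompts:
        try:
            pred = backend.segment_slice(image.values[sp.z], sp)
        except Exception as exc:
            raise RuntimeError(f"backend failed on slice {sp.z}: {exc}") from exc
        pred = np.asarray(pred)
        if pred.shape != g.shape[1:]:
            raise ValueError(
                f"backend returned shape {pred.shape} for slice {sp.z}, expected {g.shape[1:]}"
            )
        out[sp.z] |= pred.astype(bool).astype(np.uint8)
    if timings is not None:
        timings.append((ps.centerline_id, time.perf_counter() - t0))
    return Mask(geometry=g, values=out)


class OracleBackend:
    """Ground-truth lookup backend for pipeline validation.

    Returns the 8-connected components of the reference slice that contain a
    positive prompt — the ideal single-mask response.
    """

    def __init__(self, reference: Mask):
        self.reference = reference

    def segment_slice(self, image_slice: np.ndarray, prompt: SlicePrompt) -> np.ndarray:
        ref = self.reference.values[prompt.z].astype(bool)
        labels, n = ndimage.label(ref, structure=np.ones((3, 3), dtype=bool))
        keep = {labels[y, x] for y, x in prompt.positives if labels[y, x] > 0}
        if not keep:
            return np.zeros_like(ref, dtype=np.uint8)
        return np.isin(labels, sorted(keep)).astype(np.uint8)


class ThresholdRegionGrowBackend:
    """Deterministic classical backend: intensity-band region growing.

    Grows 8-connected regions from each positive prompt over voxels whose
    intensity is at least ``low_fraction`` times the positive's intensity;
    components containing a negative prompt are discarded.  Intended to run
    on the vessel-enhanced volume where the lumen is near 1.
    """

    def __init__(self, low_fraction: float = 0.6):
        if not 0 < low_fraction <= 1:
            raise ValueError("low_fraction must be in (0, 1]")
        self.low_fraction = low_fraction

    def segment_slice(self, image_slice: np.ndarray, prompt: SlicePrompt) -> np.ndarray:
        out = np.zeros(image_slice.shape, dtype=np.uint8)
        neg = set(prompt.negatives)
        for y, x in prompt.positives:
            thr = self.low_fraction * float(image_slice[y, x])
            band = image_slice >= thr
            labels, _ = ndimage.label(band, structure=np.ones((3, 3), dtype=bool))
            lab = labels[y, x]
            if lab == 0:
                continue
            if any(labels[ny_, nx_] == lab for ny_, nx_ in neg):
                continue
            out |= (labels == lab).astype(np.uint8)
        return out
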