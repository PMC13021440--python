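"""Classical image-processing anatomical priors.

From a CTA volume and externally supplied rectus muscle masks this module
derives the patient-specific reference structures the rest of the pipeline
needs: a vessel-enhanced volume, the anterior skin sheet, the umbilicus
landmark, the anterior rectus fascia, and the candidate-perforator mask that
seeds centerline extraction.

Muscle masks are inputs, never computed here — in the clinical workflow they
come from a dedicated segmentation model; on phantoms they are ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, white_tophat

from .volume_io import Geometry, Mask, Volume, VoxelPoint

__all__ = [
    "AnatomyPriors",
    "LandmarkError",
    "enhance_vessels",
    "segment_skin",
    "detect_umbilicus",
    "derive_fascia",
    "extract_candidates",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class LandmarkError(RuntimeError):
    """Umbilicus detection failed; caller may supply a landmark file instead."""


@dataclass
class AnatomyPriors:
    """All prior structures on one grid.

    ``fascia`` is disjoint from the muscles by construction (it is their
    anterior boundary layer) and ``candidates`` excludes skin voxels.
    """

    geometry: Geometry
    skin: Optional[Mask] = None
    umbilicus: Optional[VoxelPoint] = None
    muscle_left: Optional[Mask] = None
    muscle_right: Optional[Mask] = None
    fascia: Optional[Mask] = None
    candidates: Optional[Mask] = None

    def muscle_union(self) -> Mask:
        parts = [m for m in (self.muscle_left, self.muscle_right) if m is not None]
        if not parts:
            raise ValueError("no muscle masks present")
        u = np.zeros(self.geometry.shape, dtype=np.uint8)
        for m in parts:
            u |= m.values
        return Mask(geometry=self.geometry, values=u)


def enhance_vessels(
    image: Volume,
    window: tuple[float, float],
    tophat_radius: int | None = None,
) -> Volume:
    """Clip intensities to ``window`` and rescale linearly to [0, 1].

    Optionally applies a 2D white top-hat per axial slice afterwards to
    accentuate thin bright structures; without it the map is monotone in the
    input intensity within the window.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate intensity window {window}")
    out = (np.clip(image.values, lo, hi) - lo) / (hi - lo)
    if tophat_radius is not None and tophat_radius > 0:
        se = disk(tophat_radius)
        out = np.stack([white_tophat(sl, footprint=se) for sl in out])
        out = np.clip(out, 0.0, 1.0)
    return Volume(geometry=image.geometry, values=out)


def segment_skin(image: Volume, air_threshold: float) -> Mask:
    """One-voxel-thick anterior tissue boundary.

    For each (z, x) column along Y, the first supra-threshold (tissue) voxel
    encountered from the anterior side; all-air columns contribute nothing.
    """
    tissue = image.values > air_threshold
    if not tissue.any() or tissue.all():
        raise ValueError("image must contain both air and tissue voxels")
    has_tissue = tissue.any(axis=1)
    first_y = tissue.argmax(axis=1)  # first True along Y per (z, x)
    out = np.zeros(image.geometry.shape, dtype=np.uint8)
    zz, xx = np.nonzero(has_tissue)
    out[zz, first_y[zz, xx], xx] = 1
    return Mask(geometry=image.geometry, values=out)


def detect_umbilicus(
    skin: Mask,
    midline_fraction: float = 0.15,
    smooth_sigma: float = 8.0,
    min_depth_voxels: float = 2.0,
) -> VoxelPoint:
    """Locate the umbilicus as the deepest anterior skin indentation near the midline.

    The skin depth map D(z, x) (anterior skin Y index per column) is smoothed;
    the voxel maximising the posterior displacement D − smooth(D) within the
    band ``|x − nx/2| <= midline_fraction · nx`` is returned.  If no
    indentation exceeds ``min_depth_voxels`` a :class:`LandmarkError` is
    raised so the caller can fall back to a landmark file.
    """
    vals = skin.as_bool()
    if not vals.any():
        raise ValueError("empty skin mask")
    nz, ny, nx = skin.geometry.shape
    has = vals.any(axis=1)
    depth = vals.argmax(axis=1).astype(float)
    fill = np.median(depth[has]) if has.any() else 0.0
    depth_f = np.where(has, depth, fill)
    # light pre-smoothing removes the integer plateau of the depth map so the
    # indentation peaks at the dent centre instead of a plateau edge
    fine = ndimage.gaussian_filter(depth_f, sigma=1.5, mode="nearest")
    baseline = ndimage.gaussian_filter(depth_f, sigma=smooth_sigma, mode="nearest")
    indent = np.where(has, fine - baseline, -np.inf)

    mid = nx / 2.0
    band = np.abs(np.arange(nx) - mid) <= midline_fraction * nx
    indent[:, ~band] = -np.inf
    z0, x0 = np.unravel_index(np.argmax(indent), indent.shape)
    if not np.isfinite(indent[z0, x0]) or indent[z0, x0] < min_depth_voxels:
        raise LandmarkError(
            f"no skin indentation deeper than {min_depth_voxels} voxels near the midline"
        )
    # refine to the indent-weighted centroid of the peak's half-height blob
    blob = np.isfinite(indent) & (indent >= 0.5 * indent[z0, x0])
    labels, _ = ndimage.label(blob)
    blob = labels == labels[z0, x0]
    w = np.where(blob, indent, 0.0)
    zc = int(round(float((w.sum(axis=1) * np.arange(nz)).sum() / w.sum())))
    xc = int(round(float((w.sum(axis=0) * np.arange(nx)).sum() / w.sum())))
    return VoxelPoint(z=zc, y=int(depth[zc, xc]), x=xc)


def derive_fascia(
    muscle_left: Mask | None,
    muscle_right: Mask | None,
    thickness_voxels: int = 2,
) -> Mask:
    """Anterior boundary layer of the muscle union (the anterior rectus sheath).

    A voxel belongs to the fascia iff it lies within ``thickness_voxels``
    anterior (decreasing-Y) steps of the union's anterior surface in its own
    (z, x) column and is not itself muscle.
    """
    if thickness_voxels < 1:
        raise ValueError("thickness_voxels must be >= 1")
    masks = [m for m in (muscle_left, muscle_right) if m is not None and m.values.any()]
    if not masks:
        raise ValueError("both muscle masks empty or missing")
    g = masks[0].geometry
    union = np.zeros(g.shape, dtype=bool)
    for m in masks:
        union |= m.as_bool()
    has = union.any(axis=1)
    first_y = union.argmax(axis=1)
    out = np.zeros(g.shape, dtype=bool)
    ny = g.shape[1]
    yy = np.arange(ny)[None, :, None]
    fy = np.where(has, first_y, ny + thickness_voxels + 1)[:, None, :]
    out = (yy < fy) & (yy >= fy - thickness_voxels)
    out &= ~union
    return Mask(geometry=g, values=out.astype(np.uint8))


def extract_candidates(
    enhanced: Volume,
    priors: AnatomyPriors,
    threshold: float,
    min_size_voxels: int = 30,
    posterior_margin_mm: float = 12.0,
) -> Mask:
    """Threshold the enhanced volume into a candidate-perforator mask.

    The result is restricted to the retro-skin region of interest — per
    (z, x) column, strictly posterior to the skin voxel and no deeper than
    the posterior muscle surface plus ``posterior_margin_mm`` (perforators
    originate from the deep inferior epigastric artery just behind the
    rectus) — and cleaned of 26-connected components smaller than
    ``min_size_voxels``.  An empty result is a valid (empty) mask.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = enhanced.geometry
    ny = g.shape[1]
    fg = enhanced.values >= threshold

    muscle = priors.muscle_union().as_bool()
    yy = np.arange(ny)[None, :, None]

    if priors.skin is not None:
        sv = priors.skin.as_bool()
        has_skin = sv.any(axis=1)
        skin_y = np.where(has_skin, sv.argmax(axis=1), -1)[:, None, :]
        fg &= yy > skin_y
        fg &= np.broadcast_to(has_skin[:, None, :], g.shape)

    has_m = muscle.any(axis=1)
    last_m = ny - 1 - muscle[:, ::-1, :].argmax(axis=1)
    global_last = int(last_m[has_m].max()) if has_m.any() else ny - 1
    margin_vox = int(round(posterior_margin_mm / g.spacing[1]))
    post_bound = np.where(has_m, last_m, global_last)[:, None, :] + margin_vox
    fg &= yy <= post_bound

    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size_voxels
        keep[0] = False
        fg = keep[labels]
    return Mask(geometry=g, values=fg.astype(np.uint8))
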