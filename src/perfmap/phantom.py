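"""Synthetic CTA-like abdominal phantom with full ground truth.

The phantom emulates the anterior abdominal wall as seen in a
contrast-enhanced CT angiography study: layered anatomy along the
anterior–posterior (Y) axis — air, skin, subcutaneous fat, rectus fascia,
the paired rectus abdominis muscles, and posterior soft tissue — plus a
midline umbilical skin indentation and a configurable number of perforator
vessels.  Each vessel is a smooth parametric curve rasterised as a tube: it
starts posterior to the muscle (where the deep inferior epigastric artery
runs), traverses the muscle (the intramuscular segment), pierces the fascia
at a recorded emergence point and ends in the subcutaneous fat.

Ground truth is analytic: intramuscular lengths come from dense arc-length
integration of the parametric curve clipped to the muscle region, not from
any rasterised voxels, so they are an implementation-independent oracle for
the centerline-based measurements downstream.

All layer positions are fixed in millimetres (realistic abdominal-wall
proportions); geometries too small for the layer stack are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .centerline import Centerline
from .volume_io import (
    Geometry,
    Mask,
    Volume,
    VoxelPoint,
    write_landmark,
    write_volume,
)

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "VesselSpec",
    "ConfigurationError",
    "generate_phantom",
    "export_case",
    "MUSCLE_Y_MM",
    "FASCIA_Y_MM",
]


class ConfigurationError(ValueError):
    """Phantom geometry cannot fit the anatomical layer stack."""


# Layer positions along Y in mm (anterior at y = 0).
AIR_END_MM = 6.0
SKIN_THICKNESS_MM = 2.0
FASCIA_Y_MM = (26.0, 28.0)
MUSCLE_Y_MM = (28.0, 48.0)
VESSEL_Y_START_MM = 58.0   # posterior curve start, behind the muscle
VESSEL_Y_END_MM = 12.0     # anterior curve end, in subcutaneous fat
MUSCLE_EDGE_MARGIN_MM = 6.0
MIDLINE_GAP_MM = 6.0       # half-width of the linea alba gap
UMBILICUS_DEPTH_MM = 4.0
UMBILICUS_SIGMA_MM = 6.0


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic case.

    Defaults mirror a typical abdominal CTA: ~1 mm slices, sub-millimetre
    in-plane resolution, contrast-enhanced vessels around 400 HU against
    soft tissue near 50 HU, and moderate quantum noise.
    """

    shape: tuple[int, int, int] = (80, 96, 120)
    spacing: tuple[float, float, float] = (1.0, 0.8, 0.8)
    n_vessels: int = 5
    vessel_radius_mm: float = 1.5
    vessel_intensity: float = 400.0
    tissue_intensities: dict = field(
        default_factory=lambda: {"air": -1000.0, "fat": -100.0, "muscle": 50.0, "skin": 20.0}
    )
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ConfigurationError("n_vessels must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing components must be positive")
        tmax = max(self.tissue_intensities.values())
        if not self.vessel_intensity > tmax:
            raise ConfigurationError(
                "vessel_intensity must exceed every tissue intensity (contrast assumption)"
            )
        if self.vessel_radius_mm < max(self.spacing) / 2:
            raise ConfigurationError("vessel_radius_mm must be >= max(spacing)/2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        ez, ey, ex = (n * s for n, s in zip(self.shape, self.spacing))
        if ey < 70.0 or ez < 68.0 or ex < 60.0:
            raise ConfigurationError(
                f"geometry extent ({ez:.0f}, {ey:.0f}, {ex:.0f}) mm too small for the layer stack"
            )

    @property
    def geometry(self) -> Geometry:
        return Geometry(shape=self.shape, spacing=self.spacing)


@dataclass(frozen=True)
class VesselSpec:
    """Parametric description of one perforator curve.

    The curve is parameterised by the anterior walk ``s`` in mm with
    ``y(s) = VESSEL_Y_START_MM - s``; ``kind`` selects the lateral course:

    * ``straight``  — constant x, z drifting at ``slope_z`` per mm,
    * ``oblique``   — x drifting at ``slope_x``, z at ``slope_z``,
    * ``sinusoid``  — x = lane + amp·sin(2πs/period), z at ``slope_z``,
    * ``helix``     — one full turn of radius ``helix_radius_mm`` across the
      muscle slab (pitch = slab thickness) in the x–z plane,
    * ``steep``     — z climbing at ``slope_z`` only inside the muscle slab
      (a long, steeply superior intramuscular course).
    """

    kind: str
    x_mm: float
    z0_mm: float
    slope_x: float = 0.0
    slope_z: float = 0.0
    amp_mm: float = 2.5
    period_mm: float = 23.0
    helix_radius_mm: float = 2.5

    def xyz(self, s: np.ndarray) -> np.ndarray:
        """Curve points (n, 3) in world mm (z, y, x) order."""
        s = np.asarray(s, dtype=float)
        y = VESSEL_Y_START_MM - s
        s_m0 = VESSEL_Y_START_MM - MUSCLE_Y_MM[1]
        s_m1 = VESSEL_Y_START_MM - MUSCLE_Y_MM[0]
        if self.kind == "straight":
            x = np.full_like(s, self.x_mm)
            z = self.z0_mm + self.slope_z * s
        elif self.kind == "oblique":
            x = self.x_mm + self.slope_x * s
            z = self.z0_mm + self.slope_z * s
        elif self.kind == "sinusoid":
            x = self.x_mm + self.amp_mm * np.sin(2 * np.pi * s / self.period_mm)
            z = self.z0_mm + self.slope_z * s
        elif self.kind == "helix":
            theta = 2 * np.pi * (s - s_m0) / (s_m1 - s_m0)
            x = self.x_mm + self.helix_radius_mm * np.cos(theta)
            z = self.z0_mm + self.helix_radius_mm * np.sin(theta)
        elif self.kind == "steep":
            x = np.full_like(s, self.x_mm)
            z = self.z0_mm + self.slope_z * (np.clip(s, s_m0, s_m1) - s_m0)
        else:
            raise ConfigurationError(f"unknown vessel kind {self.kind!r}")
        return np.stack([z, y, x], axis=-1)


@dataclass
class PhantomCase:
    image: Volume
    vessel_mask: Mask
    muscle_mask_left: Mask
    muscle_mask_right: Mask
    fascia_mask: Mask
    skin_mask: Mask
    umbilicus: VoxelPoint
    gt_centerlines: list[Centerline]
    gt_intramuscular_length_mm: list[float]
    gt_emergence_points: list[VoxelPoint]
    config: PhantomConfig


def _default_vessels(cfg: PhantomConfig) -> list[VesselSpec]:
    """Lane layout across the two rectus muscles, cycling five archetypes.

    Per-seed jitter on lane positions, axis offsets and course slopes gives
    each case its own anatomy, the way patients differ; the helix archetype
    keeps its radius and pitch (one full turn across the muscle slab) so its
    arc length stays analytically known.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ex = cfg.shape[2] * cfg.spacing[2]
    mid = ex / 2.0
    left = (MUSCLE_EDGE_MARGIN_MM + 4.0, mid - MIDLINE_GAP_MM - 4.0)
    right = (mid + MIDLINE_GAP_MM + 4.0, ex - MUSCLE_EDGE_MARGIN_MM - 4.0)
    n = cfg.n_vessels
    n_left = (n + 1) // 2
    n_right = n - n_left
    lanes = [left[0] + (i + 1) * (left[1] - left[0]) / (n_left + 1) for i in range(n_left)]
    lanes += [right[0] + (i + 1) * (right[1] - right[0]) / (n_right + 1) for i in range(n_right)]
    # archetype order keeps the laterally drifting oblique on an outer lane
    kinds = ["straight", "sinusoid", "oblique", "helix", "steep"]
    z0s = {"straight": 16.0, "oblique": 30.0, "sinusoid": 60.0, "helix": 24.0, "steep": 16.0}
    slopes = {"straight": 0.5, "oblique": 0.4, "sinusoid": -0.3, "helix": 0.0, "steep": 2.0}
    specs = []
    for i, x in enumerate(lanes):
        kind = kinds[i % len(kinds)]
        slope_scale = rng.uniform(1.0, 1.15) if kind == "steep" else rng.uniform(0.9, 1.1)
        specs.append(
            VesselSpec(
                kind=kind,
                x_mm=float(x + rng.uniform(-1.0, 1.0)),
                z0_mm=float(z0s[kind] + rng.uniform(-3.0, 3.0)),
                slope_x=0.15 * float(rng.uniform(0.9, 1.1)) if kind == "oblique" else 0.0,
                slope_z=slopes[kind] * float(slope_scale),
                amp_mm=float(rng.uniform(2.2, 2.8)) if kind == "sinusoid" else 2.5,
                period_mm=float(rng.uniform(21.0, 25.0)) if kind == "sinusoid" else 23.0,
            )
        )
    return specs


def _in_muscle_region(pts: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Analytic membership test of world points in the rectus muscle region."""
    ex = cfg.shape[2] * cfg.spacing[2]
    mid = ex / 2.0
    z, y, x = pts[..., 0], pts[..., 1], pts[..., 2]
    in_y = (y >= MUSCLE_Y_MM[0]) & (y < MUSCLE_Y_MM[1])
    in_left = (x >= MUSCLE_EDGE_MARGIN_MM) & (x <= mid - MIDLINE_GAP_MM)
    in_right = (x >= mid + MIDLINE_GAP_MM) & (x <= ex - MUSCLE_EDGE_MARGIN_MM)
    return in_y & (in_left | in_right)


def _arc_length_in_muscle(spec: VesselSpec, cfg: PhantomConfig, step_mm: float = 0.01) -> float:
    s_end = VESSEL_Y_START_MM - VESSEL_Y_END_MM
    s = np.arange(0.0, s_end + step_mm, step_mm)
    pts = spec.xyz(s)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    mids = 0.5 * (pts[1:] + pts[:-1])
    return float(seg_len[_in_muscle_region(mids, cfg)].sum())


def _curve_to_centerline(spec: VesselSpec, cfg: PhantomConfig, cid: str) -> Centerline:
    g = cfg.geometry
    step = 0.2 * min(cfg.spacing)
    s_end = VESSEL_Y_START_MM - VESSEL_Y_END_MM
    pts = spec.xyz(np.arange(0.0, s_end + step, step))
    vox = np.round(pts / np.asarray(cfg.spacing)).astype(int)
    keep = [0]
    for i in range(1, len(vox)):
        if not np.array_equal(vox[i], vox[keep[-1]]):
            keep.append(i)
    vox = vox[keep]
    # drop any late revisit of an earlier voxel (can occur at rounding cusps)
    seen: dict = {}
    ordered = []
    for v in map(tuple, vox):
        if v in seen:
            continue
        seen[v] = True
        ordered.append(VoxelPoint(*v))
    return Centerline(points=ordered, geometry=g, id=cid)


def _rasterize_tube(spec: VesselSpec, cfg: PhantomConfig) -> np.ndarray:
    """Voxel is foreground iff its centre lies within radius of the curve."""
    g = cfg.geometry
    sp = np.asarray(cfg.spacing)
    step = 0.25 * min(cfg.spacing)
    s_end = VESSEL_Y_START_MM - VESSEL_Y_END_MM
    pts = spec.xyz(np.arange(0.0, s_end + step, step))
    r = cfg.vessel_radius_mm
    lo = np.maximum(np.floor((pts.min(axis=0) - r) / sp - 1).astype(int), 0)
    hi = np.minimum(np.ceil((pts.max(axis=0) + r) / sp + 1).astype(int), np.asarray(g.shape) - 1)
    zz, yy, xx = np.meshgrid(
        *(np.arange(a, b + 1) for a, b in zip(lo, hi)), indexing="ij"
    )
    centers = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) * sp
    d, _ = cKDTree(pts).query(centers, workers=-1)
    inside = d <= r
    out = np.zeros(g.shape, dtype=bool)
    sel = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)[inside]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return out


def generate_phantom(
    config: PhantomConfig, vessels: list[VesselSpec] | None = None
) -> PhantomCase:
    """Build one fully annotated synthetic case, deterministic given the seed."""
    cfg = config
    g = cfg.geometry
    nz, ny, nx = cfg.shape
    sz, sy, sx = cfg.spacing
    rng = np.random.default_rng(cfg.seed)
    specs = vessels if vessels is not None else _default_vessels(cfg)

    z_mm = np.arange(nz)[:, None, None] * sz
    y_mm = np.arange(ny)[None, :, None] * sy
    x_mm = np.arange(nx)[None, None, :] * sx
    ex = nx * sx
    mid = ex / 2.0

    # skin surface with the umbilical indentation (posterior dent at midline)
    zu_mm, xu_mm = (nz * sz) / 2.0, mid
    dent = UMBILICUS_DEPTH_MM * np.exp(
        -((z_mm - zu_mm) ** 2 + (x_mm - xu_mm) ** 2) / (2 * UMBILICUS_SIGMA_MM**2)
    )
    surf = AIR_END_MM + dent  # (nz, 1, nx) broadcastable surface depth

    ti = cfg.tissue_intensities
    img = np.full(cfg.shape, ti["air"], dtype=np.float64)
    skin = (y_mm >= surf) & (y_mm < surf + SKIN_THICKNESS_MM)
    tissue = y_mm >= surf
    fat = tissue & ~skin & (y_mm < FASCIA_Y_MM[0])
    in_left_x = (x_mm >= MUSCLE_EDGE_MARGIN_MM) & (x_mm <= mid - MIDLINE_GAP_MM)
    in_right_x = (x_mm >= mid + MIDLINE_GAP_MM) & (x_mm <= ex - MUSCLE_EDGE_MARGIN_MM)
    muscle_y = (y_mm >= MUSCLE_Y_MM[0]) & (y_mm < MUSCLE_Y_MM[1])
    fascia_y = (y_mm >= FASCIA_Y_MM[0]) & (y_mm < FASCIA_Y_MM[1])
    muscle_left = np.broadcast_to(muscle_y & in_left_x, cfg.shape)
    muscle_right = np.broadcast_to(muscle_y & in_right_x, cfg.shape)
    fascia = np.broadcast_to(fascia_y & (in_left_x | in_right_x), cfg.shape)
    posterior = tissue & (y_mm >= MUSCLE_Y_MM[1])

    img[np.broadcast_to(skin, cfg.shape)] = ti["skin"]
    img[np.broadcast_to(fat, cfg.shape)] = ti["fat"]
    img[np.broadcast_to(fascia_y & tissue, cfg.shape)] = ti["muscle"]
    img[muscle_left | muscle_right] = ti["muscle"]
    img[np.broadcast_to(posterior, cfg.shape)] = ti["muscle"]

    vessel = np.zeros(cfg.shape, dtype=bool)
    gt_centerlines: list[Centerline] = []
    gt_lengths: list[float] = []
    gt_emerge: list[VoxelPoint] = []
    fascia_anterior_y_mm = sy * int(np.ceil(FASCIA_Y_MM[0] / sy))
    for i, spec in enumerate(specs):
        tube = _rasterize_tube(spec, cfg)
        vessel |= tube
        gt_centerlines.append(_curve_to_centerline(spec, cfg, cid=f"gt{i:02d}"))
        gt_lengths.append(_arc_length_in_muscle(spec, cfg))
        # emergence: curve point at the most anterior fascia voxel-centre plane
        s_e = VESSEL_Y_START_MM - fascia_anterior_y_mm
        pe = spec.xyz(np.array([s_e]))[0]
        gt_emerge.append(
            VoxelPoint(*(int(v) for v in np.round(pe / np.asarray(cfg.spacing))))
        )
    img[vessel] = cfg.vessel_intensity

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)

    # umbilicus: anterior-most skin voxel on the dent axis
    zu_i, xu_i = int(round(zu_mm / sz)), int(round(xu_mm / sx))
    skin_col = np.flatnonzero(np.broadcast_to(skin, cfg.shape)[zu_i, :, xu_i])
    umbilicus = VoxelPoint(z=zu_i, y=int(skin_col[0]), x=xu_i)

    mk = lambda a: Mask(geometry=g, values=np.ascontiguousarray(a).astype(np.uint8))
    return PhantomCase(
        image=Volume(geometry=g, values=img.astype(np.float32)),
        vessel_mask=mk(vessel),
        muscle_mask_left=mk(muscle_left),
        muscle_mask_right=mk(muscle_right),
        fascia_mask=mk(fascia),
        skin_mask=mk(np.broadcast_to(skin, cfg.shape)),
        umbilicus=umbilicus,
        gt_centerlines=gt_centerlines,
        gt_intramuscular_length_mm=gt_lengths,
        gt_emergence_points=gt_emerge,
        config=cfg,
    )


def export_case(case: PhantomCase, out_dir: str | Path) -> None:
    """Write the case (NRRD volumes, landmark JSON, ground-truth manifest)."""
    out = Path(out_dir)
    if not out.is_dir():
        raise IOError(f"not a writable directory: {out}")
    write_volume(case.image, out / "image.nrrd")
    for name in ("vessel_mask", "muscle_mask_left", "muscle_mask_right", "fascia_mask", "skin_mask"):
        write_volume(getattr(case, name), out / f"{name}.nrrd")
    write_landmark(case.umbilicus, out / "umbilicus.json")
    manifest = {
        "seed": case.config.seed,
        "config": {
            **asdict(case.config),
            "shape": list(case.config.shape),
            "spacing": list(case.config.spacing),
        },
        "gt_intramuscular_length_mm": case.gt_intramuscular_length_mm,
        "gt_emergence_points": [list(p.as_tuple()) for p in case.gt_emergence_points],
        "gt_centerlines": [
            {"id": c.id, "voxels": c.as_array().tolist()} for c in case.gt_centerlines
        ],
        "umbilicus": list(case.umbilicus.as_tuple()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
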