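"""Segmentation evaluation: overlap and boundary metrics, error statistics,
timing, and multi-model comparison statistics.

Conventions pinned here (several coexist in the literature):

* surface voxels are foreground voxels with at least one face-adjacent
  background neighbour (the grid border counts as background);
* directed surface distances are pooled over both directions; ASD is their
  mean, HD their maximum, HD95 their 95th percentile with linear
  interpolation — so HD is symmetric and HD95 ≤ HD by construction;
* a prediction with no foreground leaves the boundary metrics undefined and
  the case flagged, excluded from aggregation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume_io import Mask

__all__ = [
    "MetricRecord",
    "ErrorStats",
    "ComparisonResult",
    "dsc",
    "iou",
    "surface_distance_metrics",
    "itpc",
    "error_stats",
    "compare_models",
    "evaluate_case",
]

DISTANCE_METRIC_NAMES = ("dsc", "iou", "asd_mm", "hd_mm", "hd95_mm")


@dataclass
class MetricRecord:
    case_id: str
    model_id: str
    dsc: float
    iou: float
    asd_mm: Optional[float] = None
    hd_mm: Optional[float] = None
    hd95_mm: Optional[float] = None
    itpc_s: Optional[float] = None

    def complete(self) -> bool:
        return all(
            getattr(self, m) is not None for m in ("asd_mm", "hd_mm", "hd95_mm")
        )


@dataclass(frozen=True)
class ErrorStats:
    mae_mm: float
    mdae_mm: float
    rmse_mm: float
    iqr_mm: tuple[float, float]


@dataclass
class ComparisonResult:
    manova: dict
    per_metric_anova: dict
    tukey: list[dict] = field(default_factory=list)


def _check_geometry(pred: Mask, gt: Mask) -> None:
    if pred.geometry.shape != gt.geometry.shape:
        raise ValueError("mask shapes differ")
    if pred.geometry.spacing != gt.geometry.spacing:
        raise ValueError("mask spacings differ")


def dsc(pred: Mask, gt: Mask) -> float:
    """Dice similarity coefficient; 1 when both masks are empty."""
    _check_geometry(pred, gt)
    p, g = pred.as_bool(), gt.as_bool()
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def iou(pred: Mask, gt: Mask) -> float:
    """Jaccard index; 1 when both masks are empty."""
    _check_geometry(pred, gt)
    p, g = pred.as_bool(), gt.as_bool()
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def _surface_points_mm(mask: Mask) -> np.ndarray:
    """(n, 3) physical coordinates of surface voxels (6-connectivity, border = background)."""
    vals = mask.as_bool()
    eroded = ndimage.binary_erosion(vals, structure=ndimage.generate_binary_structure(3, 1))
    surf = vals & ~eroded
    coords = np.argwhere(surf)
    return coords * np.asarray(mask.geometry.spacing) + np.asarray(mask.geometry.origin)


def surface_distance_metrics(pred: Mask, gt: Mask) -> tuple[float, float, float]:
    """(ASD, HD, HD95) in mm over pooled bidirectional surface distances.

    Raises ValueError when either mask is empty; callers flag such cases as
    undefined rather than aggregating them.
    """
    _check_geometry(pred, gt)
    if not pred.values.any() or not gt.values.any():
        raise ValueError("surface distances undefined for an empty mask")
    a = _surface_points_mm(pred)
    b = _surface_points_mm(gt)
    d_ab, _ = cKDTree(b).query(a, workers=-1)
    d_ba, _ = cKDTree(a).query(b, workers=-1)
    pooled = np.concatenate([d_ab, d_ba])
    return (
        float(pooled.mean()),
        float(pooled.max()),
        float(np.percentile(pooled, 95, method="linear")),
    )


def itpc(timings: Sequence[tuple[str, float]]) -> float:
    """Mean inference seconds per centerline."""
    if not timings:
        raise ValueError("no timings recorded")
    return float(np.mean([t for _, t in timings]))


def error_stats(pred_values: Sequence[float], ref_values: Sequence[float]) -> ErrorStats:
    """MAE, MdAE, RMSE and IQR of the absolute errors |pred − ref|."""
    p = np.asarray(pred_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("pred and ref must be equal-length, non-empty")
    e = np.abs(p - r)
    q1, q3 = np.percentile(e, [25, 75], method="linear")
    return ErrorStats(
        mae_mm=float(e.mean()),
        mdae_mm=float(np.median(e)),
        rmse_mm=float(np.sqrt(np.mean(e**2))),
        iqr_mm=(float(q1), float(q3)),
    )


def evaluate_case(
    pred: Mask, gt: Mask, case_id: str = "", model_id: str = "",
    timings: Sequence[tuple[str, float]] | None = None,
) -> MetricRecord:
    """All segmentation metrics for one case; boundary metrics stay None when undefined."""
    rec = MetricRecord(case_id=case_id, model_id=model_id, dsc=dsc(pred, gt), iou=iou(pred, gt))
    try:
        rec.asd_mm, rec.hd_mm, rec.hd95_mm = surface_distance_metrics(pred, gt)
    except ValueError:
        pass
    if timings:
        rec.itpc_s = itpc(timings)
    return rec


def compare_models(
    records: Sequence[MetricRecord],
    alpha: float = 0.05,
    metrics: Sequence[str] = DISTANCE_METRIC_NAMES,
) -> ComparisonResult:
    """MANOVA → per-metric one-way ANOVA → Tukey HSD across segmentation models.

    The multivariate test (Wilks' lambda with its F approximation) asks
    whether model choice shifts the joint metric vector at all; per-metric
    ANOVAs then localise the effect, and Tukey's HSD identifies which model
    pairs differ, at family-wise level ``alpha`` per metric.  Records with
    undefined metrics are dropped first.
    """
    from statsmodels.multivariate.manova import MANOVA
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = [
        {"model": r.model_id, **{m: getattr(r, m) for m in metrics}}
        for r in records
        if all(getattr(r, m) is not None for m in metrics)
    ]
    df = pd.DataFrame(rows)
    if df.empty or df["model"].nunique() < 2:
        raise ValueError("need at least 2 models with complete records")
    if (df.groupby("model").size() < 2).any():
        raise ValueError("need at least 2 cases per model")

    # Degenerate case first: with no between-group variation the hypothesis
    # SSCP matrix is zero (Wilks' lambda is exactly 1) and the eigenproblem
    # statsmodels solves is empty.
    vals = df[list(metrics)].to_numpy(dtype=float)
    grand = vals.mean(axis=0)
    h = np.zeros((len(metrics), len(metrics)))
    for _, g in df.groupby("model"):
        gm = g[list(metrics)].to_numpy(dtype=float).mean(axis=0)
        d = (gm - grand)[:, None]
        h += len(g) * (d @ d.T)
    p_, k_, n_ = len(metrics), df["model"].nunique(), len(df)
    if np.allclose(h, 0.0, atol=1e-12 * max(1.0, float(np.abs(vals).max()) ** 2)):
        q_ = k_ - 1
        manova = {
            "wilks_lambda": 1.0,
            "f_stat": 0.0,
            "df_pair": (float(p_ * q_), float(n_ - 1 - (p_ + q_ + 1) / 2)),
            "p_value": 1.0,
        }
    else:
        cols = {m: f"m{i}" for i, m in enumerate(metrics)}  # formula-safe names
        dfm = df.rename(columns=cols)
        formula = " + ".join(cols.values()) + " ~ model"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = MANOVA.from_formula(formula, data=dfm)
            tbl = mv.mv_test().results["model"]["stat"]
        wilks = tbl.loc["Wilks' lambda"]
        manova = {
            "wilks_lambda": float(wilks["Value"]),
            "f_stat": float(wilks["F Value"]),
            "df_pair": (float(wilks["Num DF"]), float(wilks["Den DF"])),
            "p_value": float(wilks["Pr > F"]),
        }

    per_metric = {}
    tukey_rows: list[dict] = []
    for m in metrics:
        groups = [g[m].to_numpy() for _, g in df.groupby("model")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
        if not np.isfinite(f):  # zero variance everywhere
            f, p = 0.0, 1.0
        per_metric[m] = {"f_stat": float(f), "p_value": float(p)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_tukeyhsd(df[m].to_numpy(), df["model"].to_numpy(), alpha=alpha)
        for (g1, g2), padj, rej in zip(
            itertools.combinations(res.groupsunique, 2), res.pvalues, res.reject
        ):
            if not np.isfinite(padj):  # zero within-group variance, no difference
                padj, rej = 1.0, False
            tukey_rows.append(
                {
                    "metric": m,
                    "pair": (str(g1), str(g2)),
                    "p_adj": float(padj),
                    "significant": bool(rej),
                }
            )
    return ComparisonResult(manova=manova, per_metric_anova=per_metric, tukey=tukey_rows)
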