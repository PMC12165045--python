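"""Shared contour geometry: sampling, normalization, ordering, masks, metrics.

Conventions used throughout the package: coordinates are 0-based continuous
pixel coordinates with ``(x, y)`` ordering; pixel ``(row i, col j)`` covers
the unit square ``[j, j+1) x [i, i+1)`` with its centre at ``(j+0.5, i+0.5)``;
polygons are implicitly closed (last vertex connects back to the first).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage import draw as _draw
from skimage import measure as _measure

__all__ = [
    "MetricsReport",
    "sample_contour_points",
    "box_normalize",
    "order_points_tsp",
    "rasterize_contour",
    "extract_boundary",
    "mask_iou",
    "mask_ap",
    "regression_metrics",
    "mask_to_rle",
    "rle_to_mask",
    "read_coco",
    "write_coco",
    "COCO_IOU_THRESHOLDS",
]

COCO_IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)


@dataclass
class MetricsReport:
    """Segmentation AP figures (fractions) and/or regression errors (kg)."""

    ap: float | None = None
    ap50: float | None = None
    ap75: float | None = None
    mae: float | None = None
    mse: float | None = None
    mape: float | None = None
    r2: float | None = None
    skipped_images: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("ap", "ap50", "ap75", "mae", "mse", "mape", "r2")
            if getattr(self, k) is not None
        }


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (N, 2) array of points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts


def sample_contour_points(polygon, count: int, phase: float = 0.0) -> np.ndarray:
    """Sample `count` points equally spaced by arc length along a closed polygon.

    `phase` is the fractional offset (of the total perimeter) of the first
    sample; the orientation of the input polygon is preserved.
    """
    verts = _as_points(polygon)
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if count < 3:
        raise ValueError("count must be >= 3")
    seg = np.roll(verts, -1, axis=0) - verts
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    perimeter = seglen.sum()
    if perimeter <= 0:
        raise ValueError("degenerate contour")
    # arc-length positions of each sample
    s = (phase + np.arange(count) / count) % 1.0
    target = s * perimeter
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.searchsorted(cum, target, side="right") - 1
    idx = np.clip(idx, 0, len(verts) - 1)
    local = target - cum[idx]
    frac = np.where(seglen[idx] > 0, local / np.where(seglen[idx] > 0, seglen[idx], 1.0), 0.0)
    return verts[idx] + frac[:, None] * seg[idx]


def box_normalize(points) -> np.ndarray:
    """Normalize points to the unit square via their own bounding box."""
    pts = _as_points(points)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    ext = hi - lo
    if ext[0] <= 0 or ext[1] <= 0:
        raise ValueError("degenerate box")
    return (pts - lo) / ext


def _greedy_tour(dist: np.ndarray, start: int) -> np.ndarray:
    n = dist.shape[0]
    visited = np.zeros(n, dtype=bool)
    tour = np.empty(n, dtype=int)
    tour[0] = start
    visited[start] = True
    cur = start
    for k in range(1, n):
        d = dist[cur].copy()
        d[visited] = np.inf
        nxt = int(np.argmin(d))  # argmin takes the lowest index on ties
        tour[k] = nxt
        visited[nxt] = True
        cur = nxt
    return tour


def _tour_length(dist: np.ndarray, tour: np.ndarray) -> float:
    return float(dist[tour, np.roll(tour, -1)].sum())


def order_points_tsp(points) -> np.ndarray:
    """Order an unordered point set into a closed contour.

    Nearest-neighbour greedy tours are grown from every start point; the
    input order itself is included as a candidate; the tour of minimal total
    closed-loop Euclidean length wins (earliest candidate on ties).
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    dist = cdist(pts, pts)
    best_tour = np.arange(n)  # identity (input order) candidate
    best_len = _tour_length(dist, best_tour)
    for start in range(n):
        tour = _greedy_tour(dist, start)
        length = _tour_length(dist, tour)
        if length < best_len - 1e-12:
            best_len = length
            best_tour = tour
    return pts[best_tour]


def _is_simple(verts: np.ndarray) -> bool:
    try:
        from shapely.geometry import LinearRing

        return LinearRing(verts).is_valid
    except Exception:
        return True


def rasterize_contour(contour, height: int, width: int) -> np.ndarray:
    """Rasterize a closed polygon to a binary H x W mask.

    A pixel is filled when its centre lies inside the polygon (even-odd
    rule); the result is clipped to the image rectangle.
    """
    verts = _as_points(contour)
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be positive")
    if not _is_simple(verts):
        warnings.warn("self-intersecting polygon rasterized with even-odd rule")
    mask = np.zeros((height, width), dtype=np.uint8)
    # shift by the half-pixel so integer indices test pixel centres
    rr, cc = _draw.polygon(verts[:, 1] - 0.5, verts[:, 0] - 0.5, shape=(height, width))
    mask[rr, cc] = 1
    return mask


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Extract the longest iso-contour of a binary mask as (x, y) points."""
    contours = _measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask")
    longest = max(contours, key=len)
    # find_contours returns (row, col) in index units; centre convention adds 0.5
    return np.stack([longest[:, 1] + 0.5, longest[:, 0] + 0.5], axis=1)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def _ap_101(tp: np.ndarray, fp: np.ndarray, n_truth: int) -> float:
    """COCO 101-point interpolated average precision."""
    if n_truth == 0:
        return 0.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_truth
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # monotone non-increasing envelope
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    rec_levels = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, rec_levels, side="left")
    prec_at = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(prec_at.mean())


def mask_ap(predicted, truth, iou_thresholds=None) -> MetricsReport:
    """COCO-style mask AP over one or several images.

    `predicted`: list of ``(mask, score)`` pairs, or a list of such lists
    (one per image); `truth` correspondingly a list of masks or list of
    lists. Matching is greedy in score order, one match per ground-truth
    object per IoU threshold. Images with neither predictions nor truths
    are skipped and recorded in ``skipped_images``.
    """
    if iou_thresholds is None:
        iou_thresholds = COCO_IOU_THRESHOLDS
    iou_thresholds = np.asarray(iou_thresholds, dtype=float)

    # normalize to per-image lists
    def _is_per_image(p):
        return len(p) > 0 and isinstance(p[0], (list, tuple)) and (
            len(p[0]) != 2 or not np.isscalar(p[0][1])
        )

    if _is_per_image(predicted) or (len(predicted) == 0 and _is_per_image(truth)) or (
        truth and isinstance(truth[0], list)
    ):
        pred_images, truth_images = list(predicted), list(truth)
    else:
        pred_images, truth_images = [predicted], [truth]

    skipped = []
    ious_per_image = []
    scores_per_image = []
    n_truth = 0
    for img_i, (preds, gts) in enumerate(zip(pred_images, truth_images)):
        if len(preds) == 0 and len(gts) == 0:
            skipped.append(img_i)
            continue
        n_truth += len(gts)
        if len(preds) == 0:
            ious_per_image.append(np.zeros((0, len(gts))))
            scores_per_image.append(np.zeros(0))
            continue
        masks = [p[0] for p in preds]
        scores = np.array([p[1] for p in preds], dtype=float)
        iou = np.zeros((len(masks), len(gts)))
        for i, m in enumerate(masks):
            for j, g in enumerate(gts):
                iou[i, j] = mask_iou(m, g)
        ious_per_image.append(iou)
        scores_per_image.append(scores)

    if n_truth == 0 and all(len(s) == 0 for s in scores_per_image):
        return MetricsReport(skipped_images=skipped)

    aps = []
    ap_at = {}
    for thr in iou_thresholds:
        records = []  # (score, is_tp)
        for iou, scores in zip(ious_per_image, scores_per_image):
            order = np.argsort(-scores, kind="stable")
            matched = np.zeros(iou.shape[1], dtype=bool)
            for i in order:
                cand = np.where(~matched & (iou[i] >= thr))[0]
                if len(cand):
                    j = cand[np.argmax(iou[i][cand])]
                    matched[j] = True
                    records.append((scores[i], 1))
                else:
                    records.append((scores[i], 0))
        records.sort(key=lambda r: -r[0])
        tp = np.array([r[1] for r in records], dtype=float)
        fp = 1.0 - tp
        ap = _ap_101(tp, fp, n_truth)
        aps.append(ap)
        ap_at[round(float(thr), 2)] = ap
    return MetricsReport(
        ap=float(np.mean(aps)),
        ap50=ap_at.get(0.5),
        ap75=ap_at.get(0.75),
        skipped_images=skipped,
    )


def regression_metrics(predicted, truth) -> MetricsReport:
    """MAE, MSE, MAPE (%) and the coefficient of determination R^2."""
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(truth, dtype=float)
    if yhat.shape != y.shape or y.size == 0:
        raise ValueError("predicted and truth must have equal nonzero length")
    if np.any(y == 0):
        raise ValueError("MAPE undefined for zero truth values")
    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(y)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / ss_tot) if ss_tot > 0 else float("nan")
    return MetricsReport(mae=mae, mse=mse, mape=mape, r2=r2)


# ----------------------------------------------------------------- COCO I/O
def mask_to_rle(mask: np.ndarray) -> dict:
    """Uncompressed COCO run-length encoding (column-major counts)."""
    h, w = mask.shape
    flat = np.asarray(mask, dtype=np.uint8).flatten(order="F")
    # counts alternate starting with the number of leading zeros
    change = np.flatnonzero(np.diff(flat))
    runs = np.diff(np.concatenate([[-1], change, [flat.size - 1]]))
    counts = runs.tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(h), int(w)], "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=np.uint8)
    pos, val = 0, 0
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = 1
        pos += run
        val = 1 - val
    return flat.reshape((h, w), order="F")


def write_coco(path, images: list, annotations: list) -> None:
    """Write a minimal single-category COCO instance-segmentation file.

    `images`: dicts with id/width/height/file_name; `annotations`: dicts
    with id/image_id/segmentation (flat [x0, y0, x1, y1, ...] polygon) and
    optional extra keys, which are preserved.
    """
    anns = []
    for a in annotations:
        a = dict(a)
        poly = np.asarray(a["segmentation"], dtype=float).reshape(-1, 2)
        a["segmentation"] = [np.round(poly, 3).flatten().tolist()]
        a.setdefault("category_id", 1)
        a.setdefault("iscrowd", 0)
        if "bbox" not in a:
            lo = poly.min(axis=0)
            hi = poly.max(axis=0)
            a["bbox"] = [float(lo[0]), float(lo[1]), float(hi[0] - lo[0]), float(hi[1] - lo[1])]
        if "area" not in a:
            x, y = poly[:, 0], poly[:, 1]
            a["area"] = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
        anns.append(a)
    doc = {
        "images": list(images),
        "annotations": anns,
        "categories": [{"id": 1, "name": "animal"}],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def read_coco(path):
    """Read a COCO polygon file; returns (images, annotations) with
    annotation segmentations converted to (N, 2) arrays."""
    with open(path) as fh:
        doc = json.load(fh)
    anns = []
    for a in doc.get("annotations", []):
        a = dict(a)
        seg = a["segmentation"]
        if isinstance(seg, dict):
            a["mask"] = rle_to_mask(seg)
        else:
            a["segmentation"] = np.asarray(seg[0], dtype=float).reshape(-1, 2)
        anns.append(a)
    return doc.get("images", []), anns
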