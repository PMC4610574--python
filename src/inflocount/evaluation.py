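"""Point-detection scoring against gold-standard flower centers.

Detected centers are matched to labelled centers by greedy
nearest-pair assignment within a radius; each labelled flower can be
claimed by at most one detection, and any further detection falling
within the radius of an already-claimed flower is a *redundant true
positive*, counted as a false positive.  From the resulting TP/FP/FN
counts:

    Recall    RC = TP / (TP + FN)
    Precision PC = TP / (TP + FP)

Set-level figures are unweighted per-image means of RC and PC (not
pooled counts), skipping images where a metric is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import GroundTruth

__all__ = [
    "MatchResult",
    "MetricsReport",
    "default_radius",
    "match_detections",
    "compute_metrics",
    "aggregate_metrics",
    "evaluate_detections",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN accounting for one image.

    ``pairs`` lists the matched (detection index, truth index) pairs;
    TP = len(pairs), TP + FN = number of truths, TP + FP = number of
    detections.
    """

    TP: int
    FP: int
    FN: int
    pairs: list[tuple[int, int]]


@dataclass(frozen=True)
class MetricsReport:
    """Recall/precision for one image, or per-set averages.

    Undefined metrics (zero denominator) are carried as ``None``,
    never coerced to 0.  For aggregates, ``n_images`` counts the images
    contributing to each mean.
    """

    recall: float | None = None
    precision: float | None = None
    mean_recall: float | None = None
    mean_precision: float | None = None
    n_images: int | None = None


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, GroundTruth):
        obj = obj.centers
    pts = np.asarray(list(obj), dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (row, col) pairs")
    return pts


def default_radius(truth, fallback: float = 5.0) -> float:
    """Matching radius adapted to flower scale.

    Half the median nearest-neighbour distance among the truth points:
    large enough to absorb centroid offset between a highlight and the
    flower center, small enough that neighbouring flowers stay
    distinguishable.  With fewer than two truth points the scale is
    undefined and ``fallback`` is returned.
    """
    pts = _as_points(truth)
    if len(pts) < 2:
        return fallback
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    return float(np.median(dist.min(axis=1)) / 2.0)


def match_detections(detections, truth, radius: float) -> MatchResult:
    """Greedily match detections to truth centers within ``radius``.

    Candidate (detection, truth) pairs at distance <= radius are taken
    in increasing distance order; a pair is accepted when both its
    detection and its truth point are still unclaimed.  Detections left
    unclaimed are FP — including redundant detections of an
    already-claimed flower — and unclaimed truths are FN.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    det = _as_points(detections)
    tru = _as_points(truth)
    pairs: list[tuple[int, int]] = []
    if len(det) and len(tru):
        diff = det[:, None, :] - tru[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        di, ti = np.nonzero(dist <= radius)
        order = np.lexsort((ti, di, dist[di, ti]))  # distance, then indices
        det_used = np.zeros(len(det), dtype=bool)
        tru_used = np.zeros(len(tru), dtype=bool)
        for k in order:
            d, t = int(di[k]), int(ti[k])
            if not det_used[d] and not tru_used[t]:
                det_used[d] = True
                tru_used[t] = True
                pairs.append((d, t))
    tp = len(pairs)
    return MatchResult(TP=tp, FP=len(det) - tp, FN=len(tru) - tp, pairs=pairs)


def compute_metrics(match: MatchResult) -> MetricsReport:
    """Recall and precision from one image's TP/FP/FN counts."""
    recall = precision = None
    if match.TP + match.FN > 0:
        recall = match.TP / (match.TP + match.FN)
    else:
        logger.warning("recall undefined: no truth points (TP+FN = 0)")
    if match.TP + match.FP > 0:
        precision = match.TP / (match.TP + match.FP)
    else:
        logger.warning("precision undefined: no detections (TP+FP = 0)")
    return MetricsReport(recall=recall, precision=precision)


def aggregate_metrics(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted per-image means of recall and precision.

    Missing per-image values are skipped; a mean over zero values is
    itself missing.
    """
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    recalls = [r.recall for r in reports if r.recall is not None]
    precisions = [r.precision for r in reports if r.precision is not None]
    return MetricsReport(
        mean_recall=float(np.mean(recalls)) if recalls else None,
        mean_precision=float(np.mean(precisions)) if precisions else None,
        n_images=len(reports),
    )


def evaluate_detections(detections, truth, radius: float | None = None) -> MetricsReport:
    """Convenience wrapper: match then score one image."""
    if radius is None:
        radius = default_radius(truth)
    return compute_metrics(match_detections(detections, truth, radius))
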