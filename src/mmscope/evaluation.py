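"""Detection and tracking scores against ground truth.

Mask-level scores follow the standard object-segmentation definitions:
precision = |D∩T| / |D|, recall = |D∩T| / |T| and Jaccard index
= |D∩T| / |D∪T| for a detection mask D and a ground-truth mask T.
Object-level scores: detection efficiency is the percentage of ground-
truth objects covered (by the union of detection labels) over at least a
minimum fraction of their area — an object split across several labels
still counts as detected; detection accuracy is the stricter percentage
of objects matched one-to-one by a single label that touches no other
object.  Tracking efficiency is the percentage of consecutive-frame
ground-truth links reproduced with the correct identities and event
type, computed only over correctly detected objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class MaskScore:
    precision: float
    recall: float
    jaccard: float


def mask_scores(detected: np.ndarray, truth: np.ndarray) -> MaskScore:
    """Precision, recall and Jaccard index of two binary masks."""
    d = np.asarray(detected, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if d.shape != t.shape:
        raise ValueError("masks must share one shape")
    nd, nt = int(d.sum()), int(t.sum())
    if nt == 0:
        raise ValueError("empty ground-truth mask: recall undefined")
    if nd == 0:
        raise ValueError("empty detection mask: precision undefined")
    inter = int((d & t).sum())
    union = nd + nt - inter
    return MaskScore(precision=inter / nd, recall=inter / nt, jaccard=inter / union)


def _overlap_matrix(det_labels: np.ndarray, truth_labels: np.ndarray):
    """Pixel-overlap counts between every detection and truth label."""
    det_ids = np.unique(det_labels)
    det_ids = det_ids[det_ids > 0]
    truth_ids = np.unique(truth_labels)
    truth_ids = truth_ids[truth_ids > 0]
    overlaps: Dict[Tuple[int, int], int] = {}
    both = (det_labels > 0) & (truth_labels > 0)
    pairs, counts = np.unique(
        np.stack([det_labels[both], truth_labels[both]]), axis=1, return_counts=True
    )
    for (d, t), n in zip(pairs.T, counts):
        overlaps[(int(d), int(t))] = int(n)
    return det_ids, truth_ids, overlaps


def detection_efficiency(
    det_labels: np.ndarray,
    truth_labels: np.ndarray,
    min_overlap: float = 0.5,
) -> float:
    """Percentage of truth objects detected.

    A truth object counts as detected when the union of all detection
    labels covers at least ``min_overlap`` of its area; being split over
    several labels does not disqualify it.
    """
    truth_ids = np.unique(truth_labels)
    truth_ids = truth_ids[truth_ids > 0]
    if truth_ids.size == 0:
        raise ValueError("no ground-truth objects")
    det_any = det_labels > 0
    hit = 0
    for t in truth_ids:
        region = truth_labels == t
        if (det_any & region).sum() >= min_overlap * region.sum():
            hit += 1
    return 100.0 * hit / truth_ids.size


def detection_accuracy(
    det_labels: np.ndarray,
    truth_labels: np.ndarray,
    min_overlap: float = 0.5,
) -> float:
    """Percentage of truth objects identified by exactly one label.

    The matched label must cover >= ``min_overlap`` of the object, no
    other label may overlap the object, and the label must not overlap any
    other object (splits and merges both fail).
    """
    det_ids, truth_ids, overlaps = _overlap_matrix(det_labels, truth_labels)
    if truth_ids.size == 0:
        raise ValueError("no ground-truth objects")
    truth_areas = {int(t): int((truth_labels == t).sum()) for t in truth_ids}
    dets_of_truth: Dict[int, List[int]] = {int(t): [] for t in truth_ids}
    truths_of_det: Dict[int, List[int]] = {int(d): [] for d in det_ids}
    for (d, t), n in overlaps.items():
        dets_of_truth[t].append(d)
        truths_of_det[d].append(t)
    accurate = 0
    for t in truth_ids:
        t = int(t)
        dets = dets_of_truth[t]
        if len(dets) != 1:
            continue
        d = dets[0]
        if len(truths_of_det[d]) != 1:
            continue
        if overlaps[(d, t)] >= min_overlap * truth_areas[t]:
            accurate += 1
    return 100.0 * accurate / truth_ids.size


def match_objects(
    det_labels: np.ndarray,
    truth_labels: np.ndarray,
    min_overlap: float = 0.5,
) -> Dict[int, int]:
    """truth id -> detection label covering >= min_overlap of it (if any)."""
    det_ids, truth_ids, overlaps = _overlap_matrix(det_labels, truth_labels)
    out: Dict[int, int] = {}
    for t in truth_ids:
        t = int(t)
        area = int((truth_labels == t).sum())
        best, best_n = None, 0
        for (d, tt), n in overlaps.items():
            if tt == t and n > best_n:
                best, best_n = d, n
        if best is not None and best_n >= min_overlap * area:
            out[t] = best
    return out


def tracking_efficiency(
    predicted_links: Iterable[Tuple[int, int, Tuple[int, ...], str]],
    truth_links: Iterable[Tuple[int, int, Tuple[int, ...], str]],
) -> float:
    """Percentage of ground-truth links predicted with the right children
    and event type.

    Links are (frame, parent_id, children_ids, event) tuples expressed in
    a common id space (ground-truth ids; predictions must be mapped to
    truth ids via detection matching first).  Children order is ignored.
    """
    truth = {
        (frame, parent): (frozenset(children), event)
        for frame, parent, children, event in truth_links
    }
    if not truth:
        raise ValueError("no ground-truth links to evaluate")
    pred = {
        (frame, parent): (frozenset(children), event)
        for frame, parent, children, event in predicted_links
    }
    correct = sum(1 for key, val in truth.items() if pred.get(key) == val)
    return 100.0 * correct / len(truth)
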