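"""Bacteria segmentation inside detected channels.

In both brightfield and phase contrast the bacteria appear darker than
their channel background, so each channel image is inverted and its
slowly varying background removed with a rolling-ball filter; the cells
then stand out bright on a near-zero background wherever they sit along
the channel profile.  A scale-normalised Laplacian-of-Gaussian filter
bank, maximum-projected over scale, turns rods of varying width into
uniform positive blobs.  One Li threshold, computed jointly over the
responses of all channels in the frame (a per-channel threshold would
over-segment empty channels), binarises the responses; watershed markers
are taken as the regions deeper than a configured distance from the mask
background, and the marker-controlled watershed splits touching regions.
Survivors are filtered for width and area.

A second splitting stage targets abutting cells the watershed missed:
each region is skeletonised and a split is declared where, within a small
window along the skeleton, both the local width (distance transform) and
the local intensity drop below median - k*MAD thresholds computed over
all initially detected bacteria of the frame.  Regions are cut
transversally at split points; the children partition the parent exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, restoration, segmentation

from .channels import ChannelSet, threshold_li
from .config import PipelineConfig
from .io import FrameStack

logger = logging.getLogger(__name__)


@dataclass
class Bacterium:
    """One segmented bacterium within one channel of one frame."""

    id: int
    channel_id: int
    centroid: Tuple[float, float]  # (row, col), frame coordinates
    area: int
    mask: np.ndarray = field(repr=False, compare=False)  # full-frame boolean


@dataclass
class BacteriaSet:
    """Labelled bacteria per channel for one frame."""

    labels: Dict[int, np.ndarray]  # channel id -> full-frame int label image
    bacteria: List[Bacterium]

    def in_channel(self, channel_id: int) -> List[Bacterium]:
        return [b for b in self.bacteria if b.channel_id == channel_id]

    def __len__(self) -> int:
        return len(self.bacteria)


@dataclass(frozen=True)
class SplitThresholds:
    """Frame-level robust thresholds for the skeleton splitting stage."""

    median_intensity: float
    mad_intensity: float
    median_width: float
    mad_width: float
    k: float

    @property
    def intensity_cut(self) -> float:
        return self.median_intensity - self.k * self.mad_intensity

    @property
    def width_cut(self) -> float:
        return self.median_width - self.k * self.mad_width


def subtract_background(
    channel_image: np.ndarray,
    config: PipelineConfig | None = None,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Invert a channel image and remove its rolling-ball background.

    Output is >= 0 with the bacteria bright on a near-zero background,
    independent of their position along the channel profile and of any
    smooth illumination gradient.
    """
    config = config or PipelineConfig()
    img = np.asarray(channel_image, dtype=np.float64)
    inverted = img.max() - img
    if mask is not None:
        inverted = np.where(mask, inverted, 0.0)
    radius = max(config.s(config.rolling_ball_radius), 1.0)
    background = restoration.rolling_ball(inverted, radius=radius)
    out = inverted - background
    return np.maximum(out, 0.0)


def scale_space_filter(
    image: np.ndarray, scales: Sequence[float] | None = None, config: PipelineConfig | None = None
) -> np.ndarray:
    """Scale-normalised Laplacian-of-Gaussian bank, maximum-projected.

    For each sigma the response is sigma^2 * (-LoG); bright blobs give
    positive responses with a scale-independent magnitude, so the pixelwise
    maximum over scales picks each structure's best scale.
    """
    config = config or PipelineConfig()
    if scales is None:
        scales = config.log_scales_px
    img = np.asarray(image, dtype=np.float64)
    # remove the DC component first: the discrete LoG kernel does not sum
    # exactly to zero, so a constant offset would bias every response
    img = img - img.mean()
    best = np.full(img.shape, -np.inf)
    for sigma in scales:
        response = -(sigma**2) * ndi.gaussian_laplace(img, sigma)
        np.maximum(best, response, out=best)
    return best


def _region_width(mask: np.ndarray) -> float:
    """Characteristic width: twice the maximum inscribed-disk radius."""
    return float(2.0 * ndi.distance_transform_edt(mask).max())


def segment_initial(
    response: np.ndarray,
    threshold: float,
    config: PipelineConfig | None = None,
    channel_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Initial labelling of one channel's scale-space response.

    ``threshold`` is the frame-level Li threshold over all channel
    responses.  Markers are the connected regions whose distance transform
    exceeds the configured marker distance; a marker-controlled watershed
    on the inverted response delineates the cells, which are then filtered
    for width and area.  An empty channel yields zero labels.
    """
    config = config or PipelineConfig()
    mask = response > threshold
    if channel_mask is not None:
        mask &= channel_mask
    if not mask.any():
        return np.zeros(response.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    markers, n_markers = ndi.label(distance >= config.s(config.marker_distance))
    if n_markers == 0:
        return np.zeros(response.shape, dtype=np.int32)
    labels = segmentation.watershed(-response, markers=markers, mask=mask, connectivity=1)

    lo_w, hi_w = config.bacteria_width_px
    lo_a, hi_a = config.bacteria_area_px2
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        area = int(region.sum())
        if not (lo_a <= area <= hi_a):
            continue
        width = _region_width(region)
        if not (lo_w <= width <= hi_w):
            continue
        out[region] = next_label
        next_label += 1
    return out


def _skeleton_path(mask: np.ndarray) -> Optional[np.ndarray]:
    """Ordered (row, col) pixels of the longest skeleton path of ``mask``.

    Returns None for degenerate skeletons (loops, empty)."""
    skel = morphology.skeletonize(mask)
    pts = np.argwhere(skel)
    if len(pts) < 3:
        return None
    index = {tuple(p): i for i, p in enumerate(pts)}
    neigh: List[List[int]] = [[] for _ in pts]
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    neigh[i].append(j)
    ends = [i for i, nb in enumerate(neigh) if len(nb) == 1]
    if not ends:
        return None

    def bfs(start: int) -> Tuple[int, Dict[int, int]]:
        prev = {start: -1}
        queue = [start]
        last = start
        while queue:
            nxt = []
            for node in queue:
                for j in neigh[node]:
                    if j not in prev:
                        prev[j] = node
                        nxt.append(j)
                        last = j
            queue = nxt
        return last, prev

    far, _ = bfs(ends[0])
    far2, prev = bfs(far)
    path = []
    node = far2
    while node != -1:
        path.append(node)
        node = prev[node]
    return pts[np.array(path)]


def compute_split_thresholds(
    labelled: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: PipelineConfig | None = None,
) -> Optional[SplitThresholds]:
    """Median/MAD of skeleton width and intensity over all initial bacteria.

    ``labelled`` pairs each (per-channel) label image with the aligned
    intensity image the values are read from.
    """
    config = config or PipelineConfig()
    widths: List[np.ndarray] = []
    intensities: List[np.ndarray] = []
    for lab_img, intensity in labelled:
        for lab in range(1, int(lab_img.max()) + 1):
            mask = lab_img == lab
            path = _skeleton_path(mask)
            if path is None:
                continue
            dt = ndi.distance_transform_edt(mask)
            widths.append(dt[path[:, 0], path[:, 1]])
            intensities.append(intensity[path[:, 0], path[:, 1]])
    if not widths:
        return None
    w = np.concatenate(widths)
    i = np.concatenate(intensities)
    return SplitThresholds(
        median_intensity=float(np.median(i)),
        mad_intensity=float(np.median(np.abs(i - np.median(i)))),
        median_width=float(np.median(w)),
        mad_width=float(np.median(np.abs(w - np.median(w)))),
        k=config.split_k,
    )


def split_adjacent(
    labels: np.ndarray,
    intensity: np.ndarray,
    thresholds: Optional[SplitThresholds],
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Cut regions at skeleton points that are both constricted and dim.

    A split fires only where the skeleton width falls below
    median_width - k*MAD AND the intensity falls below
    median_intensity - k*MAD within the same small window; requiring both
    keeps single cells with a dim patch, or a waist but no dimming, whole.
    Children partition the parent region exactly.
    """
    config = config or PipelineConfig()
    if thresholds is None:
        return labels.copy()
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    window = max(int(config.split_window), 1)
    for lab in range(1, int(labels.max()) + 1):
        mask = labels == lab
        path = _skeleton_path(mask)
        if path is None:
            out[mask] = next_label
            next_label += 1
            continue
        dt = ndi.distance_transform_edt(mask)
        w = dt[path[:, 0], path[:, 1]]
        i = intensity[path[:, 0], path[:, 1]]
        narrow = w < thresholds.width_cut
        dim = i < thresholds.intensity_cut
        # the rounded end caps of a rod are naturally narrow and dim, so
        # exclude a cap-sized margin at both skeleton ends
        margin = max(int(np.ceil(2.0 * thresholds.median_width)), 3)
        fires = np.zeros(len(path), dtype=bool)
        for idx in range(margin, len(path) - margin):
            lo, hi = max(idx - window + 1, margin), min(idx + window, len(path) - margin)
            if narrow[lo:hi].any() and dim[lo:hi].any() and (narrow[idx] or dim[idx]):
                fires[idx] = True
        # split point = centre of each run of firing skeleton pixels,
        # excluding the skeleton ends (no zero-area children)
        cut_indices: List[int] = []
        run_start = None
        for idx in range(len(path) + 1):
            active = idx < len(path) and fires[idx]
            if active and run_start is None:
                run_start = idx
            elif not active and run_start is not None:
                centre = (run_start + idx - 1) // 2
                if 0 < centre < len(path) - 1:
                    cut_indices.append(centre)
                run_start = None
        if not cut_indices:
            out[mask] = next_label
            next_label += 1
            continue
        # segment the skeleton between cuts and assign every region pixel
        # to the nearest skeleton segment
        bounds = [0] + [c for c in cut_indices] + [len(path)]
        seg_of_skel = np.zeros(len(path), dtype=np.int32)
        for seg, (a, b) in enumerate(zip(bounds, bounds[1:])):
            seg_of_skel[a:b] = seg
        rr, cc = np.nonzero(mask)
        d2 = (rr[:, None] - path[None, :, 0]) ** 2 + (cc[:, None] - path[None, :, 1]) ** 2
        nearest = np.argmin(d2, axis=1)
        assigned = seg_of_skel[nearest]
        n_segments = len(bounds) - 1
        # a cut that leaves a child below the minimum bacterium area was
        # spurious: merge that child back into its neighbour so the
        # children still partition the parent exactly
        lo_area = config.bacteria_area_px2[0]
        sizes = np.bincount(assigned, minlength=n_segments)
        order = np.argsort(sizes)
        remap = np.arange(n_segments)
        for seg in order:
            if sizes[seg] >= lo_area or sizes[seg] == 0:
                continue
            neighbours = [s for s in (seg - 1, seg + 1) if 0 <= s < n_segments and remap[s] != seg]
            if not neighbours:
                continue
            target = max(neighbours, key=lambda s: sizes[remap[s]])
            tgt = remap[target]
            sizes[tgt] += sizes[seg]
            sizes[seg] = 0
            remap[remap == seg] = tgt
        assigned = remap[assigned]
        for seg in np.unique(assigned):
            sel = assigned == seg
            out[rr[sel], cc[sel]] = next_label
            next_label += 1
    return out


def detect_bacteria(
    frame: FrameStack,
    channels: ChannelSet,
    config: PipelineConfig | None = None,
) -> BacteriaSet:
    """Segment the bacteria in every channel of one frame.

    Per channel: background-subtract and invert, scale-space filter; then
    one joint Li threshold over all channel responses feeds the
    marker-controlled watershed, and the skeleton splitting stage refines
    adjacent cells.  Deterministic: identical input gives identical labels.
    """
    config = config or PipelineConfig()
    responses: Dict[int, np.ndarray] = {}
    clean: Dict[int, np.ndarray] = {}
    masks: Dict[int, np.ndarray] = {}
    for info in channels.channels:
        cid = info.id
        mask = channels.mask_of(cid)
        if not mask.any():
            continue
        rows = np.any(mask, axis=1)
        cols = np.any(mask, axis=0)
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        sl = (slice(r0, r1 + 1), slice(c0, c1 + 1))
        sub_mask = mask[sl]
        sub_img = frame.primary[sl]
        bg_free = subtract_background(sub_img, config, mask=sub_mask)
        response = scale_space_filter(bg_free, config=config)
        responses[cid] = np.where(sub_mask, response, 0.0)
        clean[cid] = bg_free
        masks[cid] = (sl, sub_mask)

    if not responses:
        return BacteriaSet(labels={}, bacteria=[])

    pooled = np.concatenate(
        [responses[cid][masks[cid][1]].ravel() for cid in responses]
    )
    try:
        t = threshold_li(pooled)
    except ValueError:
        t = np.inf  # all-flat responses: nothing to segment

    initial: Dict[int, np.ndarray] = {}
    for cid, response in responses.items():
        sl, sub_mask = masks[cid]
        initial[cid] = segment_initial(response, t, config, channel_mask=sub_mask)

    thresholds = compute_split_thresholds(
        [(initial[cid], clean[cid]) for cid in responses], config
    )

    labels_full: Dict[int, np.ndarray] = {}
    bacteria: List[Bacterium] = []
    next_id = 1
    for cid in responses:
        sl, sub_mask = masks[cid]
        refined = split_adjacent(initial[cid], clean[cid], thresholds, config)
        full = np.zeros(frame.primary.shape, dtype=np.int32)
        full[sl] = refined
        labels_full[cid] = full
        for lab in range(1, int(refined.max()) + 1):
            region = full == lab
            rr, cc = np.nonzero(region)
            if rr.size == 0:
                continue
            bacteria.append(
                Bacterium(
                    id=next_id,
                    channel_id=cid,
                    centroid=(float(rr.mean()), float(cc.mean())),
                    area=int(rr.size),
                    mask=region,
                )
            )
            # relabel to the global id within this channel image
            full[region] = next_id
            next_id += 1
    return BacteriaSet(labels=labels_full, bacteria=bacteria)
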