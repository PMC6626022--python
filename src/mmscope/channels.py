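"""Microfluidic channel detection.

The channel walls are the most reliable landmark in a mother-machine
frame: they are enhanced with a ridge filter (Frangi for brightfield,
where walls are dark lines, Sobel gradient magnitude for phase contrast,
where they are strong edges), binarised with Li's minimum cross-entropy
threshold, and filtered by connected-component area.  The surviving
outlines are dilated to close small gaps, hole-filled, and the channel
interiors recovered as the difference between the filled regions and the
outlines.  Each interior yields an axis vector (its farthest-apart
perimeter pair) that is filtered for length and perpendicular width;
channels missed by this process are interpolated from the regular
channel-to-channel spacing, with the average detected channel shape
stamped at each interpolated position.  A frame in which fewer than three
channels are detected is rejected: the spacing cannot be estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from scipy.ndimage import binary_dilation as _nd_binary_dilation
from skimage import filters, morphology


def _binary_dilate(mask, footprint):
    return _nd_binary_dilation(mask, structure=footprint)
from skimage.transform import rotate as _sk_rotate

from .config import PipelineConfig
from .modality import Modality

logger = logging.getLogger(__name__)


class FrameRejected(RuntimeError):
    """Fewer channels than required were detected; skip this frame."""


@dataclass
class ChannelInfo:
    """One detected (or interpolated) channel."""

    id: int
    centroid: Tuple[float, float]  # (row, col)
    axis_vector: Tuple[float, float]  # (drow, dcol), |.| = channel length
    width_px: float
    interpolated: bool = False
    mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def length_px(self) -> float:
        return float(np.hypot(*self.axis_vector))


@dataclass
class ChannelSet:
    """All channels of one frame, ordered left to right."""

    labels: np.ndarray  # 0 = background, k = channel k
    channels: List[ChannelInfo]
    mean_shape: Optional[np.ndarray]
    spacing_px: float

    def __len__(self) -> int:
        return len(self.channels)

    def mask_of(self, channel_id: int) -> np.ndarray:
        return self.labels == channel_id


def ridge_filter(image: np.ndarray, modality: Modality, config: PipelineConfig | None = None) -> np.ndarray:
    """Enhance channel outlines: Frangi ridges (brightfield, dark walls)
    or Sobel gradient magnitude (phase contrast).  Response is >= 0."""
    config = config or PipelineConfig()
    img = np.asarray(image, dtype=np.float64)
    if modality is Modality.BRIGHTFIELD:
        response = filters.frangi(img, sigmas=config.frangi_scales_px, black_ridges=True)
    else:
        response = filters.sobel(img)
    return np.maximum(response, 0.0)


def threshold_li(image: np.ndarray) -> float:
    """Li's iterative minimum cross-entropy threshold.

    The returned value is a fixed point of Li & Tam's iteration; pixels
    strictly above it are foreground.  Raises ValueError for a constant
    image, which has no threshold.
    """
    values = np.asarray(image, dtype=np.float64)
    if values.min() == values.max():
        raise ValueError("constant image: threshold undefined")
    return float(filters.threshold_li(values))


def extract_channel_regions(mask: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Channel interiors from a binary outline mask.

    Connected components outside the configured area bounds are dropped;
    the survivors are dilated to close small gaps in the outlines, holes
    are filled, and the interiors are returned (labelled) as the filled
    regions minus the dilated outlines.
    """
    config = config or PipelineConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    lab, n = ndi.label(mask)
    if n:
        areas = np.bincount(lab.ravel())[1:]
        lo, hi = config.channel_area_px2
        keep = np.flatnonzero((areas >= lo) & (areas <= hi)) + 1
        mask = np.isin(lab, keep)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    radius = max(int(round(config.s(config.outline_dilation_radius))), 1)
    dilated = _binary_dilate(mask, morphology.disk(radius))
    filled = ndi.binary_fill_holes(dilated)
    interiors = filled & ~dilated
    # the cells inside a channel also respond to the ridge/edge filter and
    # can slice its interior into fragments; treat all fragments within one
    # filled component as one channel interior and close the slice gaps
    filled_lab, n_filled = ndi.label(filled)
    close_r = radius + 2
    footprint = morphology.disk(close_r)
    out = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    for comp in range(1, n_filled + 1):
        comp_mask = filled_lab == comp
        interior = comp_mask & interiors
        if not interior.any():
            continue
        closed = ndi.binary_closing(
            np.pad(interior, close_r), structure=footprint
        )[close_r:-close_r, close_r:-close_r]
        out[closed & comp_mask] = next_label
        next_label += 1
    return out


def _farthest_pair(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """The two points farthest apart (they lie on the convex hull)."""
    if len(points) > 4:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (collinear) regions: brute force below
    diff = points[:, None, :] - points[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return points[i], points[j]


def fit_channel_vectors(
    interiors: np.ndarray, config: PipelineConfig | None = None
) -> List[ChannelInfo]:
    """Axis vectors of interior regions, filtered for length and width.

    The axis of each region joins its farthest-apart perimeter pixels;
    regions are kept iff the axis length and the perpendicular extent lie
    inside the configured, scale-adjusted ranges.
    """
    config = config or PipelineConfig()
    lo_len, hi_len = config.channel_length_px
    lo_w, hi_w = config.channel_width_px
    infos: List[ChannelInfo] = []
    for region_label in range(1, int(interiors.max()) + 1):
        mask = interiors == region_label
        coords = np.argwhere(mask).astype(np.float64)
        if coords.size == 0:
            continue
        p1, p2 = _farthest_pair(coords)
        axis = p2 - p1
        length = float(np.hypot(*axis))
        if length == 0 or not (lo_len <= length <= hi_len):
            continue
        unit = axis / length
        perp = np.array([-unit[1], unit[0]])
        proj = coords @ perp
        width = float(proj.max() - proj.min()) + 1.0  # pixel extent
        if not (lo_w <= width <= hi_w):
            continue
        # canonical orientation: positive row component (ties: positive col)
        if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
            axis = -axis
        centroid = coords.mean(axis=0)
        infos.append(
            ChannelInfo(
                id=0,
                centroid=(float(centroid[0]), float(centroid[1])),
                axis_vector=(float(axis[0]), float(axis[1])),
                width_px=width,
                mask=mask,
            )
        )
    return infos


def _mean_axis_angle(infos: Sequence[ChannelInfo]) -> float:
    """Mean axis direction (radians) of the detected channels."""
    vecs = np.array([c.axis_vector for c in infos], dtype=np.float64)
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    mean = units.mean(axis=0)
    return float(np.arctan2(mean[0], mean[1]))


def _aligned_mean_shape(infos: Sequence[ChannelInfo], mean_angle: float) -> np.ndarray:
    """Pixelwise-majority shape of the detected interiors after translating
    them to a common centroid and rotating them to the common axis angle."""
    half = 1
    for info in infos:
        extent = int(np.ceil(max(info.length_px, info.width_px))) + 4
        half = max(half, extent // 2 + 2)
    size = 2 * half + 1
    stack = np.zeros((len(infos), size, size), dtype=np.float64)
    for idx, info in enumerate(infos):
        r0, c0 = info.centroid
        rr, cc = np.nonzero(info.mask)
        r = np.round(rr - r0 + half).astype(int)
        c = np.round(cc - c0 + half).astype(int)
        ok = (r >= 0) & (r < size) & (c >= 0) & (c < size)
        canvas = np.zeros((size, size), dtype=np.float64)
        canvas[r[ok], c[ok]] = 1.0
        angle = np.arctan2(info.axis_vector[0], info.axis_vector[1])
        delta_deg = np.rad2deg(angle - mean_angle)
        if abs(delta_deg) > 0.5:
            canvas = _sk_rotate(canvas, delta_deg, order=0, preserve_range=True)
        stack[idx] = canvas
    majority = stack.mean(axis=0) > 0.5
    # trim to the tight bounding box
    rows = np.any(majority, axis=1)
    cols = np.any(majority, axis=0)
    if not rows.any():
        return majority
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return majority[r0 : r1 + 1, c0 : c1 + 1]


def _stamp(labels: np.ndarray, shape: np.ndarray, centre: Tuple[float, float], value: int) -> None:
    """Paint ``shape`` centred at ``centre`` into free pixels of ``labels``."""
    sh, sw = shape.shape
    r0 = int(round(centre[0] - (sh - 1) / 2.0))
    c0 = int(round(centre[1] - (sw - 1) / 2.0))
    H, W = labels.shape
    rs, re = max(r0, 0), min(r0 + sh, H)
    cs, ce = max(c0, 0), min(c0 + sw, W)
    if rs >= re or cs >= ce:
        return
    sub = shape[rs - r0 : re - r0, cs - c0 : ce - c0]
    target = labels[rs:re, cs:ce]
    target[sub & (target == 0)] = value


def interpolate_channels(
    infos: Sequence[ChannelInfo],
    frame_shape: Tuple[int, int],
    config: PipelineConfig | None = None,
) -> ChannelSet:
    """Order channels left to right, estimate their spacing, stamp the mean
    shape into interior gaps, and assemble the labelled ChannelSet.

    Raises
    ------
    FrameRejected
        If fewer than ``min_channels`` channels were detected.
    """
    config = config or PipelineConfig()
    infos = list(infos)
    if len(infos) < config.min_channels:
        raise FrameRejected(
            f"only {len(infos)} channel(s) detected; at least {config.min_channels} "
            "are required to estimate the channel spacing"
        )
    mean_angle = _mean_axis_angle(infos)
    axis_unit = np.array([np.sin(mean_angle), np.cos(mean_angle)])
    perp = np.array([-axis_unit[1], axis_unit[0]])
    if perp[1] < 0:  # left-to-right = increasing column
        perp = -perp
    infos.sort(key=lambda c: float(np.dot(c.centroid, perp)))
    positions = np.array([float(np.dot(c.centroid, perp)) for c in infos])
    seps = np.diff(positions)
    # divisor-aware median: a separation spanning a missed channel is an
    # integer multiple of the true pitch, so normalise by that multiple
    # before taking the median (a plain median fails when gaps dominate)
    base = float(seps.min())
    spacing = float(np.median(seps / np.maximum(np.round(seps / base), 1.0)))

    mean_shape = _aligned_mean_shape(infos, mean_angle)

    # fill interior gaps of ~m * spacing with m-1 stamped channels
    full: List[ChannelInfo] = [infos[0]]
    for prev, curr, sep in zip(infos, infos[1:], seps):
        m = int(round(sep / spacing)) if spacing > 0 else 1
        if m >= 2 and abs(sep - m * spacing) <= 0.25 * spacing:
            p0 = np.asarray(prev.centroid)
            p1 = np.asarray(curr.centroid)
            for j in range(1, m):
                centre = p0 + (p1 - p0) * (j / m)
                full.append(
                    ChannelInfo(
                        id=0,
                        centroid=(float(centre[0]), float(centre[1])),
                        axis_vector=prev.axis_vector,
                        width_px=prev.width_px,
                        interpolated=True,
                        mask=None,
                    )
                )
        full.append(curr)
    full.sort(key=lambda c: float(np.dot(c.centroid, perp)))

    radius = max(int(round(config.s(config.channel_mask_dilation))), 0)
    selem = morphology.disk(radius) if radius else None
    labels = np.zeros(frame_shape, dtype=np.int32)
    stamp_shape = mean_shape
    if selem is not None and stamp_shape.any():
        stamp_shape = _binary_dilate(
            np.pad(mean_shape, radius), selem
        )
    for new_id, info in enumerate(full, start=1):
        info.id = new_id
        if info.mask is not None:
            mask = info.mask
            if selem is not None:
                mask = _binary_dilate(mask, selem)
            target = labels
            target[mask & (target == 0)] = new_id
            info.mask = None
        else:
            _stamp(labels, stamp_shape, info.centroid, new_id)
    return ChannelSet(labels=labels, channels=full, mean_shape=mean_shape, spacing_px=spacing)


def detect_channels(
    image: np.ndarray,
    modality: Modality,
    config: PipelineConfig | None = None,
) -> ChannelSet:
    """Full channel detection for one frame.

    Composition of ridge filtering, Li thresholding, interior extraction,
    vector fitting and spacing-based interpolation.  Raises FrameRejected
    when fewer than three channels are found.
    """
    config = config or PipelineConfig()
    response = ridge_filter(image, modality, config)
    t = threshold_li(response)
    mask = response > t
    interiors = extract_channel_regions(mask, config)
    infos = fit_channel_vectors(interiors, config)
    return interpolate_channels(infos, image.shape, config)
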