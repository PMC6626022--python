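"""Synthetic mother-machine time-lapses with complete ground truth.

The renderer emulates what the detection and tracking stages rely on in
real acquisitions: a row of parallel dead-end channels drawn as dark wall
outlines (brightfield) or a bright-on-dark scheme (phase contrast),
rod-shaped bacteria darker than their channel background, uneven
illumination, Gaussian sensor noise, rigid inter-frame drift, and cell
growth, division and lysis over time, with matching fluorescence planes.

Cells are capsules (rectangle with semicircular caps) packed from the
dead end; they grow linearly, divide at a length threshold into two
half-length children separated by a 1-px gap, and lyse (disappear) on a
schedule.  Everything is rendered analytically from device coordinates,
so arbitrary device rotation and sub-pixel drift come for free and the
ground-truth label images are exact by construction.

It deliberately does not model real optics (point-spread function, phase
halo structure) or mechanical cell-cell interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import FrameStack
from .modality import Modality


@dataclass
class FixtureSpec:
    """Geometry, dynamics and rendering parameters of a synthetic series."""

    n_channels: int = 8
    channel_length: float = 150.0
    channel_width: float = 12.0
    pitch: float = 40.0
    wall_thickness: float = 2.5
    device_angle: float = 0.0  # degrees, counter-clockwise
    modality: Modality = Modality.BRIGHTFIELD
    n_frames: int = 5
    #: rigid drift applied per frame transition (dy, dx) px
    drift: Tuple[float, float] = (0.0, 0.0)
    margin: float = 50.0

    # cell dynamics
    cells_per_channel: int = 2
    initial_length_range: Tuple[float, float] = (25.0, 40.0)
    cell_width: float = 8.0
    growth_rate: float = 3.0  # px per frame
    division_length: float = 55.0
    division_gap: float = 1.0
    cell_gap: float = 3.0
    dead_end_offset: float = 3.0
    #: explicit initial lengths per channel (overrides the random draw)
    initial_lengths: Optional[Sequence[Sequence[float]]] = None
    #: lysis schedule: (frame, channel_index, stack_slot); the cell in that
    #: slot is present up to frame-1 and gone from that frame on
    lysis_schedule: Tuple[Tuple[int, int, int], ...] = ()

    # rendering
    noise_sigma_frac: float = 0.05  # of the cell/background contrast
    illumination_amplitude: float = 10.0
    n_fluo: int = 0
    fluo_background: float = 10.0
    fluo_level_mean: float = 150.0
    fluo_level_sd: float = 20.0
    fluo_noise_sigma: float = 3.0

    seed: int = 0
    area_id: str = "Area01"
    t0: datetime = field(default_factory=lambda: datetime(2017, 10, 16, 12, 0, 0))
    cadence: timedelta = field(default_factory=lambda: timedelta(hours=1))

    def __post_init__(self) -> None:
        if self.pitch <= self.channel_width:
            raise ValueError("pitch must exceed channel_width")
        if min(self.n_channels, self.n_frames) < 1:
            raise ValueError("need at least one channel and one frame")
        if self.channel_length <= 0 or self.channel_width <= 0 or self.cell_width <= 0:
            raise ValueError("all geometry must be positive")

    @property
    def image_shape(self) -> Tuple[int, int]:
        height = int(round(self.channel_length + 2 * self.margin))
        width = int(round(self.n_channels * self.pitch + 2 * self.margin))
        return height, width


@dataclass
class CellRecord:
    """Ground truth for one cell in one frame."""

    cell_id: int
    channel_index: int  # 0-based, left to right
    centroid: Tuple[float, float]  # (row, col)
    length: float
    area: int  # rendered mask pixel count
    fluo_levels: Tuple[float, ...]


@dataclass
class LineageLink:
    """Ground-truth transition into ``frame``: parent -> children."""

    frame: int  # index of the *current* frame of the transition
    parent_id: int
    children: Tuple[int, ...]  # () = lysis, (c,) = no change, (a, b) = division
    event: str  # "nochange" | "division" | "lysis"


@dataclass
class GroundTruth:
    """Per-frame label images, lineage and drift, exact by construction."""

    channel_labels: List[np.ndarray]
    bacteria_labels: List[np.ndarray]
    cells: List[List[CellRecord]]
    links: List[LineageLink]
    shifts: List[Tuple[float, float]]  # per-transition (dy, dx); shifts[0] = (0, 0)
    channel_centroids: List[List[Tuple[float, float]]]
    channel_axis: Tuple[float, float]  # unit (drow, dcol) along the axis, dead end first

    def frame_link_map(self, frame: int) -> Dict[int, LineageLink]:
        """parent_id -> link for the transition into ``frame``."""
        return {l.parent_id: l for l in self.links if l.frame == frame}


class _Cell:
    __slots__ = ("cell_id", "length", "start", "fluo")

    def __init__(self, cell_id: int, length: float, start: float, fluo: Tuple[float, ...]):
        self.cell_id = cell_id
        self.length = length
        self.start = start  # axis distance of the dead-end-side tip from the dead end
        self.fluo = fluo


def _device_coords(shape, offset, angle_deg):
    """Axis (a) and lateral (b) coordinates of every pixel, with the device
    centre at the image centre plus ``offset`` and rotated by ``angle_deg``."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dr = rows - (h / 2.0 + offset[0])
    dc = cols - (w / 2.0 + offset[1])
    theta = np.deg2rad(angle_deg)
    a = dr * np.cos(theta) - dc * np.sin(theta)
    b = dr * np.sin(theta) + dc * np.cos(theta)
    return a, b


def _capsule_mask(a, b, a_centre, b_centre, length, radius):
    """Pixels within ``radius`` of the cell's axis segment."""
    half = max(length / 2.0 - radius, 0.0)
    da = np.clip(a - a_centre, -half, half) - (a - a_centre)
    db = b_centre - b
    return da**2 + db**2 <= radius**2


def generate_series(spec: FixtureSpec) -> Tuple[List[FrameStack], GroundTruth]:
    """Render a synthetic time-lapse and its exact ground truth.

    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    n = spec.n_channels
    lat_centres = [(k - (n - 1) / 2.0) * spec.pitch for k in range(n)]

    # initial cell population
    next_id = 1
    state: List[List[_Cell]] = []
    for k in range(n):
        cells = []
        if spec.initial_lengths is not None:
            lengths = list(spec.initial_lengths[k])
        else:
            lengths = rng.uniform(*spec.initial_length_range, size=spec.cells_per_channel)
        start = spec.dead_end_offset
        for L in lengths:
            fluo = tuple(
                float(np.clip(rng.normal(spec.fluo_level_mean, spec.fluo_level_sd), 0, None))
                for _ in range(spec.n_fluo)
            )
            cells.append(_Cell(next_id, float(L), start, fluo))
            start += float(L) + spec.cell_gap
            next_id += 1
        state.append(cells)

    frames: List[FrameStack] = []
    gt = GroundTruth([], [], [], [], [], [], channel_axis=(0.0, 0.0))
    theta = np.deg2rad(spec.device_angle)
    # axis unit vector in image coords (a increases with rows at angle 0)
    gt.channel_axis = (float(np.cos(theta)), float(-np.sin(theta)))

    offset = np.array([0.0, 0.0])
    for t in range(spec.n_frames):
        if t > 0:
            links: List[LineageLink] = []
            lysed = {(c, s) for (f, c, s) in spec.lysis_schedule if f == t}
            new_state: List[List[_Cell]] = []
            for k, cells in enumerate(state):
                survivors: List[_Cell] = []
                for slot, cell in enumerate(cells):
                    if (k, slot) in lysed:
                        # the lysed cell leaves a persistent gap: cells
                        # nearer the open end do not slide back
                        links.append(LineageLink(t, cell.cell_id, (), "lysis"))
                        continue
                    grown = cell.length + spec.growth_rate
                    if grown >= spec.division_length:
                        child_len = (grown - spec.division_gap) / 2.0
                        kids = [
                            _Cell(next_id, child_len, cell.start, cell.fluo),
                            _Cell(
                                next_id + 1,
                                child_len,
                                cell.start + child_len + spec.division_gap,
                                cell.fluo,
                            ),
                        ]
                        next_id += 2
                        links.append(
                            LineageLink(t, cell.cell_id, (kids[0].cell_id, kids[1].cell_id), "division")
                        )
                        survivors.extend(kids)
                    else:
                        kept = _Cell(cell.cell_id, grown, cell.start, cell.fluo)
                        links.append(LineageLink(t, cell.cell_id, (cell.cell_id,), "nochange"))
                        survivors.append(kept)
                # growth pushes cells toward the open end only: each cell's
                # dead-end-side tip never moves back past its predecessor
                prev_end = spec.dead_end_offset - spec.cell_gap
                kept: List[_Cell] = []
                for cell in survivors:
                    cell.start = max(cell.start, prev_end + spec.cell_gap)
                    prev_end = cell.start + cell.length
                    # cells pushed past the open end leave the stack untracked;
                    # default geometry is chosen so this does not occur
                    if prev_end > spec.channel_length:
                        links = [l for l in links if cell.cell_id not in l.children]
                        continue
                    kept.append(cell)
                new_state.append(kept)
            state = new_state
            gt.links.extend(links)
            offset = offset + np.asarray(spec.drift, dtype=np.float64)
            gt.shifts.append((float(spec.drift[0]), float(spec.drift[1])))
        else:
            gt.shifts.append((0.0, 0.0))

        primary, fluo_planes, chan_labels, bact_labels, cell_records, centroids = _render_frame(
            spec, state, lat_centres, tuple(offset), rng
        )
        frames.append(
            FrameStack(
                primary=primary,
                fluorescence=fluo_planes,
                area_id=spec.area_id,
                timestamp=spec.t0 + t * spec.cadence,
                path=f"{spec.area_id}_t{t:03d}",
            )
        )
        gt.channel_labels.append(chan_labels)
        gt.bacteria_labels.append(bact_labels)
        gt.cells.append(cell_records)
        gt.channel_centroids.append(centroids)

    return frames, gt


def _render_frame(spec, state, lat_centres, offset, rng):
    shape = spec.image_shape
    a, b = _device_coords(shape, offset, spec.device_angle)
    L, w = spec.channel_length, spec.channel_width
    wall = spec.wall_thickness

    chan_labels = np.zeros(shape, dtype=np.int32)
    bact_labels = np.zeros(shape, dtype=np.int32)
    wall_mask = np.zeros(shape, dtype=bool)
    cell_records: List[CellRecord] = []
    centroids: List[Tuple[float, float]] = []

    theta = np.deg2rad(spec.device_angle)
    h2, w2 = shape[0] / 2.0 + offset[0], shape[1] / 2.0 + offset[1]

    for k, bk in enumerate(lat_centres):
        interior = (np.abs(b - bk) <= w / 2.0) & (np.abs(a) <= L / 2.0)
        outline = (
            (np.abs(b - bk) <= w / 2.0 + wall)
            & (a >= -L / 2.0 - wall)
            & (a <= L / 2.0 + wall)
            & ~interior
        )
        chan_labels[interior] = k + 1
        wall_mask |= outline
        # image-coordinate position of the channel centre (a=0, b=bk)
        centroids.append((float(h2 + bk * np.sin(theta)), float(w2 + bk * np.cos(theta))))

        radius = spec.cell_width / 2.0
        for cell in state[k]:
            a_centre = -L / 2.0 + cell.start + cell.length / 2.0
            mask = _capsule_mask(a, b, a_centre, bk, cell.length, radius)
            bact_labels[mask] = cell.cell_id
            rr, cc = np.nonzero(mask)
            if rr.size == 0:
                continue
            cell_records.append(
                CellRecord(
                    cell_id=cell.cell_id,
                    channel_index=k,
                    centroid=(float(rr.mean()), float(cc.mean())),
                    length=cell.length,
                    area=int(rr.size),
                    fluo_levels=cell.fluo,
                )
            )

    cell_mask = bact_labels > 0
    interior_mask = chan_labels > 0

    if spec.modality is Modality.BRIGHTFIELD:
        bg, wall_i, cell_i = 200.0, 120.0, 100.0
        img = np.full(shape, bg)
        img[wall_mask] = wall_i
        img[cell_mask] = cell_i
        contrast = bg - cell_i
    else:
        bg, int_i, wall_i, cell_i = 40.0, 140.0, 190.0, 60.0
        img = np.full(shape, bg)
        img[interior_mask] = int_i
        img[wall_mask] = wall_i
        img[cell_mask] = cell_i
        contrast = int_i - cell_i

    # uneven illumination: linear ramp across columns
    grad = spec.illumination_amplitude * (np.linspace(-0.5, 0.5, shape[1]))[None, :]
    img = img + grad
    img = img + rng.normal(0.0, spec.noise_sigma_frac * contrast, size=shape)
    primary = np.clip(np.round(img), 0, 255).astype(np.uint8)

    fluo_planes = []
    for j in range(spec.n_fluo):
        fluo = np.full(shape, spec.fluo_background)
        for rec in cell_records:
            fluo[bact_labels == rec.cell_id] = rec.fluo_levels[j]
        fluo = fluo + rng.normal(0.0, spec.fluo_noise_sigma, size=shape)
        fluo_planes.append(np.clip(np.round(fluo), 0, 65535).astype(np.uint16))

    return primary, fluo_planes, chan_labels, bact_labels, cell_records, centroids


def ground_truth_channelset(spec: FixtureSpec, gt: GroundTruth, frame: int):
    """Build a ChannelSet from the ground-truth channel labels of one frame
    (used to decouple tracking tests from the detection stage)."""
    from .channels import ChannelInfo, ChannelSet

    labels = gt.channel_labels[frame]
    axis = gt.channel_axis
    infos = [
        ChannelInfo(
            id=k + 1,
            centroid=centroid,
            axis_vector=(axis[0] * spec.channel_length, axis[1] * spec.channel_length),
            width_px=spec.channel_width,
            interpolated=False,
        )
        for k, centroid in enumerate(gt.channel_centroids[frame])
    ]
    return ChannelSet(
        labels=labels.copy(), channels=infos, mean_shape=None, spacing_px=spec.pitch
    )
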