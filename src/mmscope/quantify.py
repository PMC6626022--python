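"""Per-bacterium morphometry and fluorescence quantification.

Length and width are the major and minor axis lengths of the second-
moment ellipse of each cell mask (the standard region-property default;
a skeleton-based geodesic length can be switched on for strongly curved
cells).  Fluorescence is reported as the mean pixel intensity over the
cell mask minus the background, where the background is the mean
fluorescence of the *empty* parts of the same channel in the same frame
— the channel mask minus all detected bacteria.  A fully occupied
channel borrows the pooled empty-area background of the frame's other
channels, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import morphology
from skimage.measure import regionprops

from .bacteria import BacteriaSet, Bacterium
from .channels import ChannelSet
from .tracking import EVENT_LYSIS, EVENT_NEW, TrackGraph

logger = logging.getLogger(__name__)


@dataclass
class MeasurementRecord:
    """One bacterium at one time point."""

    area_id: str
    timestamp: Optional[datetime]
    frame_index: int
    channel_id: int
    bacterium_id: int  # stable global lineage id
    parent_id: Optional[int]
    event: str
    length_px: float
    width_px: float
    area_px: float
    fluorescence: List[Tuple[float, float]] = field(default_factory=list)  # (mean, background)


def measure_regions(bacteria: BacteriaSet, geodesic: bool = False) -> Dict[int, Tuple[float, float, float]]:
    """(length, width, area) per bacterium id.

    Length/width are the moment-ellipse major/minor axis lengths; with
    ``geodesic`` the length is instead the cell's skeleton path length.
    """
    out: Dict[int, Tuple[float, float, float]] = {}
    for b in bacteria.bacteria:
        mask = b.mask.astype(np.uint8)
        props = regionprops(mask)[0]
        length = float(props.axis_major_length)
        width = float(props.axis_minor_length)
        if geodesic:
            skel = morphology.skeletonize(b.mask)
            n = int(skel.sum())
            if n > 1:
                length = float(n)
        if width > length:
            length, width = width, length
        out[b.id] = (length, width, float(b.area))
    return out


def measure_fluorescence(
    bacteria: BacteriaSet,
    channels: ChannelSet,
    fluo_image: np.ndarray,
) -> Dict[int, Tuple[float, float]]:
    """(background-subtracted mean, background) per bacterium id.

    Background = mean fluorescence over the empty pixels of the cell's own
    channel (channel mask minus every bacterium mask of that channel).
    """
    fluo = np.asarray(fluo_image, dtype=np.float64)
    all_cells = np.zeros(fluo.shape, dtype=bool)
    for b in bacteria.bacteria:
        all_cells |= b.mask

    backgrounds: Dict[int, float] = {}
    empties: List[np.ndarray] = []
    for info in channels.channels:
        cid = info.id
        empty = channels.mask_of(cid) & ~all_cells
        if empty.any():
            backgrounds[cid] = float(fluo[empty].mean())
            empties.append(fluo[empty])
    pooled = float(np.concatenate(empties).mean()) if empties else 0.0

    out: Dict[int, Tuple[float, float]] = {}
    for b in bacteria.bacteria:
        bg = backgrounds.get(b.channel_id)
        if bg is None:
            logger.warning(
                "channel %d has no empty pixels; using the frame's pooled background",
                b.channel_id,
            )
            bg = pooled
        mean = float(fluo[b.mask].mean()) - bg
        out[b.id] = (mean, bg)
    return out


def build_lineage_table(
    graph: TrackGraph,
    per_frame: Sequence[dict],
) -> List[MeasurementRecord]:
    """Assemble the lineage-resolved measurement table.

    ``per_frame[t]`` holds that frame's context: keys ``bacteria``
    (BacteriaSet), ``morphometry`` (id -> (length, width, area)),
    ``fluorescence`` (list, one dict id -> (mean, background) per
    fluorophore), ``area_id``, ``timestamp``.  Every graph node must have
    a measurement; an orphan measurement (bacterium absent from the
    graph) raises.
    """
    records: List[MeasurementRecord] = []
    node_by_frame_label: Dict[Tuple[int, int], Tuple] = {}
    for node in graph.graph.nodes:
        frame, channel_id, label = node
        node_by_frame_label[(frame, label)] = node

    for t, ctx in enumerate(per_frame):
        bacteria: BacteriaSet = ctx["bacteria"]
        morpho = ctx["morphometry"]
        fluo_tables = ctx.get("fluorescence", [])
        for b in bacteria.bacteria:
            node = node_by_frame_label.get((t, b.id))
            if node is None:
                raise ValueError(
                    f"measurement for frame {t}, bacterium label {b.id} has no lineage node"
                )
            data = graph.graph.nodes[node]
            parent = graph.parent_of(node)
            parent_id = graph.global_id(parent) if parent is not None else None
            event = data.get("event", EVENT_NEW)
            if data.get("fate") == EVENT_LYSIS:
                event = EVENT_LYSIS
            length, width, area = morpho[b.id]
            records.append(
                MeasurementRecord(
                    area_id=ctx.get("area_id", ""),
                    timestamp=ctx.get("timestamp"),
                    frame_index=t,
                    channel_id=b.channel_id,
                    bacterium_id=graph.global_id(node),
                    parent_id=parent_id,
                    event=event,
                    length_px=length,
                    width_px=width,
                    area_px=area,
                    fluorescence=[table[b.id] for table in fluo_tables],
                )
            )
    records.sort(key=lambda r: (r.bacterium_id, r.frame_index))
    return records
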