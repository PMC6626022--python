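"""End-to-end orchestration: frames in, lineage-resolved table out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bacteria import BacteriaSet, detect_bacteria
from .channels import ChannelSet, FrameRejected, detect_channels
from .config import PipelineConfig
from .io import FrameStack
from .modality import Modality, classify_modality, vote_modality
from .quantify import (
    MeasurementRecord,
    build_lineage_table,
    measure_fluorescence,
    measure_regions,
)
from .tracking import (
    EVENT_NEW,
    FrameShift,
    TrackGraph,
    estimate_frame_shift,
    track_bacteria,
    track_channels,
)

logger = logging.getLogger(__name__)


@dataclass
class SeriesResult:
    """Everything the pipeline produced for one imaging area."""

    records: List[MeasurementRecord]
    graph: TrackGraph
    modality: Modality
    channels: List[Optional[ChannelSet]]  # None = rejected frame
    bacteria: List[Optional[BacteriaSet]]
    shifts: List[Optional[FrameShift]]


def _relabel_channels(curr: ChannelSet, mapping: Dict[int, int], next_free: int) -> int:
    """Rename current channel ids to their matched previous ids in place.

    ``mapping`` is previous id -> current id.  Unmatched current channels
    get fresh ids starting at ``next_free``; returns the new next_free.
    """
    inverse = {c: p for p, c in mapping.items()}
    old_labels = curr.labels.copy()
    new_labels = np.zeros_like(old_labels)
    for info in curr.channels:
        old = info.id
        if old in inverse:
            new = inverse[old]
        else:
            new = next_free
            next_free += 1
        new_labels[old_labels == old] = new
        info.id = new
    curr.labels = new_labels
    return next_free


def analyze_series(
    frames: Sequence[FrameStack],
    config: PipelineConfig | None = None,
    modality: Optional[Modality] = None,
) -> SeriesResult:
    """Run detection, tracking and quantification over one time series.

    Frames in which fewer than three channels are detected are skipped
    with a warning; tracking then links the surrounding accepted frames.
    The imaging modality is auto-detected per frame and decided by
    majority vote unless given explicitly.
    """
    config = config or PipelineConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to analyse")

    if modality is None:
        modality = vote_modality(classify_modality(f.primary) for f in frames)

    graph = TrackGraph()
    channel_sets: List[Optional[ChannelSet]] = []
    bacteria_sets: List[Optional[BacteriaSet]] = []
    shifts: List[Optional[FrameShift]] = []
    per_frame_ctx: List[dict] = []

    prev_idx: Optional[int] = None
    next_channel_id = 1

    for t, frame in enumerate(frames):
        try:
            channels = detect_channels(frame.primary, modality, config)
        except FrameRejected as exc:
            logger.warning("frame %d rejected: %s", t, exc)
            channel_sets.append(None)
            bacteria_sets.append(None)
            shifts.append(None)
            per_frame_ctx.append(
                {"bacteria": BacteriaSet(labels={}, bacteria=[]), "morphometry": {},
                 "fluorescence": [], "area_id": frame.area_id, "timestamp": frame.timestamp}
            )
            continue

        if prev_idx is None:
            next_channel_id = max((c.id for c in channels.channels), default=0) + 1
            shift = None
        else:
            prev_frame = frames[prev_idx]
            shift = estimate_frame_shift(prev_frame.primary, frame.primary, config)
            mapping = track_channels(channel_sets[prev_idx], channels, shift)
            next_channel_id = _relabel_channels(channels, mapping, next_channel_id)

        bacteria = detect_bacteria(frame, channels, config)

        if prev_idx is None:
            for b in bacteria.bacteria:
                graph.add_root(t, b.channel_id, b.id, EVENT_NEW)
        else:
            identity_map = {
                info.id: info.id
                for info in channels.channels
                if any(p.id == info.id for p in channel_sets[prev_idx].channels)
            }
            track_bacteria(
                bacteria_sets[prev_idx],
                bacteria,
                identity_map,
                channel_sets[prev_idx],
                channels,
                graph,
                prev_idx,
                t,
                shift,
                config,
            )
            # cells of the current frame in channels that were not matched
            tracked = {n[2] for n in graph.nodes_of_frame(t)}
            for b in bacteria.bacteria:
                if b.id not in tracked:
                    graph.add_root(t, b.channel_id, b.id, EVENT_NEW)

        morpho = measure_regions(bacteria)
        fluo_tables = [
            measure_fluorescence(bacteria, channels, plane) for plane in frame.fluorescence
        ]
        channel_sets.append(channels)
        bacteria_sets.append(bacteria)
        shifts.append(shift)
        per_frame_ctx.append(
            {
                "bacteria": bacteria,
                "morphometry": morpho,
                "fluorescence": fluo_tables,
                "area_id": frame.area_id,
                "timestamp": frame.timestamp,
            }
        )
        prev_idx = t

    records = build_lineage_table(graph, per_frame_ctx)
    return SeriesResult(
        records=records,
        graph=graph,
        modality=modality,
        channels=channel_sets,
        bacteria=bacteria_sets,
        shifts=shifts,
    )
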