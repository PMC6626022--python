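"""Channel and bacteria tracking across consecutive frames.

Tracking has two stages.  First the rigid inter-frame drift of the whole
field of view is estimated by cross-correlation template matching; the
shift-corrected channel centroids of consecutive frames are then linked
by mutual nearest neighbours (two channels match only if each is the
other's closest counterpart).

Within each tracked channel the bacteria are linked by multiple-
hypothesis scoring.  Between two frames each previous bacterium either
persists (no change), fades away (lysis) or divides one or more times;
new cells may enter only at the channel's open end, and assignments never
cross along the channel axis, because cells cannot pass one another in a
mother-machine channel.  Every order-preserving combination of events
consistent with the observed cell count is enumerated and scored as a
product of per-bacterium terms: a Gaussian penalty on the relative area
change between a cell and its offspring (normalised by the number of
divisions), a Gaussian penalty on the centroid displacement (each
division is expected to displace centroids by half an average bacterium
length), and the prior probability of the event itself.  The highest-
probability combination relabels the current frame: persisting cells keep
their global lineage id, offspring and newcomers get fresh ids.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from skimage.registration import phase_cross_correlation

from .bacteria import BacteriaSet, Bacterium
from .channels import ChannelSet
from .config import PipelineConfig

logger = logging.getLogger(__name__)

EVENT_NO_CHANGE = "no-change"
EVENT_DIVISION = "division"
EVENT_LYSIS = "lysis-terminal"
EVENT_NEW = "new-root"


@dataclass(frozen=True)
class FrameShift:
    """Rigid drift between two frames: a feature at (r, c) in the previous
    frame appears at (r + dy, c + dx) in the current one."""

    dy: float
    dx: float
    peak_correlation: float


@dataclass
class TrackingParams:
    """Priors and model scales of the hypothesis scoring."""

    p_no_change: float = 0.90
    p_division: float = 0.07
    p_lysis: float = 0.03
    mean_bacterium_length: float = 30.0
    area_sigma: float = 0.2
    centroid_sigma: Optional[float] = None  # default: mean_bacterium_length / 2

    @classmethod
    def from_config(cls, config: PipelineConfig, mean_length: float) -> "TrackingParams":
        return cls(
            p_no_change=config.p_no_change,
            p_division=config.p_division,
            p_lysis=config.p_lysis,
            mean_bacterium_length=mean_length,
            area_sigma=config.area_sigma,
            centroid_sigma=config.centroid_sigma,
        )

    @property
    def sigma_c(self) -> float:
        return self.centroid_sigma if self.centroid_sigma is not None else self.mean_bacterium_length / 2.0


@dataclass(frozen=True)
class EventHypothesis:
    """One combination of events mapping previous to current bacteria.

    ``assignment[i]`` is the tuple of current-frame indices assigned to
    previous bacterium i (ordered along the channel): () = lysis,
    one index = no change, 2**m indices = m successive divisions.
    Current indices absent from every assignment are new cells at the
    open end.
    """

    assignment: Tuple[Tuple[int, ...], ...]
    new: Tuple[int, ...]
    n_divisions: int
    probability: float = 0.0

    def events(self) -> Tuple[str, ...]:
        out = []
        for children in self.assignment:
            if len(children) == 0:
                out.append(EVENT_LYSIS)
            elif len(children) == 1:
                out.append(EVENT_NO_CHANGE)
            else:
                out.append(EVENT_DIVISION)
        return tuple(out)


def estimate_frame_shift(
    prev_image: np.ndarray,
    curr_image: np.ndarray,
    config: PipelineConfig | None = None,
) -> FrameShift:
    """Whole-image rigid shift by cross-correlation template matching.

    The returned peak value is the normalised correlation coefficient of
    the two images at the estimated shift; below the configured floor the
    shift falls back to (0, 0) with a warning.
    """
    config = config or PipelineConfig()
    a = np.asarray(prev_image, dtype=np.float64)
    b = np.asarray(curr_image, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must share one shape")
    shift, _, _ = phase_cross_correlation(b, a, normalization=None)
    dy, dx = float(shift[0]), float(shift[1])
    peak = _normalised_correlation(a, b, int(round(dy)), int(round(dx)))
    if peak < config.min_peak_correlation:
        logger.warning(
            "frame-shift correlation peak %.3f below floor %.3f; assuming no drift",
            peak,
            config.min_peak_correlation,
        )
        return FrameShift(0.0, 0.0, peak)
    return FrameShift(dy, dx, peak)


def _normalised_correlation(a: np.ndarray, b: np.ndarray, dy: int, dx: int) -> float:
    """Pearson correlation of the overlap of ``a`` and ``b`` shifted by (dy, dx)."""
    h, w = a.shape
    ar0, ar1 = max(0, -dy), min(h, h - dy)
    ac0, ac1 = max(0, -dx), min(w, w - dx)
    if ar0 >= ar1 or ac0 >= ac1:
        return 0.0
    sub_a = a[ar0:ar1, ac0:ac1]
    sub_b = b[ar0 + dy : ar1 + dy, ac0 + dx : ac1 + dx]
    sa, sb = sub_a.std(), sub_b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((sub_a - sub_a.mean()) * (sub_b - sub_b.mean())) / (sa * sb))


def track_channels(
    prev: ChannelSet,
    curr: ChannelSet,
    shift: FrameShift,
) -> Dict[int, int]:
    """Mutual-nearest-neighbour matching of shift-corrected centroids.

    Returns previous channel id -> current channel id; channels without a
    mutual nearest neighbour on the other side stay unmatched.
    """
    if len(prev) == 0 or len(curr) == 0:
        return {}
    prev_pts = np.array([c.centroid for c in prev.channels]) + np.array([shift.dy, shift.dx])
    curr_pts = np.array([c.centroid for c in curr.channels])
    d = np.linalg.norm(prev_pts[:, None, :] - curr_pts[None, :, :], axis=-1)
    nn_of_prev = np.argmin(d, axis=1)
    nn_of_curr = np.argmin(d, axis=0)
    mapping: Dict[int, int] = {}
    for i, j in enumerate(nn_of_prev):
        if nn_of_curr[j] == i:
            mapping[prev.channels[i].id] = curr.channels[int(j)].id
    return mapping


def enumerate_hypotheses(
    n_prev,
    n_curr,
    division_cap: int = 2,
) -> List[EventHypothesis]:
    """All order-preserving event combinations for one channel.

    Each previous bacterium (ordered from the dead end) lyses, persists,
    or divides m times (producing 2**m consecutive current cells,
    m <= division_cap); leftover current cells are new entries at the open
    end.  The per-cell division cap bounds the combinatorics; exceeding
    hypotheses are simply not generated.
    """
    n_prev = n_prev if isinstance(n_prev, (int, np.integer)) else len(n_prev)
    n_curr = n_curr if isinstance(n_curr, (int, np.integer)) else len(n_curr)
    options: List[Tuple[int, int]] = [(0, 0), (1, 0)]  # (n_children, n_div)
    options += [(2**m, m) for m in range(1, division_cap + 1)]
    out: List[EventHypothesis] = []
    for combo in itertools.product(options, repeat=n_prev):
        total = sum(c for c, _ in combo)
        if total > n_curr:
            continue
        n_new = n_curr - total
        assignment: List[Tuple[int, ...]] = []
        cursor = 0
        for c, _ in combo:
            assignment.append(tuple(range(cursor, cursor + c)))
            cursor += c
        new = tuple(range(cursor, n_curr))
        out.append(
            EventHypothesis(
                assignment=tuple(assignment),
                new=new,
                n_divisions=sum(m for _, m in combo),
            )
        )
    return out


def _axis_position(b: Bacterium, origin: np.ndarray, axis_unit: np.ndarray) -> float:
    return float(np.dot(np.asarray(b.centroid) - origin, axis_unit))


def score_hypothesis(
    h: EventHypothesis,
    prev: Sequence[Bacterium],
    curr: Sequence[Bacterium],
    params: TrackingParams,
    shift: Tuple[float, float] = (0.0, 0.0),
) -> float:
    """Probability of one event combination.

    Per previous bacterium the term is p_area * p_centroid * p_event:
    p_area penalises the relative deviation of the children's total area
    from the parent's (taken to the 1/n_div power for divisions, a
    per-division geometric mean); p_centroid penalises the deviation of
    the mean child displacement from the expected n_div * L/2, where L is
    the average bacterium length; p_event is the prior.  The hypothesis
    probability is the product over bacteria.  Lysed cells contribute
    their prior only; new cells contribute no term.
    """
    prob = 1.0
    offset = np.asarray(shift, dtype=np.float64)
    for i, children in enumerate(h.assignment):
        parent = prev[i]
        if len(children) == 0:
            prob *= params.p_lysis
            continue
        kids = [curr[j] for j in children]
        n_div = int(math.log2(len(children))) if len(children) > 1 else 0
        total_area = sum(k.area for k in kids)
        rel = total_area / parent.area - 1.0
        p_area = math.exp(-0.5 * (rel / params.area_sigma) ** 2)
        if n_div > 0:
            p_area = p_area ** (1.0 / n_div)
        parent_pos = np.asarray(parent.centroid) + offset
        disp = float(np.mean([np.linalg.norm(np.asarray(k.centroid) - parent_pos) for k in kids]))
        expected = n_div * params.mean_bacterium_length / 2.0
        p_centroid = math.exp(-0.5 * ((disp - expected) / params.sigma_c) ** 2)
        p_event = params.p_no_change if n_div == 0 else params.p_division**n_div
        prob *= p_area * p_centroid * p_event
    return prob


class TrackGraph:
    """Lineage across frames.

    Nodes are (frame_index, channel_id, bacterium_label); each carries a
    stable global lineage id.  Edges carry the event that links a parent
    node to a child node; lysis and new-cell events are recorded as node
    attributes (a lysed node has no outgoing edge, a new cell no incoming
    edge).
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._next_global = 1

    def _new_global_id(self) -> int:
        gid = self._next_global
        self._next_global += 1
        return gid

    def add_root(self, frame: int, channel_id: int, label: int, event: str = EVENT_NEW) -> int:
        gid = self._new_global_id()
        self.graph.add_node((frame, channel_id, label), global_id=gid, event=event)
        return gid

    def add_child(
        self, parent: Tuple[int, int, int], frame: int, channel_id: int, label: int, event: str
    ) -> int:
        if event == EVENT_NO_CHANGE:
            gid = self.graph.nodes[parent]["global_id"]
        else:
            gid = self._new_global_id()
        node = (frame, channel_id, label)
        self.graph.add_node(node, global_id=gid, event=event)
        self.graph.add_edge(parent, node, event=event)
        return gid

    def mark_lysis(self, node: Tuple[int, int, int]) -> None:
        self.graph.nodes[node]["fate"] = EVENT_LYSIS

    def global_id(self, node: Tuple[int, int, int]) -> int:
        return self.graph.nodes[node]["global_id"]

    def nodes_of_frame(self, frame: int):
        return [n for n in self.graph.nodes if n[0] == frame]

    def parent_of(self, node: Tuple[int, int, int]):
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None


def _ordered(bacteria: Sequence[Bacterium], channel, config: PipelineConfig) -> List[Bacterium]:
    """Order a channel's bacteria dead-end first along the channel axis."""
    axis = np.asarray(channel.axis_vector, dtype=np.float64)
    norm = np.linalg.norm(axis)
    unit = axis / norm if norm else np.array([1.0, 0.0])
    origin = np.asarray(channel.centroid)
    keyed = sorted(bacteria, key=lambda b: _axis_position(b, origin, unit))
    if config.dead_end == "high":
        keyed.reverse()
    return keyed


def _hypothesis_sort_key(h: EventHypothesis):
    n_events = sum(1 for ch in h.assignment if len(ch) != 1)  # non-trivial events
    return (-h.probability, n_events, h.n_divisions, h.assignment)


def best_hypothesis(
    prev: Sequence[Bacterium],
    curr: Sequence[Bacterium],
    params: TrackingParams,
    shift: Tuple[float, float] = (0.0, 0.0),
    division_cap: int = 2,
) -> EventHypothesis:
    """Score every hypothesis and return the most probable one.

    Ties break deterministically: fewest non-trivial events, then fewest
    divisions, then lexicographically smallest assignment.
    """
    hyps = enumerate_hypotheses(len(prev), len(curr), division_cap)
    scored = [
        EventHypothesis(h.assignment, h.new, h.n_divisions, score_hypothesis(h, prev, curr, params, shift))
        for h in hyps
    ]
    scored.sort(key=_hypothesis_sort_key)
    return scored[0]


def track_bacteria(
    prev_bacteria: BacteriaSet,
    curr_bacteria: BacteriaSet,
    channel_map: Dict[int, int],
    prev_channels: ChannelSet,
    curr_channels: ChannelSet,
    graph: TrackGraph,
    prev_frame: int,
    curr_frame: int,
    shift: FrameShift,
    config: PipelineConfig | None = None,
) -> None:
    """Apply the most probable event combination in every tracked channel.

    Persisting cells keep their global lineage id; division children and
    newcomers get fresh ids; lysed tracks are marked terminal.  Bacteria
    in unmatched channels are left untracked for this transition.
    """
    config = config or PipelineConfig()
    curr_by_id = {c.id: c for c in curr_channels.channels}
    prev_by_id = {c.id: c for c in prev_channels.channels}

    # "average bacterium" = median length over the previous frame's cells,
    # using the bounding-box extent as a cheap rod-length proxy
    est_lengths = []
    for b in prev_bacteria.bacteria:
        rr, cc = np.nonzero(b.mask)
        est_lengths.append(float(max(rr.max() - rr.min(), cc.max() - cc.min()) + 1))
    mean_len = float(np.median(est_lengths)) if est_lengths else 30.0
    params = TrackingParams.from_config(config, mean_len)

    for pcid, ccid in channel_map.items():
        prev_ch = prev_by_id.get(pcid)
        curr_ch = curr_by_id.get(ccid)
        if prev_ch is None or curr_ch is None:
            continue
        prev_list = _ordered(prev_bacteria.in_channel(pcid), prev_ch, config)
        curr_list = _ordered(curr_bacteria.in_channel(ccid), curr_ch, config)
        if not prev_list and not curr_list:
            continue
        if not prev_list:
            for b in curr_list:
                graph.add_root(curr_frame, ccid, b.id, EVENT_NEW)
            continue
        hyp = best_hypothesis(
            prev_list, curr_list, params, (shift.dy, shift.dx), config.division_cap
        )
        for i, children in enumerate(hyp.assignment):
            parent_node = (prev_frame, pcid, prev_list[i].id)
            if parent_node not in graph.graph:
                graph.add_root(prev_frame, pcid, prev_list[i].id, EVENT_NEW)
            if len(children) == 0:
                graph.mark_lysis(parent_node)
                continue
            event = EVENT_NO_CHANGE if len(children) == 1 else EVENT_DIVISION
            for j in children:
                graph.add_child(parent_node, curr_frame, ccid, curr_list[j].id, event)
        for j in hyp.new:
            graph.add_root(curr_frame, ccid, curr_list[j].id, EVENT_NEW)
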