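import itertools

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

from mmscope.bacteria import Bacterium
from mmscope.config import PipelineConfig
from mmscope.pipeline import analyze_series
from mmscope.synthetic import FixtureSpec, generate_series, ground_truth_channelset
from mmscope.tracking import (
    EVENT_DIVISION,
    EVENT_LYSIS,
    EVENT_NO_CHANGE,
    FrameShift,
    TrackingParams,
    best_hypothesis,
    enumerate_hypotheses,
    estimate_frame_shift,
    score_hypothesis,
    track_channels,
)


def brute_force_hypotheses(n_prev, n_curr, cap=2):
    """Independent oracle: enumerate raw per-cell event strings and build
    the implied order-preserving assignments."""
    options = [0, 1] + [2**m for m in range(1, cap + 1)]  # children counts
    out = set()
    for counts in itertools.product(options, repeat=n_prev):
        if sum(counts) > n_curr:
            continue
        cursor = 0
        assignment = []
        for c in counts:
            assignment.append(tuple(range(cursor, cursor + c)))
            cursor += c
        out.add((tuple(assignment), tuple(range(cursor, n_curr))))
    return out


def make_bact(idx, row, area=200, channel=1):
    mask = np.zeros((1, 1), dtype=bool)
    return Bacterium(id=idx, channel_id=channel, centroid=(row, 10.0), area=area, mask=mask)


class TestFrameShift:
    def test_identical_frames_give_zero(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (64, 64))
        s = estimate_frame_shift(img, img)
        assert (s.dy, s.dx) == (0.0, 0.0)
        assert s.peak_correlation == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("dy,dx", [(0, -12), (7, 3), (-15, 15)])
    def test_known_translation_recovered_exactly(self, dy, dx):
        spec = FixtureSpec(seed=11, n_frames=1, noise_sigma_frac=0.0)
        frames, _ = generate_series(spec)
        img = frames[0].primary.astype(float)
        moved = nd_shift(img, (dy, dx), order=0, mode="nearest")
        s = estimate_frame_shift(img, moved)
        assert (s.dy, s.dx) == (dy, dx)

    def test_unrelated_noise_falls_back_to_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (64, 64))
        b = rng.normal(0, 1, (64, 64))
        s = estimate_frame_shift(a, b)
        assert (s.dy, s.dx) == (0.0, 0.0)
        assert s.peak_correlation < 0.3


class TestTrackChannels:
    def _channelset(self, cols):
        from mmscope.channels import ChannelInfo, ChannelSet

        infos = [
            ChannelInfo(id=i + 1, centroid=(100.0, float(c)), axis_vector=(150.0, 0.0), width_px=12.0)
            for i, c in enumerate(cols)
        ]
        return ChannelSet(labels=np.zeros((1, 1), np.int32), channels=infos,
                          mean_shape=None, spacing_px=40.0)

    def test_identical_centroids_identity_map(self):
        prev = self._channelset([0, 100, 200])
        curr = self._channelset([0, 100, 200])
        assert track_channels(prev, curr, FrameShift(0, 0, 1.0)) == {1: 1, 2: 2, 3: 3}

    def test_mutual_nearest_neighbour_example(self):
        prev = self._channelset([0, 100])
        curr = self._channelset([5, 98])
        mapping = track_channels(prev, curr, FrameShift(0, 0, 1.0))
        assert mapping == {1: 1, 2: 2}  # 0->5, 100->98

    def test_missing_channel_leaves_others_unaffected(self):
        prev = self._channelset([0, 100, 200])
        curr = self._channelset([0, 200])
        mapping = track_channels(prev, curr, FrameShift(0, 0, 1.0))
        assert mapping == {1: 1, 3: 2}

    def test_shift_correction_applied_before_matching(self):
        prev = self._channelset([0, 40, 80])
        curr = self._channelset([20, 60, 100])
        mapping = track_channels(prev, curr, FrameShift(0.0, 20.0, 1.0))
        assert mapping == {1: 1, 2: 2, 3: 3}


class TestEnumerateHypotheses:
    @pytest.mark.parametrize("n_prev,n_curr", [(p, c) for p in range(4) for c in range(4)])
    def test_matches_brute_force_oracle(self, n_prev, n_curr):
        got = {(h.assignment, h.new) for h in enumerate_hypotheses(n_prev, n_curr)}
        assert got == brute_force_hypotheses(n_prev, n_curr)

    def test_one_to_one_includes_no_change_and_lysis_plus_new(self):
        hyps = {(h.assignment, h.new) for h in enumerate_hypotheses(1, 1)}
        assert hyps == {(((0,),), ()), (((),), (0,))}

    def test_one_to_two_includes_single_division(self):
        assignments = [h.assignment for h in enumerate_hypotheses(1, 2)]
        assert ((0, 1),) in assignments

    def test_two_to_one_includes_both_lysis_orders(self):
        hyps = {h.assignment for h in enumerate_hypotheses(2, 1)}
        assert ((), (0,)) in hyps
        assert ((0,), ()) in hyps

    def test_division_counts_recorded(self):
        by_assignment = {h.assignment: h.n_divisions for h in enumerate_hypotheses(1, 4)}
        assert by_assignment[((0, 1, 2, 3),)] == 2


class TestScoreHypothesis:
    def _params(self):
        return TrackingParams(mean_bacterium_length=30.0)

    def test_identical_frames_no_change_scores_highest(self):
        prev = [make_bact(1, 50.0), make_bact(2, 90.0)]
        curr = [make_bact(1, 50.0), make_bact(2, 90.0)]
        params = self._params()
        hyps = enumerate_hypotheses(2, 2)
        scores = {
            h.assignment: score_hypothesis(h, prev, curr, params) for h in hyps
        }
        best = max(scores, key=scores.get)
        assert best == ((0,), (1,))
        assert all(0 < s <= 1 for s in scores.values())

    def test_clean_division_beats_lysis_plus_new(self):
        prev = [make_bact(1, 50.0, area=200)]
        curr = [make_bact(1, 42.0, area=100), make_bact(2, 58.0, area=100)]
        params = self._params()
        hyps = {h.assignment: h for h in enumerate_hypotheses(1, 2)}
        division = score_hypothesis(hyps[((0, 1),)], prev, curr, params)
        lysis_new = score_hypothesis(hyps[((),)], prev, curr, params)
        assert division > lysis_new

    def test_probability_in_unit_interval(self):
        rng = np.random.default_rng(5)
        params = self._params()
        for _ in range(50):
            n_prev, n_curr = rng.integers(1, 4), rng.integers(0, 4)
            prev = [make_bact(i + 1, float(r), int(a))
                    for i, (r, a) in enumerate(zip(np.sort(rng.uniform(0, 150, n_prev)),
                                                   rng.uniform(100, 400, n_prev)))]
            curr = [make_bact(i + 1, float(r), int(a))
                    for i, (r, a) in enumerate(zip(np.sort(rng.uniform(0, 150, n_curr)),
                                                   rng.uniform(100, 400, n_curr)))]
            for h in enumerate_hypotheses(n_prev, n_curr):
                p = score_hypothesis(h, prev, curr, params)
                assert 0 < p <= 1


class TestBestHypothesis:
    def test_deterministic_tie_break_prefers_fewest_events(self):
        # zero-area symmetric situation engineered so several hypotheses tie
        prev = [make_bact(1, 50.0)]
        curr = [make_bact(1, 50.0)]
        h = best_hypothesis(prev, curr, TrackingParams(mean_bacterium_length=30.0))
        assert h.assignment == ((0,),)


class TestTrackBacteriaEndToEnd:
    def _links_from_graph(self, graph):
        """(frame_to, parent_gid, children_gids, event) for every transition."""
        links = []
        for parent, child, data in graph.graph.edges(data=True):
            links.append((child[0], graph.global_id(parent), graph.global_id(child), data["event"]))
        return links

    def test_static_series_tracks_are_straight_chains(self):
        spec = FixtureSpec(seed=21, n_channels=3, n_frames=5, growth_rate=0.0)
        frames, gt = generate_series(spec)
        res = analyze_series(frames)
        per_frame = {}
        for node, data in res.graph.graph.nodes(data=True):
            per_frame.setdefault(node[0], []).append(data)
        n0 = len(per_frame[0])
        for t in range(1, 5):
            assert len(per_frame[t]) == n0
            assert all(d["event"] == EVENT_NO_CHANGE for d in per_frame[t])
        gids = {d["global_id"] for t in per_frame for d in per_frame[t]}
        assert len(gids) == n0

    def test_programmed_division_found_at_right_frame(self, lineage_series):
        spec, frames, gt = lineage_series
        res = analyze_series(frames)
        division_edges = [
            (parent, child)
            for parent, child, data in res.graph.graph.edges(data=True)
            if data["event"] == EVENT_DIVISION
        ]
        assert len(division_edges) == 2  # one division, two offspring
        assert all(child[0] == 3 for _, child in division_edges)
        parents = {parent for parent, _ in division_edges}
        assert len(parents) == 1

    def test_programmed_lysis_terminates_track(self, lineage_series):
        spec, frames, gt = lineage_series
        res = analyze_series(frames)
        lysed = [
            node
            for node, data in res.graph.graph.nodes(data=True)
            if data.get("fate") == EVENT_LYSIS
        ]
        assert len(lysed) == 1
        node = lysed[0]
        assert node[0] == 4  # last frame where the lysing cell is present
        assert list(res.graph.graph.successors(node)) == []
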