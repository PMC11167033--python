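"""Linking, gap closing and trajectory statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from caftrack.tracking import (
    LinkingParams,
    Track,
    build_tracklets,
    close_gaps,
    link_frame_pair,
    trajectory_stats,
)

from conftest import spot


def brute_force_matching(pa, pb, cap):
    """Enumerate all partial matchings; return (max cardinality,
    minimal total squared distance at that cardinality)."""
    na, nb = len(pa), len(pb)
    best = (0, 0.0)
    idx_b = list(range(nb))
    for k in range(min(na, nb), -1, -1):
        found_cost = None
        for sub_a in itertools.combinations(range(na), k):
            for sub_b in itertools.permutations(idx_b, k):
                cost = 0.0
                ok = True
                for i, j in zip(sub_a, sub_b):
                    d2 = (pa[i][0] - pb[j][0]) ** 2 + (pa[i][1] - pb[j][1]) ** 2
                    if d2 > cap**2 + 1e-9:
                        ok = False
                        break
                    cost += d2
                if ok and (found_cost is None or cost < found_cost):
                    found_cost = cost
        if found_cost is not None:
            return (k, found_cost)
    return best


class TestLinkFramePair:
    def test_empty_inputs(self):
        assert link_frame_pair([], [spot(1, 0, 0)], 36.0, 1.0) == []
        assert link_frame_pair([spot(0, 0, 0)], [], 36.0, 1.0) == []

    def test_distance_cap_excludes_far_pair(self):
        a = [spot(0, 0.0, 0.0)]
        b = [spot(1, 40.0, 0.0)]
        assert link_frame_pair(a, b, 36.0, 1.0) == []

    def test_boundary_distance_is_linked(self):
        a = [spot(0, 0.0, 0.0)]
        b = [spot(1, 36.0, 0.0)]
        assert link_frame_pair(a, b, 36.0, 1.0) == [(0, 0)]

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        na, nb = rng.integers(0, 6, size=2)
        pa = rng.uniform(0, 50, size=(na, 2))
        pb = rng.uniform(0, 50, size=(nb, 2))
        cap = 15.0
        links = link_frame_pair(
            [spot(0, x, y) for x, y in pa], [spot(1, x, y) for x, y in pb], cap, 1.0
        )
        cost = sum(
            (pa[i][0] - pb[j][0]) ** 2 + (pa[i][1] - pb[j][1]) ** 2 for i, j in links
        )
        k_star, cost_star = brute_force_matching(pa, pb, cap)
        assert len(links) == k_star
        assert cost == pytest.approx(cost_star, abs=1e-9)


class TestBuildTracklets:
    def test_stationary_spot_single_tracklet(self):
        det = {f: [spot(f, 10, 10)] for f in range(10)}
        tracks = build_tracklets(det, LinkingParams(), 1.0)
        assert len(tracks) == 1
        assert len(tracks[0].spots) == 10

    def test_far_spots_stay_separate(self):
        det = {f: [spot(f, 0, 0), spot(f, 200, 200)] for f in range(5)}
        tracks = build_tracklets(det, LinkingParams(link_max_um=36.0), 1.0)
        assert len(tracks) == 2

    def test_every_detection_in_exactly_one_tracklet(self):
        rng = np.random.default_rng(5)
        det = {
            f: [spot(f, x, y) for x, y in rng.uniform(0, 300, size=(8, 2))]
            for f in range(6)
        }
        tracks = build_tracklets(det, LinkingParams(), 1.0)
        n_total = sum(len(v) for v in det.values())
        seen = [(s.frame, s.x_px, s.y_px) for t in tracks for s in t.spots]
        assert len(seen) == n_total
        assert len(set(seen)) == n_total


class TestCloseGaps:
    def _fragments(self, gap_frames, dist):
        t1 = Track(0, [spot(f, 10.0, 10.0) for f in range(5)])
        start = 5 + gap_frames
        t2 = Track(
            1, [spot(f, 10.0 + dist, 10.0) for f in range(start, start + 5)]
        )
        return [t1, t2]

    def test_five_frame_gap_ten_um_is_bridged(self):
        merged = close_gaps(self._fragments(5, 10.0), LinkingParams(), 1.0)
        assert len(merged) == 1
        assert len(merged[0].spots) == 10
        assert sum(merged[0].gap_closed) == 1

    def test_six_frame_gap_not_bridged(self):
        merged = close_gaps(self._fragments(6, 10.0), LinkingParams(), 1.0)
        assert len(merged) == 2

    def test_distance_above_cap_not_bridged(self):
        merged = close_gaps(self._fragments(3, 12.5), LinkingParams(), 1.0)
        assert len(merged) == 2

    def test_nearest_candidate_start_wins(self):
        end = Track(0, [spot(f, 0.0, 0.0) for f in range(3)])
        near = Track(1, [spot(5, 3.0, 0.0), spot(6, 3.0, 0.0)])
        far = Track(2, [spot(5, 8.0, 0.0), spot(6, 8.0, 0.0)])
        merged = close_gaps([end, far, near], LinkingParams(), 1.0)
        by_len = sorted(merged, key=lambda t: -len(t.spots))
        assert len(merged) == 2
        assert [s.x_px for s in by_len[0].spots] == [0.0, 0.0, 0.0, 3.0, 3.0]

    def test_never_increases_track_count(self, rng):
        tracklets = []
        for i in range(12):
            f0 = int(rng.integers(0, 20))
            x, y = rng.uniform(0, 100, size=2)
            tracklets.append(
                Track(i, [spot(f0 + k, x + k, y) for k in range(int(rng.integers(1, 5)))])
            )
        merged = close_gaps(tracklets, LinkingParams(), 1.0)
        assert len(merged) <= len(tracklets)
        n_in = sum(len(t.spots) for t in tracklets)
        assert sum(len(t.spots) for t in merged) == n_in


class TestTrajectoryStats:
    def test_stationary_track(self):
        tr = Track(0, [spot(f, 5, 5) for f in range(4)])
        st = trajectory_stats(tr, 1.0, 5.0)
        assert st.path_length_um == 0.0
        assert st.net_displacement_um == 0.0
        assert st.confinement_ratio == 0.0
        assert st.duration_min == 20.0

    def test_square_path_returns_to_start(self):
        s = 7.0
        pts = [(0, 0), (s, 0), (s, s), (0, s), (0, 0)]
        tr = Track(0, [spot(f, x, y) for f, (x, y) in enumerate(pts)])
        st = trajectory_stats(tr, 1.0, 5.0)
        assert st.path_length_um == pytest.approx(4 * s)
        assert st.net_displacement_um == 0.0

    def test_random_track_path_matches_resummation(self, rng):
        pts = rng.uniform(0, 100, size=(21, 2))
        tr = Track(0, [spot(f, x, y) for f, (x, y) in enumerate(pts)])
        px = 0.65
        st = trajectory_stats(tr, px, 5.0)
        expected = sum(
            math.hypot(*(pts[i + 1] - pts[i])) * px for i in range(len(pts) - 1)
        )
        assert st.path_length_um == pytest.approx(expected)
        assert st.net_displacement_um <= st.path_length_um
        assert 0.0 <= st.confinement_ratio <= 1.0
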