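"""Contact rule, episode extraction, arrest coefficient, condition tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from caftrack.contact_analysis import (
    ContactParams,
    arrest_coefficient,
    compare_conditions,
    contact_timeline,
    extract_episodes,
    in_contact,
)
from caftrack.tracking import Track

from conftest import spot


def rle_episodes_oracle(flags, min_len):
    """Independent run-length-encoding of a boolean timeline."""
    out = []
    for is_true, grp in itertools.groupby(enumerate(flags), key=lambda t: t[1]):
        grp = list(grp)
        if is_true and len(grp) >= min_len:
            out.append((grp[0][0], grp[-1][0]))
    return out


class TestInContact:
    def test_center_on_foreground(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert in_contact(spot(0, 10, 10), mask, 4.0, 1.0)

    def test_far_spot_not_in_contact(self):
        mask = np.zeros((20, 20), bool)
        mask[0, 0] = True
        assert not in_contact(spot(0, 19, 19), mask, 1.0, 1.0)

    def test_boundary_distance_inclusive(self):
        # exact distance-transform geometry on a toy 20x20 mask
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        d = ndi.distance_transform_edt(~mask)
        assert d[10, 14] == 4.0
        assert in_contact(spot(0, 14, 10), mask, 4.0, 1.0)
        assert not in_contact(spot(0, 15, 10), mask, 4.0, 1.0)

    def test_empty_mask_is_false_not_error(self):
        assert not in_contact(spot(0, 5, 5), np.zeros((10, 10), bool), 4.0, 1.0)


class TestContactTimeline:
    def _mask_with_block(self):
        m = np.zeros((40, 40), bool)
        m[20:30, 20:30] = True
        return m

    def test_track_outside_mask_all_false(self):
        track = Track(0, [spot(f, 2, 2) for f in range(5)])
        masks = {f: self._mask_with_block() for f in range(5)}
        assert contact_timeline(track, masks, ContactParams(), 1.0) == [False] * 5

    def test_entry_at_frame_seven_of_ten(self):
        pts = [(2.0, 2.0)] * 7 + [(24.0, 24.0)] * 3
        track = Track(0, [spot(f, x, y) for f, (x, y) in enumerate(pts)])
        masks = {f: self._mask_with_block() for f in range(10)}
        tl = contact_timeline(track, masks, ContactParams(), 1.0)
        assert tl == [False] * 7 + [True] * 3

    def test_empty_masks_all_false(self):
        track = Track(0, [spot(f, 24, 24) for f in range(4)])
        masks = {f: np.zeros((40, 40), bool) for f in range(4)}
        assert contact_timeline(track, masks, ContactParams(), 1.0) == [False] * 4

    def test_missing_mask_raises(self):
        track = Track(0, [spot(0, 1, 1), spot(1, 1, 1)])
        with pytest.raises(KeyError):
            contact_timeline(track, {0: np.zeros((8, 8), bool)}, ContactParams(), 1.0)

    def test_mask_dilation_never_shortens_episodes(self, rng):
        mask = np.zeros((60, 60), bool)
        mask[25:35, 25:35] = True
        big = ndi.binary_dilation(mask, iterations=3)
        pts = rng.uniform(0, 59, size=(30, 2))
        track = Track(0, [spot(f, x, y) for f, (x, y) in enumerate(pts)])
        p = ContactParams()
        tl_small = contact_timeline(track, {f: mask for f in range(30)}, p, 1.0)
        tl_big = contact_timeline(track, {f: big for f in range(30)}, p, 1.0)
        assert all(b or not s for s, b in zip(tl_small, tl_big))
        assert arrest_coefficient(tl_big) >= arrest_coefficient(tl_small)
        for e in extract_episodes(tl_small, p):
            covering = [
                d
                for d in extract_episodes(tl_big, p)
                if d.start_frame <= e.start_frame and d.end_frame >= e.end_frame
            ]
            assert covering


class TestExtractEpisodes:
    def test_two_frame_contact_lasts_ten_minutes(self):
        flags = [False, False, False, True, True, False]
        eps = extract_episodes(flags, ContactParams())
        assert len(eps) == 1
        assert (eps[0].start_frame, eps[0].end_frame) == (3, 4)
        assert eps[0].duration_min == 10.0

    def test_single_frame_below_window_dropped(self):
        assert extract_episodes([False, True, False], ContactParams()) == []

    def test_no_bridging_across_gap(self):
        eps = extract_episodes([1, 1, 1, 0, 1, 1], ContactParams())
        assert [(e.n_frames) for e in eps] == [3, 2]

    def test_frame_jump_breaks_run(self):
        # gap-closed frames carry no flag: a jump in frame numbers splits runs
        eps = extract_episodes(
            [True, True, True, True],
            ContactParams(),
            frames=[3, 4, 8, 9],
        )
        assert [(e.start_frame, e.end_frame) for e in eps] == [(3, 4), (8, 9)]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), max_size=40), st.integers(1, 4))
    def test_matches_rle_oracle(self, flags, min_len):
        p = ContactParams(min_episode_frames=min_len)
        got = [(e.start_frame, e.end_frame) for e in extract_episodes(flags, p)]
        assert got == rle_episodes_oracle(flags, min_len)

    def test_episode_durations_bounded_by_movie_duration(self, rng):
        flags = rng.uniform(size=200) < 0.7
        p = ContactParams()
        eps = extract_episodes(list(flags), p)
        assert sum(e.duration_min for e in eps) <= len(flags) * p.frame_interval_min


class TestArrestCoefficient:
    @pytest.mark.parametrize(
        "flags,expected",
        [([False] * 5, 0.0), ([True] * 5, 1.0), ([True] * 3 + [False] * 9, 0.25)],
    )
    def test_values(self, flags, expected):
        assert arrest_coefficient(flags) == expected

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError):
            arrest_coefficient([])


class TestCompareConditions:
    def test_identical_samples_p_one(self):
        _, p = compare_conditions([3.0, 4.0, 5.0], [3.0, 4.0, 5.0], test="ranksum")
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        # {1,2} vs {100,101}: 6 labelings, 2 as extreme as observed
        _, p = compare_conditions([1.0, 2.0], [100.0, 101.0], test="ranksum")
        assert p == pytest.approx(2.0 / 6.0)

    def test_large_samples_use_asymptotic(self, rng):
        a = rng.normal(0, 1, size=40)
        b = rng.normal(2, 1, size=40)
        _, p = compare_conditions(a, b, test="ranksum")
        assert p < 1e-6

    def test_t_test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0, 1.0], [1.0, 1.0], test="t")

    def test_sample_size_minimum(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [2.0, 3.0])
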