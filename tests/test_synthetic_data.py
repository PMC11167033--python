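"""Synthetic-data generators: determinism, ground-truth consistency,
condition-dependent motility."""

import numpy as np
import pytest

from caftrack.contact_analysis import ContactParams, extract_episodes
from caftrack.synthetic_data import (
    MotilityModel,
    OvercrowdingError,
    antigen_model,
    control_model,
    generate_if_field,
    generate_movie,
    generate_puncta_image,
    simulate_tracks,
)


class TestMotilityModel:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            MotilityModel(p_on=1.5)
        with pytest.raises(ValueError):
            MotilityModel(p_off=-0.1)

    def test_arrest_slower_than_free(self):
        with pytest.raises(ValueError):
            MotilityModel(step_sd_free_um=1.0, step_sd_arrest_um=2.0)


class TestGenerateMovie:
    def test_zero_cells_blank_channel_empty_truth(self):
        movie, truth = generate_movie(
            n_cells=0, n_frames=3, seed=0, shape=(128, 128),
            mask_spec={"kind": "disk", "radius_um": 30.0},
        )
        treg = movie.channels["treg"]
        assert truth.positions_px.shape[0] == 0
        assert truth.episodes == []
        # blank apart from background + read noise
        assert treg.std() < 5.0

    def test_same_seed_bit_identical(self):
        kw = dict(n_cells=5, n_frames=4, seed=9, shape=(128, 128),
                  mask_spec={"kind": "disk", "radius_um": 30.0})
        m1, _ = generate_movie(**kw)
        m2, _ = generate_movie(**kw)
        for name in m1.channels:
            np.testing.assert_array_equal(m1.channels[name], m2.channels[name])

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            generate_movie(n_frames=1)
        with pytest.raises(ValueError):
            generate_movie(shape=(0, 10))

    def test_antigen_episodes_longer_than_control(self):
        durs = {}
        for model in (antigen_model(), control_model()):
            _, truth = generate_movie(n_cells=40, n_frames=90, model=model, seed=2)
            d = [e.duration_min for e in truth.episodes]
            durs[model.condition] = np.mean(d)
        assert durs["antigen"] > durs["control"]

    def test_truth_episodes_consistent_with_contact_states(self):
        _, truth = generate_movie(
            n_cells=10, n_frames=40, seed=3, shape=(256, 256),
            mask_spec={"kind": "disks", "n": 5, "radius_um": 30.0},
        )
        p = ContactParams(min_episode_frames=1)
        rebuilt = []
        for c in range(truth.contact.shape[0]):
            rebuilt.extend(
                extract_episodes(list(truth.contact[c]), p, track_id=c)
            )
        assert [
            (e.track_id, e.start_frame, e.end_frame) for e in rebuilt
        ] == [(e.track_id, e.start_frame, e.end_frame) for e in truth.episodes]

    def test_higher_p_on_does_not_reduce_arrested_frames(self):
        # >= 200 simulated cells, identical random streams
        mask = np.zeros((256, 256), bool)
        yy, xx = np.mgrid[0:256, 0:256]
        mask[(yy - 128) ** 2 + (xx - 128) ** 2 <= 80**2] = True
        totals = []
        for p_on in (0.05, 0.3, 0.8):
            model = MotilityModel(p_on=p_on, p_off=0.2)
            rng = np.random.default_rng(77)
            _, arrested, _ = simulate_tracks(200, 40, model, mask, rng)
            totals.append(arrested.sum())
        assert totals[0] <= totals[1] <= totals[2]

    def test_excluded_volume_keeps_cells_apart(self):
        _, truth = generate_movie(
            n_cells=30, n_frames=20, seed=5, shape=(256, 256),
            mask_spec={"kind": "disks", "n": 5, "radius_um": 30.0},
        )
        for t in range(20):
            pos = truth.positions_px[:, t, :]
            d = np.hypot(
                pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1]
            )
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 8.0 * 0.98  # soft-core: small residual overlap allowed


class TestGenerateIfField:
    def test_zero_cells(self):
        channels, truth = generate_if_field(0, 0, 0.3, seed=0, shape=(256, 256))
        assert truth.cell_count_rich == truth.cell_count_poor == 0

    def test_requested_fraction_realized(self):
        _, truth = generate_if_field(3, 3, 0.25, seed=1)
        assert 0.24 <= truth.marker_area_fraction <= 0.26

    def test_fixed_seed_reproducible(self):
        c1, _ = generate_if_field(5, 5, 0.4, seed=8)
        c2, _ = generate_if_field(5, 5, 0.4, seed=8)
        np.testing.assert_array_equal(c1["nuclei"], c2["nuclei"])
        np.testing.assert_array_equal(c1["marker"], c2["marker"])

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_if_field(1, 1, 1.2, seed=0)

    def test_overcrowding_raises(self):
        with pytest.raises(OvercrowdingError):
            generate_if_field(500, 0, 0.05, seed=0, shape=(128, 128))


class TestGeneratePunctaImage:
    def test_truth_counts_recorded(self):
        _, truth = generate_puncta_image([((40.0, 40.0), 12.0, 7)], seed=0)
        assert truth.puncta_counts == [7]

    def test_zero_puncta(self):
        _, truth = generate_puncta_image([((40.0, 40.0), 12.0, 0)], seed=0)
        assert truth.puncta_counts == [0]

    def test_puncta_must_fit_in_radius(self):
        with pytest.raises(ValueError):
            generate_puncta_image([((40.0, 40.0), 0.5, 3)], seed=0)
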