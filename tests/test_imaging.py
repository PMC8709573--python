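"""Drift estimation/correction, channel alignment, segmentation, extraction."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from togsense.errors import DegenerateInputError
from togsense.imaging import (Recording, DriftTrack, align_channels, apply_drift,
                              drift_correct, estimate_drift, extract_traces,
                              segment_nuclei, Spot, SpotSet)
from togsense.synthetic import SimulationConfig, simulate_organ_truth, \
    simulate_recording


def make_recording(cfg, truth=None, tastant=None, rng=None, **truth_kwargs):
    if truth is None:
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(cfg.seed),
                                     **truth_kwargs)
    rec, bundle = simulate_recording(cfg, truth, tastant=tastant, rng=rng)
    return rec, bundle, truth


def _oracle_integer_shift(ref, mov, max_shift=5):
    """Exhaustive shift search maximizing overlap correlation."""
    best, best_shift = -np.inf, None
    r = ref - ref.mean()
    m = mov - mov.mean()
    for dz, dy, dx in itertools.product(range(-max_shift, max_shift + 1),
                                        repeat=3):
        shifted = np.roll(m, (-dz, -dy, -dx), axis=(0, 1, 2))
        score = float((r * shifted).sum())
        if score > best:
            best, best_shift = score, (dz, dy, dx)
    return np.array(best_shift, dtype=float)


class TestDrift:
    def test_drift_free_recording_gives_zero(self, small_config):
        rec, _, _ = make_recording(small_config)
        track = estimate_drift(rec)
        assert np.abs(track.shifts).max() < 1e-6

    def test_integer_drift_recovered_exactly(self):
        cfg = SimulationConfig(n_cells=6, n_landmarks=0, volume_shape=(15, 64, 64),
                               n_frames=8, stim_onset_frame=4, stim_offset_frame=6,
                               drift_per_frame=(0, 1, -1), seed=1)
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(2),
                                     cloud_center_um=(10, 13, 16),
                                     cloud_radius_um=(5, 6, 6))
        rec, bundle, _ = make_recording(cfg, truth=truth)
        track = estimate_drift(rec, subvoxel=False)
        assert np.array_equal(track.shifts, bundle.drift_voxels)

    def test_agrees_with_exhaustive_shift_oracle(self):
        cfg = SimulationConfig(n_cells=5, n_landmarks=0, volume_shape=(13, 48, 48),
                               n_frames=4, stim_onset_frame=2, stim_offset_frame=3,
                               drift_per_frame=(1, -1, 1), seed=3)
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(3),
                                     cloud_center_um=(9, 11, 9),
                                     cloud_radius_um=(4, 5, 5))
        rec, bundle, _ = make_recording(cfg, truth=truth)
        track = estimate_drift(rec, subvoxel=False, max_shift=5)
        nuclear = rec.channel("nuclear")
        for t in range(1, rec.n_frames):
            oracle = _oracle_integer_shift(nuclear[0], nuclear[t])
            assert np.array_equal(track.shifts[t], oracle)

    def test_translation_offset_shifts_every_estimate(self, small_config):
        """Adding an extra integer shift to each moving frame adds to the estimate."""
        rec, _, _ = make_recording(small_config)
        extra = (1, -2, 3)
        data = rec.intensities.copy()
        for t in range(1, rec.n_frames):
            data[t] = np.roll(data[t], extra, axis=(1, 2, 3))
        shifted = Recording(data, rec.voxel_size, rec.frame_interval)
        track = estimate_drift(shifted, subvoxel=False)
        assert np.allclose(track.shifts[1:], np.array(extra, dtype=float))

    def test_flat_volume_rejected(self):
        data = np.zeros((3, 2, 5, 8, 8))
        rec = Recording(data)
        with pytest.raises(DegenerateInputError):
            estimate_drift(rec)


class TestApplyDrift:
    def test_zero_track_is_identity(self, small_config):
        rec, _, _ = make_recording(small_config)
        track = DriftTrack(np.zeros((rec.n_frames, 3)))
        out = apply_drift(rec, track)
        assert np.array_equal(out.intensities, rec.intensities)

    def test_integer_shift_roundtrip_interior(self, small_config):
        rec, _, _ = make_recording(small_config)
        shift = np.tile([1.0, 2.0, -1.0], (rec.n_frames, 1))
        fwd = apply_drift(rec, DriftTrack(-shift))   # move content by +shift
        back = apply_drift(fwd, DriftTrack(shift))
        interior = (slice(None), slice(None), slice(2, -2), slice(3, -3),
                    slice(3, -3))
        assert np.allclose(back.intensities[interior], rec.intensities[interior],
                           atol=1e-9)

    def test_correction_leaves_subvoxel_residual(self):
        cfg = SimulationConfig(n_cells=6, n_landmarks=0, volume_shape=(15, 64, 64),
                               n_frames=8, stim_onset_frame=4, stim_offset_frame=6,
                               drift_per_frame=(0, 0.6, -0.4), noise_sd=1.0, seed=5)
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(5),
                                     cloud_center_um=(10, 13, 15),
                                     cloud_radius_um=(5, 6, 6))
        rec, _, _ = make_recording(cfg, truth=truth,
                                   rng=np.random.default_rng(50))
        result = drift_correct(rec)
        assert result.residual <= 1.0
        assert not result.discard


class TestAlignChannels:
    def test_aligned_channels_give_zero_offset(self, small_config):
        rec, _, _ = make_recording(small_config)
        _, offset = align_channels(rec)
        assert np.abs(offset).max() < 0.5

    def test_injected_offset_recovered(self, small_config):
        rec, _, _ = make_recording(small_config)
        data = rec.intensities.copy()
        data[:, 1] = np.roll(data[:, 1], (3, -2), axis=(2, 3))
        shifted = Recording(data, rec.voxel_size)
        _, offset = align_channels(shifted)
        assert abs(offset[0] - 3) <= 1 and abs(offset[1] + 2) <= 1

    def test_offset_invariant_to_intensity_scaling(self, small_config):
        rec, _, _ = make_recording(small_config)
        data = rec.intensities.copy()
        data[:, 1] = np.roll(data[:, 1], (2, 1), axis=(2, 3)) * 7.3
        _, offset = align_channels(Recording(data, rec.voxel_size))
        assert abs(offset[0] - 2) <= 1 and abs(offset[1] - 1) <= 1

    def test_flat_channel_rejected(self):
        data = np.zeros((2, 2, 5, 8, 8))
        data[:, 0, 2, 4, 4] = 10.0
        with pytest.raises(DegenerateInputError):
            align_channels(Recording(data))


class TestSegmentation:
    def test_blank_volume_gives_no_spots(self):
        rec = Recording(np.zeros((2, 2, 10, 32, 32)))
        assert len(segment_nuclei(rec)) == 0

    def test_negative_diameter_rejected(self, small_config):
        rec, _, _ = make_recording(small_config)
        with pytest.raises(ValueError):
            segment_nuclei(rec, spot_diameter_um=-1.0)

    def test_five_separated_cells_recovered(self):
        cfg = SimulationConfig(n_cells=5, n_landmarks=0, volume_shape=(15, 64, 64),
                               n_frames=4, stim_onset_frame=2, stim_offset_frame=3,
                               seed=7)
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(7),
                                     cloud_center_um=(10, 13, 13),
                                     cloud_radius_um=(6, 9, 9),
                                     min_separation_um=4 * 1.75)
        rec, _, _ = make_recording(cfg, truth=truth)
        spots = segment_nuclei(rec)
        assert len(spots) == 5
        err = cdist(truth.positions(), spots.centroids()).min(axis=1)
        voxel = np.asarray(cfg.voxel_size)
        assert (err <= np.linalg.norm(voxel)).all()

    def test_close_pair_suppressed_to_one(self):
        data = np.zeros((1, 2, 15, 48, 48))
        voxel = np.array([1.5, 0.43, 0.43])
        z, y, x = np.indices((15, 48, 48)).astype(float)
        sigma = 1.4865
        for cy in (10.0, 11.75):  # 1.75 um apart: half the min separation
            d2 = ((z * 1.5 - 10.0) ** 2 + (y * 0.43 - cy) ** 2
                  + (x * 0.43 - 10.0) ** 2)
            data[0, 0] += 150 * np.exp(-d2 / (2 * sigma ** 2))
        rec = Recording(data, tuple(voxel))
        assert len(segment_nuclei(rec)) == 1

    def test_count_monotone_in_threshold(self, small_config):
        rec, _, _ = make_recording(small_config)
        counts = [len(segment_nuclei(rec, threshold=thr))
                  for thr in (0.5, 2.0, 8.0, 32.0)]
        assert counts == sorted(counts, reverse=True)


class TestExtractTraces:
    def test_uniform_volume_gives_constant_trace(self):
        data = np.full((4, 2, 10, 24, 24), 7.0)
        rec = Recording(data)
        spots = SpotSet([Spot("c1", (7.0, 5.0, 5.0))], (10, 24, 24),
                        rec.voxel_size)
        traces = extract_traces(rec, spots)
        assert np.allclose(traces[0].values, 7.0)

    def test_roundtrip_correlation_with_generator_trace(self):
        cfg = SimulationConfig(n_cells=1, n_landmarks=0, volume_shape=(15, 48, 48),
                               seed=9)
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(9),
                                     cloud_center_um=(10, 10, 10),
                                     cloud_radius_um=(2, 2, 2),
                                     class_probs={"on": 1.0, "off_late": 0.0,
                                                  "deactivation": 0.0, "none": 0.0})
        rec, bundle, _ = make_recording(cfg, truth=truth, tastant="sucrose")
        spots = segment_nuclei(rec)
        assert len(spots) == 1
        trace = extract_traces(rec, spots, tastant="sucrose")[0]
        from togsense.synthetic import response_kernel
        generator = 100.0 * (1 + response_kernel(
            bundle.organ.cells[0].tuning["sucrose"], cfg))
        r = np.corrcoef(trace.values, generator)[0, 1]
        assert r > 0.999

    def test_traces_are_local_to_their_cell(self):
        cfg = SimulationConfig(n_cells=2, n_landmarks=0, volume_shape=(15, 64, 64),
                               seed=11)
        truth = simulate_organ_truth(cfg, ["sucrose"],
                                     rng=np.random.default_rng(11),
                                     cloud_center_um=(10, 13, 13),
                                     cloud_radius_um=(6, 10, 10),
                                     min_separation_um=14.0)
        rec, _, _ = make_recording(cfg, truth=truth, tastant="sucrose")
        spots = segment_nuclei(rec)
        assert len(spots) == 2
        both = extract_traces(rec, spots)
        # delete the second cell's blob and re-extract the first
        single = simulate_organ_truth(cfg, ["sucrose"],
                                      rng=np.random.default_rng(11),
                                      cloud_center_um=(10, 13, 13),
                                      cloud_radius_um=(6, 10, 10),
                                      min_separation_um=14.0)
        from togsense.synthetic import OrganTruth
        lone = OrganTruth(organ_id="x", cells=(single.cells[0],))
        rec_lone, _ = simulate_recording(cfg, lone, tastant="sucrose")
        # the spot sitting on cell 0
        pos0 = np.array(single.cells[0].position_um)
        idx = int(np.argmin([np.linalg.norm(np.array(s.centroid_um) - pos0)
                             for s in spots.spots]))
        sub = SpotSet([spots.spots[idx]], spots.volume_shape, spots.voxel_size)
        lone_trace = extract_traces(rec_lone, sub)[0]
        ref = extract_traces(rec, sub)[0]
        assert np.allclose(ref.values, lone_trace.values, rtol=1e-3, atol=1e-3)

    def test_commutes_with_global_scaling(self):
        data = np.random.default_rng(0).random((3, 2, 10, 24, 24)) + 0.5
        rec = Recording(data)
        spots = SpotSet([Spot("c1", (7.0, 5.0, 5.0))], (10, 24, 24), rec.voxel_size)
        a = extract_traces(rec, spots)[0].values
        b = extract_traces(Recording(data * 3.0), spots)[0].values
        assert np.allclose(b, 3.0 * a)

    def test_empty_sphere_names_the_spot(self):
        rec = Recording(np.ones((2, 2, 10, 24, 24)))
        spots = SpotSet([Spot("lost", (7.2, 5.2, 5.2), radius_um=0.05)],
                        (10, 24, 24), rec.voxel_size)
        with pytest.raises(ValueError, match="lost"):
            extract_traces(rec, spots)
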