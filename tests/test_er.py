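"""Signed distance maps, ER indices, diffusion coefficients, and the
per-cell classification rule."""

import numpy as np
import pytest

from conftest import brute_force_signed_distance
from ertrack import synth
from ertrack.er import (
    CellSummary,
    TrackMetrics,
    classify_track,
    cumulative_er_index,
    instantaneous_diffusion,
    per_cell_fraction,
    segment_er,
    signed_distance_map,
)
from ertrack.detect import Spot
from ertrack.tracking import Track


class TestSegmentEr:
    @pytest.mark.parametrize("seed", [1, 2])
    def test_noise_free_rendering_recovers_truth_mask(self, seed):
        mask, img = synth.make_er_geometry(seed=seed)
        seg = segment_er(img)
        iou = (seg & mask).sum() / (seg | mask).sum()
        assert iou >= 0.9

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="degenerate|empty"):
            seg = segment_er(np.full((64, 64), 5.0))
        assert not seg.any()

    def test_binary_probability_map_is_identity(self):
        rng = np.random.default_rng(0)
        pmap = (rng.uniform(size=(40, 40)) < 0.3).astype(float)
        seg = segment_er(pmap, threshold_mode="probability", area_min_px=0)
        assert np.array_equal(seg, pmap.astype(bool))

    def test_fixed_threshold_mode(self):
        img = np.zeros((70, 70))
        img[10:30, 10:30] = 10.0
        seg = segment_er(img, threshold_mode="fixed", fixed_threshold=5.0)
        assert np.array_equal(seg, img > 5.0)


class TestSignedDistanceMap:
    def test_single_center_pixel_forced_geometry(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        sdm = signed_distance_map(mask)
        assert sdm[1, 1] == 1.0
        assert sdm[0, 1] == sdm[1, 0] == sdm[1, 2] == sdm[2, 1] == -1.0
        assert sdm[0, 0] == pytest.approx(-np.sqrt(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 33, 2))
        mask = rng.uniform(size=shape) < rng.uniform(0.1, 0.9)
        sdm = signed_distance_map(mask)
        assert np.array_equal(sdm, brute_force_signed_distance(mask))

    def test_sign_pattern_equals_mask_membership(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(24, 24)) < 0.4
        if mask.any() and not mask.all():
            sdm = signed_distance_map(mask)
            assert np.array_equal(sdm > 0, mask)

    def test_degenerate_masks_capped_at_diagonal(self):
        empty = signed_distance_map(np.zeros((10, 20), bool))
        full = signed_distance_map(np.ones((10, 20), bool))
        diag = np.hypot(10, 20)
        assert np.all(empty == -diag)
        assert np.all(full == diag)


class TestCumulativeIndex:
    def test_forced_arithmetic(self):
        sdm = np.array([[1.0, -1.414], [2.0, -3.0]])
        track = np.array([[0, 0], [0, 0], [1, 0], [0, 0]], float)  # (x, y)
        # samples sdm values (+1, +1, -1.414, +1)
        assert cumulative_er_index(track, sdm) == pytest.approx(1.586)

    def test_on_er_track_is_positive(self):
        mask, _ = synth.make_er_geometry(seed=1)
        sdm = signed_distance_map(mask)
        r, c = np.argwhere(mask)[0]
        track = np.array([[c, r]] * 5, float)
        assert cumulative_er_index(track, sdm) > 0

    def test_additive_over_segments(self):
        rng = np.random.default_rng(4)
        sdm = rng.normal(size=(30, 30))
        pos = rng.uniform(0, 29, (12, 2))
        whole = cumulative_er_index(pos, sdm)
        assert whole == pytest.approx(
            cumulative_er_index(pos[:6], sdm)
            + cumulative_er_index(pos[6:], sdm))

    def test_out_of_bounds_position_raises(self):
        sdm = np.zeros((10, 10))
        with pytest.raises(ValueError, match="position 1"):
            cumulative_er_index(np.array([[1, 1], [50, 1]], float), sdm)

    def test_interpolated_sampling_option(self):
        sdm = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert cumulative_er_index(
            np.array([[0.5, 0.5]]), sdm, interpolate=True
        ) == pytest.approx(0.5)


class TestInstantaneousDiffusion:
    def test_stationary_track_zero(self, default_params):
        track = np.array([[t, 5.0, 5.0] for t in range(10)])
        assert instantaneous_diffusion(track, default_params) == 0.0

    def test_constant_step_forced_arithmetic(self, default_params):
        # 1 px (0.134 um) per frame at dt = 0.05 s:
        # IDC = 0.134^2 / (4 * 0.05) ~ 0.0898 um^2/s
        track = np.array([[t, float(t), 0.0] for t in range(10)])
        assert instantaneous_diffusion(track, default_params) == pytest.approx(
            0.134**2 / 0.2)

    def test_gap_bridged_pairs_excluded(self, default_params):
        track = np.array([[0, 0, 0], [1, 1, 0], [5, 30, 0], [6, 31, 0]], float)
        # only the two consecutive pairs (step 1 px) enter
        assert instantaneous_diffusion(track, default_params) == pytest.approx(
            0.134**2 / 0.2)

    def test_no_consecutive_pairs_nan_with_warning(self, default_params):
        track = np.array([[0, 0, 0], [2, 1, 0], [4, 2, 0]], float)
        with pytest.warns(UserWarning, match="IDC undefined"):
            assert np.isnan(instantaneous_diffusion(track, default_params))

    def test_ensemble_mean_matches_brownian_truth(self):
        params = synth.AcquisitionParams(shape_px=(512, 512))
        parts = synth.simulate_particles(
            np.zeros((512, 512), bool), 0, 500, 0.0, 0.02, params, seed=3)
        idcs = [instantaneous_diffusion(p.positions_px, params)
                for p in parts]
        assert 0.018 <= np.mean(idcs) <= 0.022

    def test_doubling_pixel_size_quadruples_idc(self):
        track = np.array([[t, float(t), float(t)] for t in range(8)])
        p1 = synth.AcquisitionParams(pixel_size_um=0.1)
        p2 = synth.AcquisitionParams(pixel_size_um=0.2)
        assert instantaneous_diffusion(track, p2) == pytest.approx(
            4 * instantaneous_diffusion(track, p1))


class TestClassification:
    @pytest.mark.parametrize("idc,index,expected", [
        (0.03, 12.0, True),    # below both cut-offs
        (0.08, 12.0, False),   # too mobile
        (0.01, -0.5, False),   # off the ER
        (0.06, 12.0, False),   # cut-off is strict: D < 0.06
        (0.03, 0.0, False),    # index must be strictly positive
    ])
    def test_cutoff_rule(self, idc, index, expected):
        assert classify_track(idc, index) is expected

    def test_raising_d_cutoff_never_unclassifies(self):
        rng = np.random.default_rng(1)
        idcs = rng.uniform(0, 0.2, 100)
        idx = rng.normal(0, 5, 100)
        low = [classify_track(d, i, d_cutoff=0.03) for d, i in zip(idcs, idx)]
        high = [classify_track(d, i, d_cutoff=0.1) for d, i in zip(idcs, idx)]
        assert all(h or not l for l, h in zip(low, high))


def _metrics(cell_id, values, lengths=None):
    out = []
    for k, (idc, index) in enumerate(values):
        n = lengths[k] if lengths else 50
        out.append(TrackMetrics(k, cell_id, n, idc, index,
                                classify_track(idc, index)))
    return out


def _tracks_for(metrics):
    return [Track(m.track_id,
                  [Spot(t, 0, 0, 1.0) for t in range(m.n_frames_used)],
                  m.cell_id)
            for m in metrics]


class TestPerCellFraction:
    def test_direct_rule_application(self):
        ms = _metrics(1, [(0.01, 5), (0.2, 3), (0.01, -2), (0.05, 1)])
        summaries = per_cell_fraction(_tracks_for(ms), ms)
        assert len(summaries) == 1
        assert summaries[0].fraction_er_associated == 0.5

    def test_cells_below_min_tracks_omitted(self):
        ms = _metrics(1, [(0.01, 5), (0.2, 3)])
        assert per_cell_fraction(_tracks_for(ms), ms) == []

    def test_short_tracks_never_enter_denominator(self):
        ms = _metrics(1, [(0.01, 5), (0.01, 5), (0.01, 5), (0.2, -1)],
                      lengths=[50, 50, 25, 50])
        summaries = per_cell_fraction(_tracks_for(ms), ms)
        assert summaries[0].n_tracks_eligible == 3

    def test_tracks_without_cell_excluded(self):
        ms = _metrics(None, [(0.01, 5)] * 5)
        assert per_cell_fraction(_tracks_for(ms), ms) == []

    def test_all_negative_indices_force_zero_fraction(self):
        ms = _metrics(2, [(0.01, -1), (0.02, -3), (0.01, -0.1)])
        summaries = per_cell_fraction(_tracks_for(ms), ms)
        assert summaries[0].fraction_er_associated == 0.0
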