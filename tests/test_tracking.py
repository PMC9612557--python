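"""Illumination correction, segmentation, linking and lineage heuristics."""

import itertools
import math

import numpy as np
import pytest

from colonyscope import GrowthParams, MigrationParams
from colonyscope.movies import RenderConfig, make_movie, render_frame
from colonyscope.tracking import (
    Detection,
    LinkParams,
    Lineage,
    Track,
    build_tracks,
    correct_illumination,
    evaluate_paraboloid,
    evaluate_tracking,
    fit_paraboloid,
    lineage_capture_fraction,
    lineage_from_frame,
    link_frames,
    resolve_discontinuities,
    segment_cells,
    track_movie,
    tracks_to_frame,
)


def brute_force_link_cost(dets_a, dets_b, params: LinkParams) -> float:
    """Exhaustive minimum over all partial injective matchings plus
    birth/death costs - the oracle for the assignment solver."""

    def pair_cost(a, b):
        d2 = (a.x - b.x) ** 2 + (a.y - b.y) ** 2
        if d2 > params.max_distance**2:
            return math.inf
        denom = a.intensity + b.intensity
        it = abs(a.intensity - b.intensity) / denom if denom > 0 else 0.0
        return params.w_pos * d2 + params.w_int * it

    n, m = len(dets_a), len(dets_b)
    best = math.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = sum(pair_cost(dets_a[i], dets_b[j]) for i, j in zip(rows, cols))
                cost += (n - k) * params.death + (m - k) * params.birth
                best = min(best, cost)
    return best


def _det(frame, x, y, intensity=100.0, area=30):
    return Detection(frame=frame, x=x, y=y, intensity=intensity, area=area)


class TestIlluminationCorrection:
    def test_flat_image(self):
        img = np.full((64, 64), 37.0)
        corrected, coeffs = correct_illumination(img)
        assert np.allclose(corrected, 1.0, atol=1e-9)
        assert coeffs[0] == pytest.approx(37.0)
        assert np.allclose(coeffs[1:], 0.0, atol=1e-9)

    def test_known_paraboloid_recovered(self, small_fov):
        cfg = RenderConfig(noise_model="none", illumination=(1.1, 0.08, -0.03, -0.25, 0.05, -0.22))
        img = render_frame(np.empty((0, 2)), np.empty(0), small_fov, cfg)
        _, coeffs = correct_illumination(img)
        expected = cfg.background_level * np.asarray(cfg.illumination)
        assert np.allclose(coeffs, expected, rtol=0.01, atol=0.01 * cfg.background_level * 0.01)

    def test_background_flatness_improves_with_cells_present(self, small_fov):
        cfg = RenderConfig()  # paraboloid bias + poisson noise
        stack, truth = make_movie(
            GrowthParams(), MigrationParams.per_minute(), small_fov, cfg, 24.0, seed=2
        )
        img = stack[-1].astype(float)
        corrected, _ = correct_illumination(img)
        med = np.median(img)
        bg = img < med + 3 * 1.4826 * np.median(np.abs(img - med))
        cv_before = img[bg].std() / img[bg].mean()
        cv_after = corrected[bg].std() / corrected[bg].mean()
        assert cv_after < cv_before

    def test_idempotence(self, small_fov):
        cfg = RenderConfig()
        stack, _ = make_movie(GrowthParams(), MigrationParams.per_minute(), small_fov, cfg, 12.0, seed=3)
        once, _ = correct_illumination(stack[-1].astype(float))
        twice, _ = correct_illumination(once)
        rms = np.sqrt(np.mean((twice - once) ** 2)) / np.mean(once)
        assert rms < 0.01

    def test_too_few_background_pixels(self):
        with pytest.raises(ValueError):
            fit_paraboloid(np.ones((8, 8)), np.zeros((8, 8), dtype=bool))

    def test_paraboloid_field_evaluation(self):
        coeffs = np.array([2.0, 0.0, 0.0, 1.0, 0.0, 1.0])
        field = evaluate_paraboloid(coeffs, (32, 32))
        assert field.shape == (32, 32)
        assert field.min() >= 2.0  # centre of a bowl


class TestSegmentation:
    def test_blank_frame(self):
        assert segment_cells(np.ones((64, 64)), threshold=2.0) == []

    def test_four_cells_localised_within_one_pixel(self, small_fov):
        cfg = RenderConfig(noise_model="none", illumination=(1.0, 0, 0, 0, 0, 0))
        pos = np.array([[-40.0, -40.0], [40.0, -40.0], [-40.0, 40.0], [40.0, 40.0]])
        img = render_frame(pos, np.full(4, 4e5), small_fov, cfg)
        dets = segment_cells(img, frame=0)
        assert len(dets) == 4
        px = small_fov.pixel_size
        truth = {(x / px + small_fov.n_pixels_x / 2 - 0.5, y / px + small_fov.n_pixels_y / 2 - 0.5) for x, y in pos}
        for d in dets:
            assert min(math.hypot(d.x - tx, d.y - ty) for tx, ty in truth) < 1.0

    def test_close_pair_may_merge(self, small_fov):
        cfg = RenderConfig(noise_model="none", illumination=(1.0, 0, 0, 0, 0, 0))
        pos = np.array([[-1.0, 0.0], [1.0, 0.0]])  # well under the psf width
        img = render_frame(pos, np.full(2, 4e5), small_fov, cfg)
        dets = segment_cells(img, frame=0)
        assert 1 <= len(dets) <= 2  # merging is accepted; heuristics handle it

    def test_min_area_filter(self, small_fov):
        cfg = RenderConfig(noise_model="none", illumination=(1.0, 0, 0, 0, 0, 0))
        img = render_frame([(0.0, 0.0)], [4e5], small_fov, cfg)
        assert segment_cells(img, min_area=10**6) == []


class TestLinking:
    def test_identical_sets_identity_assignment(self):
        dets = [_det(0, 10, 10), _det(0, 50, 50, intensity=200)]
        nxt = [_det(1, 10, 10), _det(1, 50, 50, intensity=200)]
        res = link_frames(dets, nxt)
        assert sorted(res.matches) == [(0, 0), (1, 1)]
        assert res.cost == 0.0

    def test_intensity_preserves_identity_under_position_swap(self):
        a = [_det(0, 0, 0, intensity=100), _det(0, 10, 0, intensity=300)]
        b = [_det(1, 10, 0, intensity=100), _det(1, 0, 0, intensity=300)]
        res = link_frames(a, b, LinkParams(w_pos=0.1, w_int=100.0))
        assert sorted(res.matches) == [(0, 0), (1, 1)]  # identities follow brightness

    def test_gate_forces_birth_and_death(self):
        a = [_det(0, 0, 0)]
        b = [_det(1, 500, 0)]
        res = link_frames(a, b)
        assert res.matches == [] and res.deaths == [0] and res.births == [0]

    @pytest.mark.parametrize("n,m", [(3, 3), (2, 4), (4, 2), (0, 3), (5, 5)])
    def test_cost_equals_exhaustive_minimum(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        params = LinkParams(max_distance=40.0)
        for _ in range(8):
            a = [_det(0, *rng.uniform(0, 80, 2), intensity=rng.uniform(50, 500)) for _ in range(n)]
            b = [_det(1, *rng.uniform(0, 80, 2), intensity=rng.uniform(50, 500)) for _ in range(m)]
            res = link_frames(a, b, params)
            assert res.cost == pytest.approx(brute_force_link_cost(a, b, params))


class TestDiscontinuityHeuristics:
    def test_clean_tracks_unchanged(self):
        frames = [[_det(f, 10, 10), _det(f, 60, 60, intensity=250)] for f in range(5)]
        tracks = build_tracks(frames)
        lineage = resolve_discontinuities(tracks, n_frames=5)
        assert len(lineage.tracks) == 2
        assert lineage.divisions == []
        assert all(t.start_frame == 0 and t.end_frame == 4 for t in lineage.tracks)

    def test_transient_merge_recovered(self):
        # B approaches A, they merge for frames 3-5, then separate again
        frames = []
        for f in range(3):
            frames.append([_det(f, 0, 0, 100), _det(f, 50 - 19 * f, 0, 110)])
        for f in range(3, 6):
            frames.append([_det(f, 5, 0, 210, area=60)])
        for f in range(6, 10):
            frames.append([_det(f, 0, 0, 100), _det(f, 12 + 3 * (f - 6), 0, 110)])
        tracks = build_tracks(frames)
        lineage = resolve_discontinuities(tracks, n_frames=10)
        spans = sorted((t.start_frame, t.end_frame) for t in lineage.tracks)
        assert spans == [(0, 9), (0, 9)]
        assert lineage.divisions == []

    def test_single_division_called_on_schedule(self, small_fov):
        stack, truth = make_movie(
            GrowthParams(), MigrationParams.per_minute(), small_fov, RenderConfig(), 14.0, seed=6
        )
        lineage = track_movie(stack)
        assert len(truth.divisions) == 1
        gt_frame = truth.divisions[0][0]
        assert len(lineage.divisions) == 1
        assert abs(lineage.divisions[0][0] - gt_frame) <= 1
        metrics = evaluate_tracking(lineage, truth, stack.shape[1:])
        assert metrics["division_recall"] == 1.0
        assert metrics["link_recovery"] == 1.0


class TestCaptureStatistic:
    def test_fully_tracked_movie(self):
        tracks = [Track(track_id=0, detections=[_det(f, 1, 1) for f in range(4)])]
        lin = Lineage(tracks=tracks)
        frac, per_frame, cls = lineage_capture_fraction(lin, np.ones(4))
        assert frac == 1.0
        assert cls == {0.5: True, 0.9: True}

    def test_half_lost_colony(self):
        tracks = [
            Track(track_id=0, detections=[_det(f, 1, 1) for f in range(4)]),
            Track(track_id=1, detections=[_det(f, 9, 9) for f in range(2)]),
        ]
        lin = Lineage(tracks=tracks)
        frac, per_frame, cls = lineage_capture_fraction(lin, np.full(4, 2))
        assert frac == pytest.approx(0.5)
        assert cls == {0.5: True, 0.9: False}

    def test_zero_expected_count_rejected(self):
        lin = Lineage(tracks=[])
        with pytest.raises(ValueError):
            lineage_capture_fraction(lin, np.zeros(3))


class TestSerialisation:
    def test_tracks_round_trip(self):
        frames = [[_det(f, 10, 10), _det(f, 60, 60, intensity=250)] for f in range(4)]
        lineage = resolve_discontinuities(build_tracks(frames), n_frames=4)
        df = tracks_to_frame(lineage)
        again = lineage_from_frame(df)
        assert len(again.tracks) == len(lineage.tracks)
        spans = {(t.start_frame, t.end_frame) for t in again.tracks}
        assert spans == {(0, 3)}
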