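"""Unit and property tests for the NCC block-matching tracker."""

import math

import numpy as np
import pytest
from skimage.feature import match_template

from leaftrack import (
    CorrelationSurface,
    FrameSequence,
    SceneSpec,
    SearchRegion,
    extract_template,
    locate_peak,
    ncc_surface,
    subpixel_peak,
    track_markers,
)
from leaftrack.synthetic import render_frame
from leaftrack.tracking import NoDefinedCorrelationError, round_half_away


def ncc_brute_force(frame, template, center, L):
    """Independent double-loop evaluation of the correlation formula.

    CC(x, y) = sum((win - win_mean)(t - t_mean))
               / sqrt(sum((win - win_mean)^2) * sum((t - t_mean)^2))
    over all candidate top-lefts in the (2L+1)^2 search grid; NaN where the
    window leaves the frame or either factor has zero variance.
    """
    frame = np.asarray(frame, dtype=float)
    t = np.asarray(template, dtype=float)
    s = t.shape[0]
    half = s // 2
    h, w = frame.shape
    T = t.mean()
    t_var = ((t - T) ** 2).sum()
    cx = int(round_half_away(center[0]))
    cy = int(round_half_away(center[1]))
    out = np.full((2 * L + 1, 2 * L + 1), np.nan)
    for dy in range(-L, L + 1):
        for dx in range(-L, L + 1):
            top = cy - half + dy
            left = cx - half + dx
            if top < 0 or left < 0 or top + s > h or left + s > w:
                continue
            acc_num = acc_win = 0.0
            I = frame[top:top + s, left:left + s].mean()
            for m in range(s):
                for n in range(s):
                    dw = frame[top + m, left + n] - I
                    acc_num += dw * (t[m, n] - T)
                    acc_win += dw * dw
            denom = math.sqrt(acc_win * t_var)
            if denom > 1e-9:
                out[dy + L, dx + L] = acc_num / denom
    return out


class TestExtractTemplate:
    def test_constant_patch(self):
        frame = np.full((5, 5), 10.0)
        patch = extract_template(frame, (2, 2), 3)
        assert patch.pixels.shape == (3, 3)
        assert np.all(patch.pixels == 10.0)
        assert patch.mean_gray == 10.0

    def test_border_crossing_raises(self):
        frame = np.zeros((480, 640))
        with pytest.raises(ValueError, match="border"):
            extract_template(frame, (0, 0), 23, marker_id=1)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_template(np.zeros((50, 50)), (25, 25), 22)

    def test_patch_is_immutable_copy(self):
        frame = np.arange(49, dtype=float).reshape(7, 7)
        patch = extract_template(frame, (3, 3), 3)
        before = patch.pixels.copy()
        frame[:] = 0
        assert np.array_equal(patch.pixels, before)
        with pytest.raises(ValueError):
            patch.pixels[0, 0] = 99

    def test_bead_center_attains_darkest_value(self):
        """A template cut at a rendered bead center attains the patch
        minimum at its center (the bead core is a flat plateau of the bead
        gray level, so the minimum is checked by value, tie-aware)."""
        corners = np.array([[30.0, 30.0], [90.0, 30.0], [60.0, 80.0]])
        spec = SceneSpec(image_size=(120, 100), n_markers=3, noise_sd=0.0,
                         initial_polygon=corners)
        frame = render_frame(spec, corners)
        patch = extract_template(frame, (30, 30), 23)
        minimum = min(patch.pixels[i, j] for i in range(23) for j in range(23))
        assert patch.pixels[11, 11] == minimum == pytest.approx(spec.bead_gray)


class TestNccSurface:
    def test_self_match_peak_is_one(self, rng):
        frame = rng.random((64, 64))
        patch = extract_template(frame, (30, 28), 9)
        surface = ncc_surface(frame, patch, SearchRegion((30, 28), 6))
        assert surface.cc_max == pytest.approx(1.0, abs=1e-12)
        assert surface.peak_offset == (0, 0)

    def test_affine_gray_invariance(self, rng):
        """i -> 3*i + 17 leaves every defined CC value unchanged: the
        tracker needs no constant-brightness assumption."""
        frame = rng.random((64, 64))
        patch = extract_template(frame, (30, 28), 9)
        region = SearchRegion((31, 27), 5)
        s1 = ncc_surface(frame, patch, region)
        s2 = ncc_surface(3.0 * frame + 17.0, patch, region)
        assert np.allclose(s1.values, s2.values, atol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        frame = rng.random((64, 64))
        center = (int(rng.integers(10, 54)), int(rng.integers(10, 54)))
        patch = extract_template(frame, center, 9)
        L = int(rng.integers(2, 6))
        shift = rng.integers(-3, 4, size=2)
        query = (center[0] + int(shift[0]), center[1] + int(shift[1]))
        surface = ncc_surface(frame, patch, SearchRegion(query, L))
        expected = ncc_brute_force(frame, patch.pixels, query, L)
        assert np.allclose(surface.values, expected, atol=1e-9, equal_nan=True)

    def test_matches_skimage_cross_check(self, rng):
        """Independent library cross-check on an interior search grid."""
        frame = rng.random((80, 80))
        patch = extract_template(frame, (40, 40), 11)
        L = 6
        surface = ncc_surface(frame, patch, SearchRegion((40, 40), L))
        full = match_template(frame, patch.pixels, pad_input=False)
        top0, left0 = 40 - 5, 40 - 5
        ref = full[top0 - L:top0 + L + 1, left0 - L:left0 + L + 1]
        assert np.allclose(surface.values, ref, atol=1e-6)

    def test_values_bounded(self, rng):
        for _ in range(30):
            frame = rng.random((40, 40))
            patch = extract_template(frame, (20, 20), 7)
            surface = ncc_surface(frame, patch, SearchRegion((21, 19), 4))
            defined = surface.values[np.isfinite(surface.values)]
            assert np.all(defined <= 1 + 1e-9) and np.all(defined >= -1 - 1e-9)

    def test_border_candidates_dropped_not_padded(self, rng):
        frame = rng.random((40, 40))
        patch = extract_template(frame, (5, 5), 9)
        surface = ncc_surface(frame, patch, SearchRegion((5, 5), 4))
        # placements pushing the window above/left of the frame are NaN
        assert np.isnan(surface.values[0, 0])
        assert np.isfinite(surface.values[4, 4])

    def test_flat_scene_has_no_defined_correlation(self):
        frame = np.full((40, 40), 0.5)
        patch = extract_template(frame, (20, 20), 7)
        with pytest.raises(NoDefinedCorrelationError):
            ncc_surface(frame, patch, SearchRegion((20, 20), 3))


class TestLocatePeak:
    def _surface(self, values, L):
        return CorrelationSurface(np.asarray(values, dtype=float), search_length=L)

    def test_rejects_below_threshold(self):
        v = np.full((3, 3), np.nan)
        v[1, 1] = 0.69
        res = locate_peak(self._surface(v, 1), cc_threshold=0.7)
        assert not res.accepted
        assert res.cc_max == pytest.approx(0.69)

    def test_accepts_single_perfect_value(self):
        v = np.full((3, 3), np.nan)
        v[1, 1] = 1.0
        res = locate_peak(self._surface(v, 1))
        assert res.accepted and res.offset == (0, 0)

    def test_tie_breaks_row_major_first(self, rng):
        """Two equal maxima resolve to the first in row-major (y, x) scan,
        matching a brute-force argmax."""
        v = rng.random((5, 5)) * 0.5
        v[1, 3] = 0.9
        v[3, 0] = 0.9
        surf = self._surface(v, 2)
        iy, ix = next(
            (i, j) for i in range(5) for j in range(5) if v[i, j] == v.max()
        )
        assert surf.peak_offset == (ix - 2, iy - 2) == (1, -1)


class TestSubpixelPeak:
    def _surface_with_neighbors(self, c_minus, c0, c_plus):
        v = np.full((3, 3), np.nan)
        v[1, 0], v[1, 1], v[1, 2] = c_minus, c0, c_plus
        v[0, 1] = v[2, 1] = c0 - 0.2
        return CorrelationSurface(v, search_length=1)

    def test_symmetric_peak_has_zero_offset(self):
        surf = self._surface_with_neighbors(0.8, 1.0, 0.8)
        dx, dy = subpixel_peak(surf)
        assert dx == pytest.approx(0.0) and dy == pytest.approx(0.0)

    def test_asymmetric_peak_parabola_vertex(self):
        # vertex of the parabola through (-1, 0.5), (0, 1.0), (1, 0.7)
        surf = self._surface_with_neighbors(0.5, 1.0, 0.7)
        dx, _ = subpixel_peak(surf)
        assert dx == pytest.approx((0.5 - 0.7) / (2 * (0.5 - 2.0 + 0.7)))
        assert dx == pytest.approx(0.125)

    def test_missing_neighbor_leaves_axis_unrefined(self):
        v = np.full((3, 3), np.nan)
        v[1, 1], v[1, 2] = 1.0, 0.4
        v[0, 1], v[2, 1] = 0.8, 0.6
        dx, dy = subpixel_peak(CorrelationSurface(v, search_length=1))
        assert dx == 0.0
        assert dy != 0.0

    def test_offset_clamped_to_half_pixel(self):
        # nearly flat triple: raw vertex would exceed 0.5
        surf = self._surface_with_neighbors(0.9999, 1.0, 0.99999)
        dx, _ = subpixel_peak(surf)
        assert abs(dx) <= 0.5

    def test_fractional_bead_shift_recovered(self):
        """A 0.3 px scene shift is recovered within 0.1 px."""
        spec = SceneSpec(image_size=(200, 160), noise_sd=0.0)
        c0 = spec.initial_polygon
        f1 = render_frame(spec, c0)
        f2 = render_frame(spec, c0 + np.array([0.3, 0.0]))
        seq = FrameSequence(np.stack([f1, f2]).astype(np.float32), 90.0)
        tracks = track_markers(seq, np.round(c0), template_size=23, search_length=6)
        shifts = np.stack([t.positions[1] - t.positions[0] for t in tracks])
        assert np.all(np.abs(shifts[:, 0] - 0.3) < 0.1)
        assert np.all(np.abs(shifts[:, 1]) < 0.1)


class TestTrackMarkers:
    def test_static_scene_positions_stationary(self, static_scene):
        """Identical frames: every marker is tracked everywhere and sits
        still. The quadratic interpolator can shift a perfect integer match
        by a small constant (its neighbors need not be symmetric), so the
        position is constant from frame 2 on and within 0.05 px of the
        start."""
        spec, seq, truth = static_scene
        init = np.round(truth.centers[0])
        tracks = track_markers(seq, init, template_size=15, search_length=6)
        for t in tracks:
            assert all(s == "tracked" for s in t.status)
            assert np.allclose(t.positions[1:], t.positions[1], atol=1e-12)
            assert np.abs(t.positions - t.positions[0]).max() < 0.05

    def test_integer_translation_recovered(self, static_scene):
        """Frame k = frame 1 rolled by (k-1)*(1, 2) px; recovered positions
        follow within 0.1 px (translation equivariance of the tracker)."""
        spec, seq, truth = static_scene
        base = seq.frames[0]
        frames = np.stack([
            np.roll(np.roll(base, k * 2, axis=0), k * 1, axis=1) for k in range(8)
        ])
        moved = FrameSequence(frames, 90.0)
        init = np.round(truth.centers[0])
        tracks = track_markers(moved, init, template_size=15, search_length=6)
        for t in tracks:
            for k in range(8):
                expected = t.positions[0] + k * np.array([1.0, 2.0])
                assert np.allclose(t.positions[k], expected, atol=0.1)

    def test_occluded_bead_goes_lost_others_unaffected(self):
        """Erasing one bead from frame 5 on drives its correlation below
        0.7 and flags it lost; the remaining markers keep tracking."""
        spec = SceneSpec(image_size=(200, 160), n_frames=9, noise_sd=0.005,
                         growth_rate_percent_per_hour=0.0,
                         occlusions=[(2, 5)], seed=11)
        from leaftrack import generate_sequence
        seq, truth = generate_sequence(spec)
        tracks = track_markers(seq, np.round(truth.centers[0]),
                               template_size=15, search_length=6)
        by_id = {t.marker_id: t for t in tracks}
        assert all(s == "lost" for s in by_id[2].status[4:])
        assert all(s == "tracked" for s in by_id[2].status[:4])
        assert np.all(np.nan_to_num(by_id[2].cc_history[4:]) < 0.7)
        for mid in (1, 3, 4, 5):
            assert all(s == "tracked" for s in by_id[mid].status)

    def test_lost_position_carried_forward(self):
        spec = SceneSpec(image_size=(200, 160), n_frames=6, noise_sd=0.0,
                         growth_rate_percent_per_hour=0.0,
                         occlusions=[(1, 3)], seed=2)
        from leaftrack import generate_sequence
        seq, truth = generate_sequence(spec)
        tracks = track_markers(seq, np.round(truth.centers[0]),
                               template_size=15, search_length=6)
        t = next(tr for tr in tracks if tr.marker_id == 1)
        assert np.allclose(t.positions[2:], t.positions[2])

    def test_determinism_bit_identical(self, small_scene):
        spec, seq, truth = small_scene
        init = np.round(truth.centers[0])
        a = track_markers(seq, init, template_size=15, search_length=6)
        b = track_markers(seq, init, template_size=15, search_length=6)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)
            assert ta.status == tb.status

    def test_requires_three_markers(self, static_scene):
        _, seq, truth = static_scene
        with pytest.raises(ValueError, match="3 markers"):
            track_markers(seq, truth.centers[0][:2])

    def test_search_length_larger_than_marker_spacing_warns(self, static_scene):
        _, seq, truth = static_scene
        two = FrameSequence(seq.frames[:2], seq.interval_seconds)
        init = np.round(truth.centers[0])
        # pentagon side is ~56 px here, so L=60 overlaps neighboring beads
        with pytest.warns(UserWarning, match="search_length"):
            track_markers(two, init, template_size=15, search_length=60)
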