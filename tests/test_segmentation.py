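"""Integral image, adaptive binarisation, morphology, candidates, tracks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usvkit.segmentation import (BinaryMask, adaptive_binarize,
                                 detect_harmonic, extract_candidates,
                                 integral_image, refine_morphology,
                                 render_candidate_image, summarize_tracks)
from usvkit.spectrogram import GrayImage
from tests.conftest import make_spec


def brute_rect_sum(img, r1, c1, r2, c2):
    return img[r1:r2 + 1, c1:c2 + 1].sum()


def brute_local_mean(img, s):
    """Naive sliding-window mean with border truncation."""
    h, w = img.shape
    half = s // 2
    out = np.empty_like(img, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            r1, r2 = max(r - half, 0), min(r + half, h - 1)
            c1, c2 = max(c - half, 0), min(c + half, w - 1)
            out[r, c] = img[r1:r2 + 1, c1:c2 + 1].mean()
    return out


class TestIntegralImage:
    def test_ones_closed_form(self):
        ii = integral_image(np.ones((3, 4)))
        assert ii.summed[2, 3] == 12
        for x in range(3):
            for y in range(4):
                assert ii.summed[x, y] == (x + 1) * (y + 1)

    def test_single_pixel(self):
        ii = integral_image(np.array([[3.5]]))
        assert ii.summed[0, 0] == 3.5

    def test_exhaustive_rectangles_match_bruteforce(self, rng):
        img = rng.integers(0, 100, size=(5, 5)).astype(float)
        ii = integral_image(img)
        for r1 in range(5):
            for c1 in range(5):
                for r2 in range(r1, 5):
                    for c2 in range(c1, 5):
                        assert ii.rect_sum(r1, c1, r2, c2) == \
                            brute_rect_sum(img, r1, c1, r2, c2)

    @given(st.integers(0, 2 ** 31))
    @settings(max_examples=30, deadline=None)
    def test_rectangle_sums_integer_exact(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 1000, size=(8, 11)).astype(float)
        ii = integral_image(img)
        r1, r2 = sorted(rng.integers(0, 8, 2))
        c1, c2 = sorted(rng.integers(0, 11, 2))
        assert ii.rect_sum(r1, c1, r2, c2) == brute_rect_sum(img, r1, c1, r2, c2)


class TestAdaptiveBinarize:
    def test_constant_image_all_background(self):
        img = GrayImage(np.full((20, 20), 0.4))
        assert not adaptive_binarize(img, s=5).mask.any()

    def test_bright_block_detected(self):
        bright = np.zeros((40, 40))
        bright[18:23, 18:23] = 1.0
        img = GrayImage(bright, polarity="signal_high")
        mask = adaptive_binarize(img, t=0.2, s=15).mask
        assert mask[18:23, 18:23].all()
        assert not mask[:3].any() and not mask[-3:].any()

    def test_matches_naive_sliding_window(self, rng):
        """Integral-image path equals brute-force window averaging."""
        for trial in range(8):
            dark = rng.random((17 + trial, 23))
            img = GrayImage(dark)
            s = 5 if trial % 2 else 7
            mask = adaptive_binarize(img, t=0.2, s=s).mask
            expected = dark <= 0.8 * brute_local_mean(dark, s)
            np.testing.assert_array_equal(mask, expected)

    def test_polarity_equivalence(self, rng):
        dark = rng.random((20, 20))
        a = adaptive_binarize(GrayImage(dark), s=7).mask
        b = adaptive_binarize(GrayImage(1 - dark, polarity="signal_high"), s=7).mask
        np.testing.assert_array_equal(a, b)

    def test_neighbourhood_too_large(self):
        img = GrayImage(np.random.default_rng(0).random((10, 10)))
        with pytest.raises(ValueError, match="larger than image"):
            adaptive_binarize(img, s=11)

    def test_even_neighbourhood_rejected(self):
        img = GrayImage(np.random.default_rng(0).random((20, 20)))
        with pytest.raises(ValueError, match="odd"):
            adaptive_binarize(img, s=6)


class TestRefineMorphology:
    def test_isolated_pixel_removed(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 10] = True
        assert not refine_morphology(BinaryMask(m)).mask.any()

    def test_large_block_survives_and_grows(self):
        m = np.zeros((30, 30), dtype=bool)
        m[10:20, 10:20] = True
        out = refine_morphology(BinaryMask(m)).mask
        assert out[10:20, 10:20].all()
        assert out.sum() >= m.sum()

    def test_small_component_size_rule(self):
        """Components under 60 px after the vertical dilation are dropped.

        Full-height blocks make the vertical dilation a no-op, so the size
        at the filtering step is exact: 10x5 = 50 px (removed), 10x6 = 60 px
        (kept, the rule is strictly '< 60 removed').
        """
        removed = np.zeros((10, 40), dtype=bool)
        removed[:, 5:10] = True
        assert not refine_morphology(BinaryMask(removed)).mask.any()
        kept = np.zeros((10, 40), dtype=bool)
        kept[:, 5:11] = True
        assert refine_morphology(BinaryMask(kept)).mask.any()


class TestExtractCandidates:
    def _mask_with_blobs(self, spans, shape=(30,400)):
        m = np.zeros(shape, dtype=bool)
        for c1, c2, r1, r2 in spans:
            m[r1:r2, c1:c2] = True
        return BinaryMask(m)

    def test_merge_below_10ms(self):
        # frame dt is 0.512 ms: 5 ms gap ~ 10 cols
        spec = make_spec(np.zeros((30, 400)))
        mask = self._mask_with_blobs([(50, 60, 5, 10), (70, 80, 15, 20)])
        cands = extract_candidates(mask, spec)
        assert len(cands) == 1
        assert len(cands[0].components) == 2

    def test_no_merge_above_10ms(self):
        spec = make_spec(np.zeros((30, 400)))
        # 15 ms gap ~ 30 cols
        mask = self._mask_with_blobs([(50, 60, 5, 10), (90, 100, 5, 10)])
        assert len(extract_candidates(mask, spec)) == 2

    def test_transitive_merge_chain(self):
        spec = make_spec(np.zeros((30, 400)))
        # three blobs with ~6 ms (12-col) gaps merge into one candidate
        mask = self._mask_with_blobs([(50, 60, 5, 10), (72, 82, 5, 10),
                                      (94, 104, 5, 10)])
        cands = extract_candidates(mask, spec)
        assert len(cands) == 1
        assert len(cands[0].components) == 3

    def test_merge_is_order_independent_closure(self, rng):
        """Greedy sorted merging equals a union-find closure oracle."""
        spec = make_spec(np.zeros((20, 600)))
        spans = []
        col = 10
        while col < 550:
            width = int(rng.integers(4, 15))
            spans.append((col, col + width, 4, 9))
            col += width + int(rng.integers(2, 40))
        mask = self._mask_with_blobs(spans, shape=(20, 600))
        cands = extract_candidates(mask, spec)

        # oracle: pairwise closure over blob time spans
        t = spec.time_axis_s
        intervals = [(t[c1], t[c2 - 1]) for c1, c2, _, _ in spans]
        n = len(intervals)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                a, b = intervals[i], intervals[j]
                gap = max(b[0] - a[1], a[0] - b[1])
                if gap < 0.010:
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(n)})
        assert len(cands) == n_groups

    def test_empty_mask(self):
        spec = make_spec(np.zeros((30, 400)))
        assert extract_candidates(BinaryMask(np.zeros((30, 400), dtype=bool)),
                                  spec) == []

    def test_candidates_sorted_by_start(self, rng):
        spec = make_spec(np.zeros((20, 600)))
        mask = self._mask_with_blobs([(500, 520, 5, 10), (50, 70, 5, 10),
                                      (300, 320, 5, 10)], shape=(20, 600))
        starts = [c.start_s for c in extract_candidates(mask, spec)]
        assert starts == sorted(starts)


class TestSummarizeTracks:
    def _flat_candidate(self, n_cols=24, row=50, level=-40.0):
        power = np.full((100, 200), -90.0)
        power[row, 30:30 + n_cols] = level
        spec = make_spec(power)
        mask = np.zeros_like(power, dtype=bool)
        mask[row, 30:30 + n_cols] = True
        cands = extract_candidates(BinaryMask(mask), spec)
        return summarize_tracks(cands[0], spec), spec

    def test_flat_call_track_frequency(self):
        cand, spec = self._flat_candidate()
        target = spec.freq_axis_hz[50]
        assert np.all(np.abs(cand.track_freq_hz - target) <= spec.freq_step_hz)

    def test_track_point_count_for_12ms(self):
        # 24 columns at 0.512 ms span ~11.78 ms -> 24 half-ms bins
        cand, _ = self._flat_candidate(n_cols=24)
        assert cand.track_time_s.size == 24

    def test_intensity_monotone_in_level(self):
        loud, _ = self._flat_candidate(level=-30.0)
        quiet, _ = self._flat_candidate(level=-50.0)
        assert np.mean(loud.track_intensity_db) > np.mean(quiet.track_intensity_db)

    def test_empty_bins_interpolated(self):
        power = np.full((100, 200), -90.0)
        power[50, 30:40] = -40.0
        power[50, 50:60] = -40.0
        spec = make_spec(power)
        mask = np.zeros_like(power, dtype=bool)
        mask[50, 30:40] = mask[50, 50:60] = True
        cand = summarize_tracks(extract_candidates(BinaryMask(mask), spec)[0], spec)
        assert not cand.track_observed.all()
        assert np.all(np.isfinite(cand.track_freq_hz))


class TestDetectHarmonic:
    def _spec_with(self, blocks):
        """blocks: (row0, row1, col0, col1, level) rectangles of power."""
        power = np.full((320, 300), -90.0)
        mask = np.zeros_like(power, dtype=bool)
        for r0, r1, c0, c1, level in blocks:
            power[r0:r1, c0:c1] = level
            mask[r0:r1, c0:c1] = True
        spec = make_spec(power)
        cands = extract_candidates(BinaryMask(mask), spec)
        assert len(cands) == 1
        cand = summarize_tracks(cands[0], spec)
        return detect_harmonic(cand, spec), spec

    def test_single_component_not_harmonic(self):
        cand, _ = self._spec_with([(50, 54, 30, 90, -40.0)])
        assert cand.harmonic is False

    def test_cotemporal_weaker_octave_band_is_harmonic(self):
        # main ridge near 57.7 kHz (rows 50-54); octave near 115.4 kHz
        cand, spec = self._spec_with([(50, 54, 30, 90, -40.0),
                                      (286, 290, 32, 88, -50.0)])
        assert cand.harmonic is True
        assert cand.harmonic_track is not None
        # main track excludes the overtone
        assert np.all(cand.track_freq_hz < spec.freq_axis_hz[100])

    def test_time_disjoint_components_not_harmonic(self):
        # two notes merged by the 10 ms rule but disjoint in time
        cand, _ = self._spec_with([(50, 54, 30, 60, -40.0),
                                   (80, 84, 65, 95, -40.0)])
        assert cand.harmonic is False

    def test_equal_loudness_band_not_harmonic(self):
        # co-temporal octave band at equal level: clutter, not an overtone
        cand, _ = self._spec_with([(50, 54, 30, 90, -40.0),
                                   (286, 290, 32, 88, -40.5)])
        assert cand.harmonic is False

    def test_non_octave_band_not_harmonic(self):
        # a weaker band at 1.4x the main frequency is not an overtone
        cand, _ = self._spec_with([(50, 54, 30, 90, -40.0),
                                   (150, 154, 32, 88, -50.0)])
        assert cand.harmonic is False


class TestRenderCandidateImage:
    def _candidate(self, col0=200, n_cols=40):
        power = np.full((120, 1000), -90.0)
        power[60, col0:col0 + n_cols] = -40.0
        spec = make_spec(power)
        mask = np.zeros_like(power, dtype=bool)
        mask[60, col0:col0 + n_cols] = True
        return extract_candidates(BinaryMask(mask), spec)[0], spec

    def test_output_shape(self):
        cand, spec = self._candidate()
        img = render_candidate_image(cand, spec)
        assert img.pixels227.shape == (227, 227)
        assert 0.0 <= img.pixels227.min() and img.pixels227.max() <= 1.0

    def test_edge_candidate_padded(self):
        cand, spec = self._candidate(col0=2, n_cols=20)
        img = render_candidate_image(cand, spec)
        assert img.pixels227.shape == (227, 227)

    def test_candidate_horizontally_centred(self):
        cand, spec = self._candidate()
        img = render_candidate_image(cand, spec)
        # the call is the brightest structure; its column centroid should sit
        # at the window centre
        col_profile = img.pixels227.max(axis=0)
        cols = np.flatnonzero(col_profile > 0.5 * col_profile.max())
        center = 0.5 * (cols.min() + cols.max())
        assert abs(center - 113) <= 1.5
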