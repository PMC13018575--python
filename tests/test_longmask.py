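"""Scanning-window mask generator: reduction, moments, selection, expansion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carotidseg as cs
from carotidseg import InvalidRegionError, PixelBox
from carotidseg.longmask import (
    MaskGenConfig,
    WindowStats,
    expand_and_validate,
    generate_longitudinal_mask,
    reduce_center_box,
    scan_windows,
    select_best,
)


class TestReduceCenterBox:
    def test_sixty_percent_example(self):
        assert reduce_center_box(PixelBox(0, 0, 100, 50), 0.6) == PixelBox(20, 10, 60, 30)

    def test_factor_one_is_identity(self):
        box = PixelBox(4, 9, 33, 21)
        assert reduce_center_box(box, 1.0) == box

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_center_preserved_within_rounding(self, data):
        left = data.draw(st.integers(0, 50))
        top = data.draw(st.integers(0, 50))
        w = data.draw(st.integers(5, 120))
        h = data.draw(st.integers(5, 120))
        factor = data.draw(st.floats(0.3, 1.0))
        box = PixelBox(left, top, w, h)
        out = reduce_center_box(box, factor)
        assert abs(out.center[0] - box.center[0]) <= 1.0
        assert abs(out.center[1] - box.center[1]) <= 1.0

    def test_too_small_result_raises(self):
        with pytest.raises(InvalidRegionError):
            reduce_center_box(PixelBox(0, 0, 20, 20), 0.5, min_size=30)


class TestScanWindows:
    def test_uniform_dark_region_all_candidates(self):
        img = np.full((60, 80), 40, dtype=np.uint8)
        stats = scan_windows(img, PixelBox(0, 0, 80, 60))
        assert stats and all(s.is_candidate for s in stats)
        assert all(s.mu == 40 and s.sigma == 0 for s in stats)

    def test_uniform_bright_region_no_candidates(self):
        img = np.full((60, 80), 200, dtype=np.uint8)
        stats = scan_windows(img, PixelBox(0, 0, 80, 60))
        assert stats and not any(s.is_candidate for s in stats)

    def test_moments_match_brute_force(self, rng):
        img = rng.integers(0, 256, (50, 70), dtype=np.uint8)
        cfg = MaskGenConfig(win=10, step=7)
        region = PixelBox(3, 5, 40, 35)
        stats = scan_windows(img, region, cfg)
        # brute-force double loop over all offsets
        offs_t = list(range(5, 5 + 35 - 10 + 1, 7)) + [5 + 35 - 10]
        offs_l = list(range(3, 3 + 40 - 10 + 1, 7)) + [3 + 40 - 10]
        expected = []
        for t in sorted(set(offs_t)):
            for l in sorted(set(offs_l)):
                patch = img[t : t + 10, l : l + 10].astype(float)
                expected.append((l, t, patch.mean(), patch.std()))
        assert len(stats) == len(expected)
        for s, (l, t, mu, sigma) in zip(stats, expected):
            assert (s.window.left, s.window.top) == (l, t)
            assert s.mu == pytest.approx(mu)
            assert s.sigma == pytest.approx(sigma)

    def test_region_smaller_than_window_raises(self):
        img = np.zeros((60, 60), dtype=np.uint8)
        with pytest.raises(InvalidRegionError):
            scan_windows(img, PixelBox(0, 0, 20, 20))


class TestSelectBest:
    def _ws(self, left, top, mu, sigma):
        return WindowStats(PixelBox(left, top, 30, 30), mu, sigma, True)

    def test_minimum_score_wins(self):
        best = select_best([self._ws(0, 0, 30, 10), self._ws(5, 5, 20, 5)])
        assert best.score == 25

    def test_tie_broken_topmost_leftmost(self):
        a = self._ws(10, 5, 20, 5)
        b = self._ws(5, 5, 20, 5)
        c = self._ws(0, 10, 20, 5)
        assert select_best([a, b, c]).window == b.window

    def test_finds_dark_homogeneous_patch(self, rng):
        # one dark uniform 30x30 patch in a bright speckled field
        img = rng.integers(150, 256, (100, 140)).astype(np.uint8)
        img[40:70, 60:90] = 30
        stats = scan_windows(img, PixelBox(0, 0, 140, 100))
        best = select_best([s for s in stats if s.is_candidate])
        assert best.window == PixelBox(60, 40, 30, 30)


class TestExpandAndValidate:
    def test_quadruple_width_recentered(self):
        img = np.zeros((200, 300), dtype=np.uint8)
        best = WindowStats(PixelBox(50, 40, 30, 30), 0.0, 0.0, True)
        roi = PixelBox(40, 0, 120, 200)  # center x = 100
        out, ok = expand_and_validate(img, best, roi)
        assert ok
        assert out == PixelBox(40, 40, 120, 30)

    def test_clipped_at_left_edge(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        best = WindowStats(PixelBox(0, 10, 30, 30), 0.0, 0.0, True)
        roi = PixelBox(0, 0, 40, 100)  # center x = 20 -> candidate spills left
        out, ok = expand_and_validate(img, best, roi)
        assert ok
        assert out.left == 0 and out.width < 120

    def test_reverts_when_expansion_hits_bright_tissue(self):
        img = np.full((100, 300), 200, dtype=np.uint8)
        img[40:70, 50:80] = 20  # only the seed is dark
        best = WindowStats(PixelBox(50, 40, 30, 30), 20.0, 0.0, True)
        roi = PixelBox(0, 0, 300, 100)
        out, ok = expand_and_validate(img, best, roi)
        assert not ok
        assert out == best.window


class TestGenerateMask:
    def test_decoy_rejected_and_mask_inside_lumen(self, longitudinal_phantom):
        img, truth, spec = longitudinal_phantom
        masks = cs.region_masks(spec)
        roi = cs.oracle_detector(truth | masks["decoy"])
        res = generate_longitudinal_mask(img, roi)
        assert not (res.mask & masks["decoy"]).any()
        assert (res.mask & truth).sum() == res.mask.sum()  # fully inside lumen
        assert not res.fallback

    def test_noise_free_chain_is_deterministic_expansion(self):
        import math

        spec = cs.default_longitudinal_spec(seed=0)
        spec = cs.PhantomSpec(**{**spec.__dict__, "speckle_looks": math.inf})
        img, truth = cs.make_phantom(spec)
        masks = cs.region_masks(spec)
        roi = cs.oracle_detector(truth | masks["decoy"])
        res = generate_longitudinal_mask(img, roi)
        assert res.expanded
        assert res.window.width == 4 * 30
        assert res.window.height == 30

    def test_all_bright_image_falls_back(self):
        img = np.full((160, 224), 220, dtype=np.uint8)
        res = generate_longitudinal_mask(img, PixelBox(10, 10, 200, 140))
        assert res.fallback
        assert res.n_candidates == 0
        assert res.mask.any()

    def test_end_to_end_determinism(self, longitudinal_phantom):
        img, truth, spec = longitudinal_phantom
        roi = cs.oracle_detector(truth)
        a = generate_longitudinal_mask(img, roi)
        b = generate_longitudinal_mask(img, roi)
        assert np.array_equal(a.mask, b.mask)
        assert a.diagnostics() == b.diagnostics()


def test_decoy_rejection_rate_over_seeds():
    """Over many seeded decoy phantoms the generated mask centers in the
    carotid band, not the jugular-like decoy."""
    hits = 0
    n = 25
    for seed in range(n):
        spec = cs.default_longitudinal_spec(seed=seed)
        img, truth = cs.make_phantom(spec)
        masks = cs.region_masks(spec)
        roi = cs.oracle_detector(truth | masks["decoy"])
        res = generate_longitudinal_mask(img, roi)
        cy = int(round(res.window.center[1]))
        band = spec.lumen_geometry
        hits += band.top <= cy < band.bottom
    assert hits / n >= 0.95
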