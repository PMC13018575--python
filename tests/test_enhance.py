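"""Enhancement stages vs direct brute-force oracles, and the quality metrics."""

import numpy as np
import pytest

from carotidseg import enhance as enh


def brute_bilateral(img, sigma_s, sigma_r):
    """Literal double-loop evaluation of the bilateral weighted average."""
    f = img.astype(np.float64)
    radius = max(1, int(np.ceil(3.0 * sigma_s)))
    p = np.pad(f, radius, mode="reflect")
    h, w = f.shape
    out = np.empty_like(f)
    for y in range(h):
        for x in range(w):
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    z = p[y + radius + dy, x + radius + dx]
                    wgt = np.exp(-(dx * dx + dy * dy) / (2 * sigma_s**2)) * np.exp(
                        -((f[y, x] - z) ** 2) / (2 * sigma_r**2)
                    )
                    num += wgt * z
                    den += wgt
            out[y, x] = num / den
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def brute_nlm(img, search, patch, h):
    """Literal per-pixel non-local means with reflect padding."""
    f = img.astype(np.float64)
    H, W = f.shape
    sr, pr = search // 2, patch // 2
    pad = sr + pr
    p = np.pad(f, pad, mode="reflect")
    out = np.empty_like(f)
    for y in range(H):
        for x in range(W):
            cy, cx = y + pad, x + pad
            ref = p[cy - pr : cy + pr + 1, cx - pr : cx + pr + 1]
            num = den = 0.0
            for dy in range(-sr, sr + 1):
                for dx in range(-sr, sr + 1):
                    q = p[cy + dy - pr : cy + dy + pr + 1,
                          cx + dx - pr : cx + dx + pr + 1]
                    d2 = np.mean((ref - q) ** 2)
                    wgt = np.exp(-d2 / h**2)
                    num += wgt * p[cy + dy, cx + dx]
                    den += wgt
            out[y, x] = num / den
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


class TestToGray:
    def test_gray_replicated_identity(self, rng):
        g = rng.integers(0, 256, (10, 12), dtype=np.uint8)
        rgb = np.repeat(g[:, :, None], 3, axis=2)
        assert np.array_equal(enh.to_gray(rgb), g)

    def test_pure_white(self):
        assert enh.to_gray(np.full((2, 2, 3), 255, dtype=np.uint8)).max() == 255

    def test_matches_luma_oracle(self, rng):
        rgb = rng.integers(0, 256, (8, 9, 3), dtype=np.uint8)
        f = rgb.astype(np.float64)
        oracle = np.rint(0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2])
        assert np.array_equal(enh.to_gray(rgb), oracle.astype(np.uint8))

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            enh.to_gray(np.zeros((4, 4, 2), dtype=np.uint8))


class TestBilateral:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 77, dtype=np.uint8)
        assert np.array_equal(enh.bilateral(img, 2.0, 20.0), img)

    def test_large_sigma_r_limit_is_gaussian_blur(self, rng):
        from scipy import ndimage

        img = rng.integers(0, 256, (9, 9), dtype=np.uint8)
        out = enh.bilateral(img, 1.0, 1e6)
        blur = ndimage.gaussian_filter(
            img.astype(float), 1.0, mode="mirror", truncate=3.0
        )
        assert np.max(np.abs(out.astype(float) - blur)) <= 1.0

    def test_matches_double_loop_oracle(self, rng):
        img = rng.integers(0, 256, (5, 5), dtype=np.uint8)
        out = enh.bilateral(img, 1.5, 25.0)
        oracle = brute_bilateral(img, 1.5, 25.0)
        assert np.max(np.abs(out.astype(int) - oracle.astype(int))) <= 1


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((64, 64), 100, dtype=np.uint8)
        out = enh.clahe(img)
        assert np.unique(out).size == 1

    def test_contrast_gain_on_low_contrast_ramp(self):
        ramp = np.tile(np.linspace(100, 130, 64).astype(np.uint8), (64, 1))
        out = enh.clahe(ramp, tiles=(4, 4), clip_limit=0.5)
        assert out.astype(float).std() > ramp.astype(float).std()

    def test_single_tile_unclipped_equals_global_equalization(self, rng):
        img = rng.integers(0, 200, (32, 32), dtype=np.uint8)
        out = enh.clahe(img, tiles=(1, 1), clip_limit=1.0)
        hist = np.bincount(img.ravel(), minlength=256)
        cdf = np.cumsum(hist) / img.size
        lut = np.clip(np.rint(255.0 * cdf), 0, 255).astype(np.uint8)
        assert np.array_equal(out, lut[img])

    def test_image_smaller_than_grid_rejected(self):
        with pytest.raises(ValueError):
            enh.clahe(np.zeros((4, 4), dtype=np.uint8), tiles=(8, 8))


class TestGamma:
    def test_identity_at_gamma_one(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        assert np.array_equal(enh.gamma_correct(img, 1.0, 1.0), img)

    def test_endpoints_fixed(self):
        img = np.array([[0, 255]], dtype=np.uint8)
        out = enh.gamma_correct(img, 1.2)
        assert out[0, 0] == 0 and out[0, 1] == 255

    def test_midpoint_closed_form(self):
        # normalized 0.5 maps to 0.5**1.2 before rescaling
        img = np.full((4, 4), 128, dtype=np.uint8)
        expect = round(255 * (128 / 255) ** 1.2)
        assert enh.gamma_correct(img, 1.2)[0, 0] == expect

    def test_monotone(self, rng):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = enh.gamma_correct(img, 1.7).ravel()[np.argsort(img.ravel())]
        assert np.all(np.diff(out.astype(int)) >= 0)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            enh.gamma_correct(np.zeros((4, 4), dtype=np.uint8), gamma=0)


class TestNlm:
    def test_constant_image_unchanged(self):
        img = np.full((11, 11), 42, dtype=np.uint8)
        assert np.array_equal(enh.nlm(img, 7, 3, 10.0), img)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.integers(0, 256, (7, 7), dtype=np.uint8)
        out = enh.nlm(img, search=5, patch=3, h=30.0)
        oracle = brute_nlm(img, 5, 3, 30.0)
        assert np.max(np.abs(out.astype(int) - oracle.astype(int))) <= 1

    def test_small_h_limit_is_identity(self, rng):
        img = rng.integers(0, 256, (9, 9), dtype=np.uint8)
        out = enh.nlm(img, search=5, patch=3, h=1e-3)
        assert np.array_equal(out, img)

    def test_even_windows_rejected(self):
        with pytest.raises(ValueError):
            enh.nlm(np.zeros((9, 9), dtype=np.uint8), search=6, patch=3)


class TestHighBoost:
    def test_alpha_zero_is_identity(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        assert np.array_equal(enh.high_boost(img, alpha=0.0), img)

    def test_constant_unchanged(self):
        img = np.full((12, 12), 90, dtype=np.uint8)
        assert np.array_equal(enh.high_boost(img, alpha=3.0), img)

    def test_sharpens_step_edge(self):
        img = np.zeros((24, 24), dtype=np.uint8)
        img[:, 12:] = 200
        assert enh.mgm(enh.high_boost(img)) > enh.mgm(img)


class TestQualityMetrics:
    def test_constant_image_zeros(self):
        img = np.full((16, 16), 50, dtype=np.uint8)
        assert enh.entropy(img) == 0.0
        assert enh.global_std(img) == 0.0
        assert enh.mgm(img) == 0.0

    def test_two_level_entropy_is_one_bit(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:8] = 255
        assert enh.entropy(img) == pytest.approx(1.0)

    def test_half_black_half_white_std(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:8] = 255
        assert enh.global_std(img) == pytest.approx(127.5)


class TestPipeline:
    @pytest.mark.parametrize(
        "stage",
        [
            lambda x: enh.bilateral(x, 2.0, 40.0),
            lambda x: enh.clahe(x, (4, 4), 0.02),
            lambda x: enh.gamma_correct(x, 1.2),
            lambda x: enh.nlm(x, 7, 3, 20.0),
            lambda x: enh.high_boost(x, 1.5, 2.0),
        ],
        ids=["bilateral", "clahe", "gamma", "nlm", "highboost"],
    )
    def test_every_stage_preserves_8bit_range(self, stage, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        out = stage(img)
        assert out.dtype == np.uint8
        assert out.min() >= 0 and out.max() <= 255

    def test_deterministic(self, transverse_phantom):
        img, _, _ = transverse_phantom
        small = img[60:124, 60:124]
        a, ra = enh.enhance_pipeline(small)
        b, rb = enh.enhance_pipeline(small)
        assert np.array_equal(a, b)
        assert ra == rb

    def test_reports_before_and_after(self, transverse_phantom):
        img, _, _ = transverse_phantom
        out, report = enh.enhance_pipeline(img[60:124, 60:124])
        assert out.shape == (64, 64)
        assert 0 <= report.before.entropy <= 8
        assert 0 <= report.after.entropy <= 8
        rows = report.to_rows("img0")
        assert {r["metric"] for r in rows} == {"entropy", "std", "mgm"}

    def test_denoises_lumen_interior(self, transverse_phantom):
        # The chain's purpose: flatten speckle inside the lumen while keeping
        # the wall rim a strong edge for the contouring stage.
        img, mask, spec = transverse_phantom
        out, _ = enh.enhance_pipeline(img)
        core = mask.copy()
        core[:] = False
        e = spec.lumen_geometry
        y, x = np.mgrid[0 : spec.height, 0 : spec.width]
        core = ((x - e.cx) / (e.a - 6)) ** 2 + ((y - e.cy) / (e.b - 6)) ** 2 <= 1
        assert out[core].std() < img[core].std()
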