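import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longiharm import metrics
from longiharm.metrics import (
    SSIMConfig,
    average_hausdorff,
    cnr,
    cnr_difference_table,
    dice,
    lpips,
    psnr,
    ssim,
)

# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations of the formulas)
# ---------------------------------------------------------------------------


def _gaussian_kernel(size: int, sd: float) -> np.ndarray:
    r = (size - 1) // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(ax**2) / (2 * sd**2))
    return k / k.sum()


def ssim_sliding_oracle(x, y, cfg: SSIMConfig) -> float:
    """Explicit loop over all fully contained Gaussian-weighted windows."""
    k1d = _gaussian_kernel(cfg.window_size, cfg.gaussian_sd)
    w = k1d
    for _ in range(x.ndim - 1):
        w = np.multiply.outer(w, k1d)
    c1, c2 = cfg.c1, cfg.c2
    vals = []
    ranges = [range(s - cfg.window_size + 1) for s in x.shape]
    import itertools

    for idx in itertools.product(*ranges):
        sl = tuple(slice(i, i + cfg.window_size) for i in idx)
        wx, wy = x[sl].astype(np.float64), y[sl].astype(np.float64)
        mx = (w * wx).sum()
        my = (w * wy).sum()
        vx = (w * wx * wx).sum() - mx**2
        vy = (w * wy * wy).sum() - my**2
        cov = (w * wx * wy).sum() - mx * my
        vals.append(
            ((2 * mx * my + c1) * (2 * cov + c2))
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    return float(np.mean(vals))


def average_hausdorff_oracle(a, b, spacing=(1.0, 1.0)) -> float:
    """All-pairs distances between boundary voxels."""
    from scipy import ndimage

    def boundary(m):
        return np.argwhere(m & ~ndimage.binary_erosion(m)) * np.asarray(spacing)

    pa, pb = boundary(np.asarray(a, bool)), boundary(np.asarray(b, bool))
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return float((d.min(axis=1).mean() + d.min(axis=0).mean()) / 2.0)


class DoublingExtractor:
    """Deterministic two-layer test extractor: identity and 2x downsample."""

    def __call__(self, img):
        img = np.asarray(img, dtype=np.float64)
        half = img[::2, ::2]
        return [img[None], np.stack([half, 2 * half])]


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


class TestSSIM:
    def test_identical_images(self):
        x = np.random.default_rng(0).random((32, 32))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_constant_images_global_mode(self):
        cfg = SSIMConfig(window="global")
        a = np.full((8, 8), 0.2)
        b = np.full((8, 8), 0.4)
        # zero variances: (2*0.08 + 1e-4) / (0.2 + 1e-4); contrast term cancels
        expected = (2 * 0.2 * 0.4 + cfg.c1) / (0.2**2 + 0.4**2 + cfg.c1)
        assert ssim(a, b, cfg) == pytest.approx(expected)
        assert expected == pytest.approx(0.80010, abs=1e-5)

    def test_sliding_matches_brute_force_2d(self):
        rng = np.random.default_rng(1)
        x = rng.random((32, 32))
        y = np.clip(x + 0.1 * rng.standard_normal((32, 32)), 0, 1)
        cfg = SSIMConfig()
        assert ssim(x, y, cfg) == pytest.approx(ssim_sliding_oracle(x, y, cfg), abs=1e-6)

    def test_sliding_matches_brute_force_3d(self):
        rng = np.random.default_rng(2)
        x = rng.random((16, 16, 16))
        y = np.clip(x + 0.05 * rng.standard_normal(x.shape), 0, 1)
        cfg = SSIMConfig()
        assert ssim(x, y, cfg) == pytest.approx(ssim_sliding_oracle(x, y, cfg), abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((20, 20)), rng.random((20, 20))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_decreases_with_noise(self):
        rng = np.random.default_rng(4)
        x = rng.random((32, 32))
        vals = []
        for sd in (0.01, 0.05, 0.2):
            trials = [
                ssim(x, np.clip(x + sd * np.random.default_rng(s).standard_normal(x.shape), 0, 1))
                for s in range(5)
            ]
            vals.append(np.mean(trials))
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------


class TestPSNR:
    def test_identical_gives_inf(self):
        x = np.random.default_rng(0).random((8, 8))
        assert psnr(x, x) == np.inf

    def test_hand_values(self):
        x = np.zeros((10, 10))
        assert psnr(x, np.full_like(x, 0.1)) == pytest.approx(20.0)
        assert psnr(x, np.full_like(x, 0.5)) == pytest.approx(6.0206, abs=1e-4)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        x, y = rng.random((16, 16)), rng.random((16, 16))
        mse = np.mean((x - y) ** 2)
        assert psnr(x, y) == pytest.approx(10 * np.log10(1.0 / mse), abs=1e-12)

    def test_monotone_in_mse(self):
        x = np.zeros((8, 8))
        assert psnr(x, np.full_like(x, 0.1)) > psnr(x, np.full_like(x, 0.2))

    @given(shift=st.floats(-0.2, 0.2))
    @settings(max_examples=20, deadline=None)
    def test_joint_shift_invariance(self, shift):
        rng = np.random.default_rng(6)
        x, y = rng.random((8, 8)), rng.random((8, 8))
        assert psnr(x + shift, y + shift) == pytest.approx(psnr(x, y), rel=1e-9)

    def test_slicewise_agrees_with_volumewise_when_uniform(self):
        # every slice has equal MSE -> per-slice mean PSNR equals volume PSNR
        x = np.zeros((6, 6, 4))
        y = np.full_like(x, 0.25)
        slicewise = [psnr(x[:, :, k], y[:, :, k]) for k in range(4)]
        assert np.mean(slicewise) == pytest.approx(psnr(x, y))


# ---------------------------------------------------------------------------
# LPIPS
# ---------------------------------------------------------------------------


class TestLPIPS:
    def test_identical_is_zero(self):
        x = np.random.default_rng(0).random((8, 8))
        assert lpips(x, x, DoublingExtractor()) == 0.0

    def test_hand_value_single_layer_identity(self):
        extractor = lambda img: [np.asarray(img)[None]]
        x = np.zeros((2, 2))
        y = np.ones((2, 2))
        # (1 / (H*W)) * sum over 4 positions of ||1||^2 = (1/4) * 4
        assert lpips(x, y, extractor) == pytest.approx(1.0)

    def test_matches_printed_sum(self):
        rng = np.random.default_rng(7)
        x, y = rng.random((8, 8)), rng.random((8, 8))
        ex = DoublingExtractor()
        expected = 0.0
        for fx, fy in zip(ex(x), ex(y)):
            h, w = fx.shape[1:]
            expected += np.sum((fx - fy) ** 2) / (h * w)
        assert lpips(x, y, ex) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.random((8, 8)), rng.random((8, 8))
        ex = DoublingExtractor()
        assert lpips(x, y, ex) == pytest.approx(lpips(y, x, ex))


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------


class TestCNR:
    def _fixture(self):
        vol = np.zeros((10, 10))
        vol[:5] = 0.8  # ROI
        rng = np.random.default_rng(9)
        vol[5:] = 0.2 + 0.1 * rng.standard_normal((5, 10))
        roi = np.zeros_like(vol, bool)
        roi[:5] = True
        return vol, roi, ~roi

    def test_hand_value(self):
        vol = np.zeros((4, 4))
        vol[:2] = 0.8
        vol[2] = 0.1
        vol[3] = 0.3  # background mean 0.2, population sd 0.1
        roi = np.zeros_like(vol, bool)
        roi[:2] = True
        assert cnr(vol, roi, ~roi) == pytest.approx(6.0)

    def test_roi_equal_background_is_zero(self):
        vol, roi, bg = self._fixture()
        vol[roi] = vol[bg].mean()
        assert cnr(vol, roi, bg) == pytest.approx(0.0)

    def test_constant_background_rejected(self):
        vol = np.ones((4, 4))
        roi = np.zeros_like(vol, bool)
        roi[0] = True
        with pytest.raises(ValueError, match="constant background"):
            cnr(vol, roi, ~roi)

    def test_invariant_under_global_offset(self):
        vol, roi, bg = self._fixture()
        assert cnr(vol + 3.0, roi, bg) == pytest.approx(cnr(vol, roi, bg))

    def test_scales_inversely_with_background_sd(self):
        vol, roi, bg = self._fixture()
        base = cnr(vol, roi, bg)
        scaled = vol.copy()
        mu = vol[bg].mean()
        scaled[bg] = mu + 2.0 * (vol[bg] - mu)  # doubles sd, keeps means
        assert cnr(scaled, roi, bg) == pytest.approx(base / 2.0)

    def test_difference_table(self):
        vol, roi, bg = self._fixture()
        regions = {"top": roi, "left": np.zeros_like(roi)}
        regions["left"][:, :2] = True
        table = cnr_difference_table(vol, vol, regions, bg)
        assert len(table) == 2
        assert np.allclose(table["cnr_difference"], 0.0)

    def test_difference_table_composes(self):
        vol, roi, bg = self._fixture()
        other = vol * 1.1 + 0.02
        table = cnr_difference_table(vol, other, {"top": roi}, bg)
        expected = abs(cnr(vol, roi, bg) - cnr(other, roi, bg))
        assert table["cnr_difference"].iloc[0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Dice / Hausdorff
# ---------------------------------------------------------------------------


class TestOverlap:
    def test_dice_identical(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert dice(m, m) == 1.0

    def test_dice_disjoint(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_dice_half_overlap(self):
        a = np.zeros((20, 10), bool)
        b = np.zeros((20, 10), bool)
        a[:10] = True  # |A| = 100
        b[5:15] = True  # |B| = 100, overlap 50
        assert dice(a, b) == pytest.approx(0.5)

    def test_dice_both_empty(self):
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_dice_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            dice(np.arange(4).reshape(2, 2), np.zeros((2, 2)))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_dice_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)

    def test_hausdorff_identical_is_zero(self):
        m = np.zeros((8, 8), bool)
        m[3:6, 3:6] = True
        assert average_hausdorff(m, m, (1.0, 1.0)) == 0.0

    def test_hausdorff_single_voxels(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[2, 2] = True
        b[2, 5] = True
        assert average_hausdorff(a, b, (1.0, 1.0)) == pytest.approx(3.0)

    def test_hausdorff_matches_all_pairs_oracle(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[3:8, 3:8] = True
        b[6:11, 5:10] = True
        got = average_hausdorff(a, b, (1.0, 1.0))
        assert got == pytest.approx(average_hausdorff_oracle(a, b), abs=1e-9)

    def test_hausdorff_symmetric(self):
        rng = np.random.default_rng(10)
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        assert average_hausdorff(a, b) == pytest.approx(average_hausdorff(b, a))

    def test_hausdorff_empty_rejected(self):
        with pytest.raises(ValueError):
            average_hausdorff(np.zeros((4, 4), bool), np.ones((4, 4), bool))

    def test_hausdorff_max_mode_respects_spacing(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[2, 2] = True
        b[2, 5] = True
        assert average_hausdorff(a, b, (1.0, 2.0), symmetric_max=True) == pytest.approx(6.0)
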