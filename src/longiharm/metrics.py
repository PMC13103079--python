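"""Quantitative image-quality and overlap measures.

SSIM, PSNR, LPIPS (with an injected feature extractor), CNR and per-region
CNR-difference tables, Dice, and average Hausdorff distance. SSIM and PSNR
support both 2D slice-wise and full-3D volume-wise evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SSIMConfig",
    "ssim",
    "psnr",
    "PSNR_INF",
    "lpips",
    "cnr",
    "cnr_difference_table",
    "dice",
    "average_hausdorff",
    "MetricReport",
]

PSNR_INF = float("inf")


@dataclass(frozen=True)
class SSIMConfig:
    """SSIM stabilization constants and window mode.

    ``window="global"`` computes one statistic over the whole array;
    ``window="sliding"`` (default) averages the SSIM map over all fully
    contained Gaussian-weighted windows.
    """

    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    window: str = "sliding"
    window_size: int = 11
    gaussian_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.data_range <= 0:
            raise ValueError("data range must be positive")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("stabilization constants must be positive")
        if self.window not in ("global", "sliding"):
            raise ValueError(f"unknown window mode {self.window!r}")
        if self.window_size % 2 != 1:
            raise ValueError("window size must be odd")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def ssim(x: np.ndarray, y: np.ndarray, config: SSIMConfig | None = None) -> float:
    """Structural similarity between two equal-shape 2D or 3D arrays.

    Implements (2 mu_x mu_y + c1)(2 cov + c2) /
    ((mu_x^2 + mu_y^2 + c1)(var_x + var_y + c2)) with population variances.
    Sliding mode returns the mean over all fully contained windows, with
    Gaussian weights inside each window.
    """
    config = config or SSIMConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    c1, c2 = config.c1, config.c2

    if config.window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = ((x - mu_x) * (y - mu_y)).mean()
        return float(
            ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
            / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
        )

    # Sliding Gaussian window via separable filtering; interior (fully
    # contained windows) is exact regardless of the boundary mode, so filter
    # then crop the half-window border.
    truncate = ((config.window_size - 1) // 2) / config.gaussian_sd
    filt = lambda a: ndimage.gaussian_filter(
        a, sigma=config.gaussian_sd, truncate=truncate, mode="nearest"
    )
    pad = (config.window_size - 1) // 2
    if any(s < config.window_size for s in x.shape):
        raise ValueError(
            f"array shape {x.shape} smaller than SSIM window {config.window_size}"
        )
    mu_x, mu_y = filt(x), filt(y)
    mu_xx, mu_yy, mu_xy = filt(x * x), filt(y * y), filt(x * y)
    var_x = mu_xx - mu_x**2
    var_y = mu_yy - mu_y**2
    cov = mu_xy - mu_x * mu_y
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    crop = tuple(slice(pad, s - pad) for s in x.shape)
    return float(ssim_map[crop].mean())


def psnr(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(L^2 / MSE).

    For normalized inputs with L = 1 this equals 10 log10(L / MSE).
    Identical arrays return the +inf sentinel.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range <= 0:
        raise ValueError("data range must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return float(10.0 * np.log10(data_range**2 / mse))


def lpips(x: np.ndarray, y: np.ndarray, extractor) -> float:
    """Layer-wise perceptual distance with an injected feature extractor.

    ``extractor(image)`` must return a list of feature maps, each of shape
    (C_l, H_l, W_l). Returns sum_l (1 / (H_l W_l)) * sum_{h,w}
    ||phi_l(x)_{h,w} - phi_l(y)_{h,w}||_2^2.
    """
    feats_x = extractor(np.asarray(x))
    feats_y = extractor(np.asarray(y))
    if len(feats_x) != len(feats_y):
        raise ValueError("extractor returned differing layer counts")
    total = 0.0
    for fx, fy in zip(feats_x, feats_y):
        fx = np.asarray(fx, dtype=np.float64)
        fy = np.asarray(fy, dtype=np.float64)
        if fx.shape != fy.shape:
            raise ValueError("feature map shape mismatch between inputs")
        if not (np.all(np.isfinite(fx)) and np.all(np.isfinite(fy))):
            raise ValueError("extractor produced non-finite features")
        _, h, w = fx.shape if fx.ndim == 3 else (1,) + fx.shape
        total += float(np.sum((fx - fy) ** 2)) / (h * w)
    return total


def cnr(volume: np.ndarray, roi_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio: (mean(ROI) - mean(background)) / sd(background),
    with the population standard deviation over background voxels."""
    vol = np.asarray(volume, dtype=np.float64)
    roi = np.asarray(roi_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if roi.shape != vol.shape or bg.shape != vol.shape:
        raise ValueError("mask shape mismatch with volume")
    if not roi.any():
        raise ValueError("empty ROI mask")
    if not bg.any():
        raise ValueError("empty background mask")
    bg_vals = vol[bg]
    sd = float(bg_vals.std())  # population sd (ddof=0)
    if sd == 0.0:
        raise ValueError("constant background: CNR undefined")
    return float((vol[roi].mean() - bg_vals.mean()) / sd)


def cnr_difference_table(
    bl: np.ndarray,
    fu: np.ndarray,
    region_masks: dict[str, np.ndarray],
    background_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-region |CNR(bl) - CNR(fu)| table, one row per named region."""
    rows = []
    for name, mask in region_masks.items():
        c_bl = cnr(bl, mask, background_mask)
        c_fu = cnr(fu, mask, background_mask)
        rows.append(
            {"region": name, "cnr_bl": c_bl, "cnr_fu": c_fu, "cnr_difference": abs(c_bl - c_fu)}
        )
    return pd.DataFrame(rows)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); defined as 1 when both are empty."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    for m in (a, b):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1, True, False))):
            raise ValueError("dice requires binary masks")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded


def average_hausdorff(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0),
    symmetric_max: bool = False,
) -> float:
    """Symmetric mean nearest-boundary distance between two masks, in
    physical units. ``symmetric_max=True`` returns the classic (max)
    Hausdorff distance instead."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("average_hausdorff requires nonempty masks")
    ba, bb = _boundary(a), _boundary(b)
    spacing = tuple(spacing)[: a.ndim]
    dist_to_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    d_ab = dist_to_b[ba]
    d_ba = dist_to_a[bb]
    if symmetric_max:
        return float(max(d_ab.max(), d_ba.max()))
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


@dataclass
class MetricReport:
    """Per-item metric values for one comparison condition, with aggregates
    recomputable from the per-item values."""

    condition: str  # e.g. "BL-vs-originalFU" | "BL-vs-FU2BL" | "BL-vs-BL2FU2BL"
    granularity: str  # "slice" | "volume"
    values: dict[str, list[float]] = field(default_factory=dict)

    def add(self, metric: str, value: float) -> None:
        self.values.setdefault(metric, []).append(float(value))

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.values[metric]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, vals in self.values.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "condition": self.condition,
                        "granularity": self.granularity,
                        "item": i,
                        "metric": metric,
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)
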