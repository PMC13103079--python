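"""Volume-level inference, the histogram-matching baseline, the
three-condition evaluation harness, and the paired statistical tests."""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import metrics
from .gan import Generator
from .ioprep import (
    Volume,
    denormalize,
    extract_axial_slices,
    normalize_intensity,
    restack_slices,
)

__all__ = [
    "EvaluationRun",
    "harmonize_volume",
    "reconstruct_volume",
    "histogram_match",
    "evaluate_conditions",
    "wilcoxon_signed_rank",
    "paired_t_test",
    "write_report",
    "compare_conditions",
]

CONDITIONS = ("BL-vs-originalFU", "BL-vs-FU2BL", "BL-vs-BL2FU2BL")


@dataclass
class EvaluationRun:
    subjects: list[str]
    conditions: list[str]
    per_item: pd.DataFrame  # condition, granularity, subject, region, metric, value
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def aggregates(self) -> pd.DataFrame:
        finite = self.per_item[np.isfinite(self.per_item["value"])]
        g = finite.groupby(["condition", "granularity", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"std": "sd", "count": "n"})


def _translate_volume(volume: Volume, generators: list[Generator],
                      exclude_fraction: float, tag: str) -> Volume:
    norm, record = normalize_intensity(volume)
    stack = extract_axial_slices(norm, exclude_fraction)
    slices = stack.slices
    for g in generators:
        slices = g.translate_slices(slices)
    stack.slices = slices
    out = restack_slices(stack, norm)
    return Volume(denormalize(out, record).data, volume.spacing, volume.affine.copy(), tag)


def harmonize_volume(
    fu: Volume, generator_to_BL: Generator, exclude_fraction: float = 0.1
) -> Volume:
    """Translate each retained axial slice of a follow-up volume into the
    baseline domain, re-stack (excluded end slices pass through unchanged),
    and restore the original intensity range."""
    return _translate_volume(fu, [generator_to_BL], exclude_fraction, "harmonized")


def reconstruct_volume(
    bl: Volume,
    generator_to_FU: Generator,
    generator_to_BL: Generator,
    exclude_fraction: float = 0.1,
) -> Volume:
    """Round-trip a baseline volume BL→FU→BL slice-wise."""
    return _translate_volume(
        bl, [generator_to_FU, generator_to_BL], exclude_fraction, "reconstructed"
    )


def histogram_match(
    source: Volume, reference: Volume, n_bins: int = 256,
    mask: np.ndarray | None = None,
) -> Volume:
    """Monotone quantile mapping of source intensities onto the reference's
    empirical distribution.

    Quantiles are estimated over all voxels by default; pass ``mask`` (e.g.
    a head mask) to estimate them over a sub-region while still remapping
    the full volume.
    """
    src = np.asarray(source.data, dtype=np.float64)
    ref = np.asarray(reference.data, dtype=np.float64)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        src_vals, ref_vals = src[m], ref[m]
    else:
        src_vals, ref_vals = src.ravel(), ref.ravel()
    if float(src_vals.max()) == float(src_vals.min()):
        raise ValueError("constant source volume: histogram matching undefined")
    q = np.linspace(0.0, 1.0, n_bins + 1)
    src_q = np.quantile(src_vals, q)
    ref_q = np.quantile(ref_vals, q)
    mapped = np.interp(src, src_q, ref_q)
    return Volume(mapped.astype(np.float32), source.spacing, source.affine.copy(),
                  "histogram_matched")


def _slicewise_rows(bl: np.ndarray, other: np.ndarray, condition: str,
                    subject: str, cfg: metrics.SSIMConfig, data_range: float) -> list[dict]:
    rows = []
    for k in range(bl.shape[2]):
        x, y = bl[:, :, k], other[:, :, k]
        rows.append({"condition": condition, "granularity": "slice", "subject": subject,
                     "region": "", "metric": "ssim", "value": metrics.ssim(x, y, cfg)})
        rows.append({"condition": condition, "granularity": "slice", "subject": subject,
                     "region": "", "metric": "psnr",
                     "value": metrics.psnr(x, y, data_range)})
    return rows


def evaluate_conditions(
    bl: Volume,
    fu_original: Volume,
    fu_harmonized: Volume | None = None,
    bl_reconstructed: Volume | None = None,
    region_masks: dict[str, np.ndarray] | None = None,
    background_mask: np.ndarray | None = None,
    lesion_masks: tuple[np.ndarray, np.ndarray] | None = None,
    subject: str = "",
    extractor=None,
) -> EvaluationRun:
    """Slice-wise and volume-wise SSIM/PSNR (plus LPIPS with an extractor)
    for the three comparison conditions, per-region CNR-difference rows for
    original and harmonized follow-up, and lesion Dice / average Hausdorff
    when lesion masks are supplied. Pure function of its inputs."""
    vol_pairs = {"BL-vs-originalFU": fu_original}
    if fu_harmonized is not None:
        vol_pairs["BL-vs-FU2BL"] = fu_harmonized
    if bl_reconstructed is not None:
        vol_pairs["BL-vs-BL2FU2BL"] = bl_reconstructed
    for cond, v in vol_pairs.items():
        if v.shape != bl.shape:
            raise ValueError(f"{cond}: grid mismatch {v.shape} vs {bl.shape}")

    bl_data = np.asarray(bl.data, dtype=np.float64)
    rng_vals = [bl_data] + [np.asarray(v.data, dtype=np.float64) for v in vol_pairs.values()]
    data_range = max(float(a.max()) for a in rng_vals) - min(float(a.min()) for a in rng_vals)
    if data_range <= 0:
        data_range = 1.0
    cfg2d = metrics.SSIMConfig(data_range=data_range)

    rows: list[dict] = []
    for cond, vol in vol_pairs.items():
        other = np.asarray(vol.data, dtype=np.float64)
        rows += _slicewise_rows(bl_data, other, cond, subject, cfg2d, data_range)
        rows.append({"condition": cond, "granularity": "volume", "subject": subject,
                     "region": "", "metric": "ssim",
                     "value": metrics.ssim(bl_data, other, cfg2d)})
        rows.append({"condition": cond, "granularity": "volume", "subject": subject,
                     "region": "", "metric": "psnr",
                     "value": metrics.psnr(bl_data, other, data_range)})
        if extractor is not None:
            vals = [
                metrics.lpips(bl_data[:, :, k], other[:, :, k], extractor)
                for k in range(bl_data.shape[2])
            ]
            for v in vals:
                rows.append({"condition": cond, "granularity": "slice", "subject": subject,
                             "region": "", "metric": "lpips", "value": v})

    if region_masks and background_mask is not None:
        for cond, vol in vol_pairs.items():
            if cond == "BL-vs-BL2FU2BL":
                continue  # CNR differences compare BL with a follow-up variant
            table = metrics.cnr_difference_table(
                bl_data, np.asarray(vol.data, dtype=np.float64), region_masks, background_mask
            )
            for _, r in table.iterrows():
                rows.append({"condition": cond, "granularity": "volume", "subject": subject,
                             "region": r["region"], "metric": "cnr_difference",
                             "value": r["cnr_difference"]})

    if lesion_masks is not None:
        m_bl, m_fu = lesion_masks
        rows.append({"condition": "BL-vs-originalFU", "granularity": "volume",
                     "subject": subject, "region": "lesion", "metric": "dice",
                     "value": metrics.dice(m_bl, m_fu)})
        if np.asarray(m_bl).any() and np.asarray(m_fu).any():
            rows.append({"condition": "BL-vs-originalFU", "granularity": "volume",
                         "subject": subject, "region": "lesion", "metric": "avg_hausdorff",
                         "value": metrics.average_hausdorff(m_bl, m_fu, bl.spacing)})

    return EvaluationRun([subject], list(vol_pairs), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties are mid-ranked. The null distribution
    is enumerated exactly for n <= ``exact_max_n`` and approximated normally
    (with tie correction and continuity correction off) above. Returns
    (W = min(W+, W-), p).
    """
    d = np.asarray(x, dtype=np.float64)
    if y is not None:
        d = d - np.asarray(y, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: test degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= exact_max_n:
        # DP over doubled ranks (midranks * 2 are integers) for the exact
        # distribution of 2*W+ across all 2^n sign assignments.
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        counts /= counts.sum()
        wp2 = int(round(2 * w_plus))
        p_le = counts[: wp2 + 1].sum()
        p_ge = counts[wp2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, t_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return w, float(p)


def paired_t_test(x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, float]:
    """Standard two-sided paired t test on differences."""
    d = np.asarray(x, dtype=np.float64)
    if y is not None:
        d = d - np.asarray(y, dtype=np.float64)
    n = len(d)
    if n < 2:
        raise ValueError("paired t test requires n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: t statistic undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def compare_conditions(
    runs: list[EvaluationRun],
    reference: str = "BL-vs-originalFU",
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Paired per-subject comparison of each condition against ``reference``.

    Pools each subject's mean per (granularity, metric) and applies the
    Wilcoxon signed-rank test (or paired t) across subjects.
    """
    per_item = pd.concat([r.per_item for r in runs], ignore_index=True)
    finite = per_item[np.isfinite(per_item["value"])]
    subj_means = (
        finite.groupby(["condition", "granularity", "metric", "subject"])["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for (gran, metric), grp in subj_means.groupby(["granularity", "metric"]):
        pivot = grp.pivot(index="subject", columns="condition", values="value")
        if reference not in pivot.columns:
            continue
        for cond in pivot.columns:
            if cond == reference:
                continue
            paired = pivot[[reference, cond]].dropna()
            row = {"granularity": gran, "metric": metric, "condition": cond,
                   "reference": reference, "n": len(paired),
                   "mean_ref": paired[reference].mean(), "mean_cond": paired[cond].mean()}
            try:
                if test == "wilcoxon":
                    stat, p = wilcoxon_signed_rank(paired[cond].values,
                                                   paired[reference].values)
                else:
                    stat, p = paired_t_test(paired[cond].values, paired[reference].values)
                row.update({"test": test, "statistic": stat, "p_value": p})
            except ValueError as exc:
                row.update({"test": test, "statistic": float("nan"),
                            "p_value": float("nan"), "note": str(exc)})
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(run: EvaluationRun, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write per-item values, aggregates and statistics as CSV plus a JSON
    summary; returns the written paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "per_item": os.path.join(out_dir, "per_item.csv"),
        "aggregates": os.path.join(out_dir, "aggregates.csv"),
        "summary": os.path.join(out_dir, "summary.json"),
    }
    run.per_item.to_csv(paths["per_item"], index=False)
    agg = run.aggregates()
    agg.to_csv(paths["aggregates"], index=False)
    summary = {
        "subjects": run.subjects,
        "conditions": run.conditions,
        "aggregates": agg.to_dict(orient="records"),
    }
    if len(run.stats):
        paths["stats"] = os.path.join(out_dir, "stats.csv")
        run.stats.to_csv(paths["stats"], index=False)
        summary["stats"] = run.stats.to_dict(orient="records")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return paths
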