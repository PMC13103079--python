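"""Paired two-domain training loop, learning-rate schedule, checkpointing,
and the matching-loss-coefficient ablation runner.

Both translation directions run in every iteration and their losses are
averaged; one Adam update is applied to the generators and one to the
discriminators per iteration.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .gan import (
    Discriminator,
    DiscriminatorSpec,
    Generator,
    GeneratorSpec,
    LossBreakdown,
    LossWeights,
    adversarial_loss,
    load_checkpoint,
    save_checkpoint,
    total_loss,
)
from .nn import Adam

__all__ = [
    "TrainConfig",
    "SubjectSlices",
    "TrainResult",
    "AblationResult",
    "lr_schedule",
    "train_step",
    "train",
    "split_subjects",
    "run_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.99
    batch_size: int = 16
    total_iterations: int = 250_000
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    gen_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc_spec: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    checkpoint_every: int = 0  # 0 = only final
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.total_iterations < 1:
            raise ValueError("invalid training configuration")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class SubjectSlices:
    """Preprocessed, co-registered, normalized slice arrays for one subject."""

    subject_id: str
    bl_slices: np.ndarray  # (n, H, W) in [0, 1]
    fu_slices: np.ndarray

    def __post_init__(self) -> None:
        if self.bl_slices.shape != self.fu_slices.shape:
            raise ValueError(f"{self.subject_id}: bl/fu slice stacks differ in shape")


@dataclass
class TrainResult:
    models: dict  # G_BL, G_FU, D_BL, D_FU
    log: pd.DataFrame
    train_subjects: list[str]
    val_subjects: list[str]
    config: TrainConfig


def lr_schedule(iteration: int, config: TrainConfig) -> float:
    """Linear ramp from the configured rate at iteration 0 to 0 at
    ``total_iterations``."""
    if not 0 <= iteration <= config.total_iterations:
        raise ValueError(
            f"iteration {iteration} outside [0, {config.total_iterations}]"
        )
    return config.learning_rate * (1.0 - iteration / config.total_iterations)


def _l1_grad(pred: np.ndarray, target: np.ndarray, weight: float) -> np.ndarray:
    return (weight / pred.size) * np.sign(pred - target).astype(np.float32)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def train_step(
    x_A: np.ndarray,
    x_B: np.ndarray,
    models: dict,
    weights: LossWeights,
    opt_G: Adam,
    opt_D: Adam,
    lr: float,
    iteration: int = 0,
) -> LossBreakdown:
    """One simultaneous bidirectional iteration.

    ``x_A`` is a batch of BL-domain slices, ``x_B`` the registered FU batch,
    both (N, 1, H, W) in [0, 1]. Computes the adversarial, cycle-consistency
    and matching terms for both directions, averages across directions,
    applies one generator and one discriminator update, and returns the
    per-term breakdown.
    """
    G_A: Generator = models["G_BL"]  # maps into the BL domain
    G_B: Generator = models["G_FU"]
    D_A: Discriminator = models["D_BL"]
    D_B: Discriminator = models["D_FU"]
    x_A = np.asarray(x_A, dtype=np.float32)
    x_B = np.asarray(x_B, dtype=np.float32)
    if x_A.shape != x_B.shape:
        raise ValueError("paired batches must share one shape")

    # ---- generator pass -------------------------------------------------
    opt_G.zero_grad()
    opt_D.zero_grad()

    fake_A, c_gA_xB = G_A.forward(x_B)  # FU -> BL
    fake_B, c_gB_xA = G_B.forward(x_A)  # BL -> FU
    rec_B, c_gB_fakeA = G_B.forward(fake_A)  # FU -> BL -> FU
    rec_A, c_gA_fakeB = G_A.forward(fake_B)  # BL -> FU -> BL
    use_oml = weights.lambda_oml > 0 and weights.variant != "none"
    if use_oml:
        idt_A, c_gA_xA = G_A.forward(x_A)
        idt_B, c_gB_xB = G_B.forward(x_B)
    else:
        idt_A, idt_B = x_A, x_B

    s_fake_A, c_dA_fake = D_A.forward(fake_A)
    s_fake_B, c_dB_fake = D_B.forward(fake_B)

    gen_A, _ = adversarial_loss(np.zeros_like(s_fake_A), s_fake_A)
    gen_B, _ = adversarial_loss(np.zeros_like(s_fake_B), s_fake_B)
    adv_g = 0.5 * (gen_A + gen_B)
    ccl = 0.5 * (
        float(np.mean(np.abs(x_A - rec_A))) + float(np.mean(np.abs(x_B - rec_B)))
    )
    cross = weights.variant == "oml"
    oml = 0.0
    if use_oml:
        if cross:
            oml += float(np.mean(np.abs(x_A - fake_A))) + float(np.mean(np.abs(x_B - fake_B)))
        oml += float(np.mean(np.abs(x_A - idt_A))) + float(np.mean(np.abs(x_B - idt_B)))

    breakdown = LossBreakdown(adv_g=adv_g, ccl=ccl, oml=oml)
    breakdown.total = total_loss(breakdown, weights)
    if not np.isfinite(breakdown.total):
        raise FloatingPointError(
            f"non-finite loss at iteration {iteration}: "
            f"adv_g={adv_g} ccl={ccl} oml={oml}"
        )

    # ---- generator backward --------------------------------------------
    # cycle paths first: they feed gradient back into the fakes
    d_rec_A = _l1_grad(rec_A, x_A, 0.5 * weights.lambda_ccl)
    d_rec_B = _l1_grad(rec_B, x_B, 0.5 * weights.lambda_ccl)
    d_fake_B = G_A.backward(c_gA_fakeB, d_rec_A)
    d_fake_A = G_B.backward(c_gB_fakeA, d_rec_B)

    if weights.lambda_adv > 0:
        # d/ds of -mean(log sigmoid(s)), averaged over the two directions
        gA = -(1.0 - _sigmoid(s_fake_A)) * (0.5 * weights.lambda_adv / s_fake_A.size)
        gB = -(1.0 - _sigmoid(s_fake_B)) * (0.5 * weights.lambda_adv / s_fake_B.size)
        d_fake_A = d_fake_A + D_A.backward(c_dA_fake, gA.astype(np.float32))
        d_fake_B = d_fake_B + D_B.backward(c_dB_fake, gB.astype(np.float32))

    if use_oml and cross:
        d_fake_A = d_fake_A + _l1_grad(fake_A, x_A, weights.lambda_oml)
        d_fake_B = d_fake_B + _l1_grad(fake_B, x_B, weights.lambda_oml)

    G_A.backward(c_gA_xB, d_fake_A)
    G_B.backward(c_gB_xA, d_fake_B)
    if use_oml:
        G_A.backward(c_gA_xA, _l1_grad(idt_A, x_A, weights.lambda_oml))
        G_B.backward(c_gB_xB, _l1_grad(idt_B, x_B, weights.lambda_oml))

    opt_G.step(lr)

    # ---- discriminator pass (fakes are constants here) ------------------
    opt_G.zero_grad()
    opt_D.zero_grad()
    adv_d = 0.0
    for D, x_real, x_fake in ((D_A, x_A, fake_A), (D_B, x_B, fake_B)):
        s_real, c_real = D.forward(x_real)
        s_fake, c_fake = D.forward(x_fake)
        _, disc = adversarial_loss(s_real, s_fake)
        adv_d += 0.5 * disc
        g_real = -(1.0 - _sigmoid(s_real)) * (0.5 / s_real.size)
        g_fake = _sigmoid(s_fake) * (0.5 / s_fake.size)
        D.backward(c_real, g_real.astype(np.float32))
        D.backward(c_fake, g_fake.astype(np.float32))
    opt_D.step(lr)

    breakdown.adv_d = adv_d
    return breakdown


def split_subjects(
    subjects: list[SubjectSlices], val_fraction: float, seed: int
) -> tuple[list[SubjectSlices], list[SubjectSlices]]:
    """Subject-level train/validation split (slices of one subject never
    straddle the split)."""
    order = np.random.default_rng(seed).permutation(len(subjects))
    n_val = int(round(val_fraction * len(subjects)))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(subjects) if i not in val_idx]
    val = [s for i, s in enumerate(subjects) if i in val_idx]
    return train, val


def _build_models(config: TrainConfig) -> dict:
    return {
        "G_BL": Generator(config.gen_spec, seed=config.seed * 4 + 0),
        "G_FU": Generator(config.gen_spec, seed=config.seed * 4 + 1),
        "D_BL": Discriminator(config.disc_spec, seed=config.seed * 4 + 2),
        "D_FU": Discriminator(config.disc_spec, seed=config.seed * 4 + 3),
    }


def subjects_from_phantoms(
    n_subjects: int,
    seed: int,
    spec_template=None,
    exclude_fraction: float = 0.1,
) -> tuple[list[SubjectSlices], list]:
    """Generate phantom pairs and preprocess them into training subjects.

    Returns (subjects, ground truths). Phantoms are generated aligned
    (identity misalignment) since the training contract expects
    co-registered pairs; registration is exercised by its own fixtures.
    """
    from . import phantom as ph
    from .ioprep import extract_axial_slices, normalize_intensity

    spec_template = spec_template or ph.PhantomSpec()
    subjects, truths = [], []
    for i in range(n_subjects):
        spec = dataclasses.replace(spec_template, seed=seed * 1000 + i)
        bl, fu, truth = ph.make_longitudinal_pair(spec)
        bl_n, _ = normalize_intensity(bl)
        fu_n, _ = normalize_intensity(fu)
        subjects.append(
            SubjectSlices(
                f"sub-{i:03d}",
                extract_axial_slices(bl_n, exclude_fraction).slices,
                extract_axial_slices(fu_n, exclude_fraction).slices,
            )
        )
        truths.append(truth)
    return subjects, truths


def train(
    config: TrainConfig,
    subjects: list[SubjectSlices],
    out_dir: str | os.PathLike | None = None,
    presplit: tuple[list[SubjectSlices], list[SubjectSlices]] | None = None,
    resume_from: str | os.PathLike | None = None,
) -> TrainResult:
    """Run the full training loop on preprocessed paired slices.

    Subjects are split 8:2 (by ``val_fraction``) at the subject level unless
    ``presplit`` is given. Logs one row per iteration; writes checkpoints at
    the configured cadence into ``out_dir`` when provided. ``resume_from``
    restores models from a checkpoint prefix and continues from its stored
    iteration count up to ``config.total_iterations``.
    """
    if not subjects:
        raise ValueError("empty dataset")
    if presplit is not None:
        train_subjects, val_subjects = presplit
    else:
        train_subjects, val_subjects = split_subjects(subjects, config.val_fraction, config.seed)
    if not train_subjects:
        raise ValueError("no training subjects after split")

    bl = np.concatenate([s.bl_slices for s in train_subjects]).astype(np.float32)
    fu = np.concatenate([s.fu_slices for s in train_subjects]).astype(np.float32)
    n_pairs = len(bl)

    start_iteration = 0
    if resume_from is not None:
        models, _, start_iteration, _ = load_checkpoint(resume_from)
        if start_iteration >= config.total_iterations:
            raise ValueError(
                f"checkpoint iteration {start_iteration} >= total "
                f"{config.total_iterations}: nothing to resume"
            )
    else:
        models = _build_models(config)
    opt_G = Adam(
        models["G_BL"].params() + models["G_FU"].params(),
        config.learning_rate, config.adam_beta1, config.adam_beta2,
    )
    opt_D = Adam(
        models["D_BL"].params() + models["D_FU"].params(),
        config.learning_rate, config.adam_beta1, config.adam_beta2,
    )

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n_pairs)
    cursor = 0
    rows = []
    for it in range(start_iteration, config.total_iterations):
        if cursor + config.batch_size > n_pairs:
            order = rng.permutation(n_pairs)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size
        lr = lr_schedule(it, config)
        bd = train_step(
            bl[idx][:, None], fu[idx][:, None], models, config.loss_weights,
            opt_G, opt_D, lr, iteration=it,
        )
        rows.append(
            {"iteration": it, "lr": lr, "adv_g": bd.adv_g, "adv_d": bd.adv_d,
             "ccl": bd.ccl, "oml": bd.oml, "total": bd.total}
        )
        if out_dir and config.checkpoint_every and (it + 1) % config.checkpoint_every == 0:
            save_checkpoint(
                os.path.join(os.fspath(out_dir), f"ckpt_{it + 1:07d}"),
                models, config.loss_weights, it + 1, config.seed,
            )

    log = pd.DataFrame(rows)
    if out_dir:
        os.makedirs(os.fspath(out_dir), exist_ok=True)
        save_checkpoint(
            os.path.join(os.fspath(out_dir), "ckpt_final"),
            models, config.loss_weights, config.total_iterations, config.seed,
        )
        log.to_csv(os.path.join(os.fspath(out_dir), "loss_log.csv"), index=False)
    return TrainResult(models, log, [s.subject_id for s in train_subjects],
                       [s.subject_id for s in val_subjects], config)


# ---------------------------------------------------------------------------
# Ablation over the matching-loss coefficient
# ---------------------------------------------------------------------------


@dataclass
class AblationResult:
    table: pd.DataFrame  # columns: lambda_oml, condition, metric, mean, sd

    def to_csv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out["mean_sd"] = out.apply(lambda r: f"{r['mean']:.4f} ± {r['sd']:.4f}", axis=1)
        out.to_csv(os.fspath(path), index=False)


def evaluate_slicewise(
    models: dict,
    val_subjects: list[SubjectSlices],
    extractor=None,
) -> pd.DataFrame:
    """Slice-wise SSIM/PSNR (and LPIPS given an extractor) for the two
    conditions BL-vs-FU2BL and BL-vs-BL2FU2BL on validation subjects."""
    cfg = metrics.SSIMConfig()
    rows = []
    for subj in val_subjects:
        harmonized = models["G_BL"].translate_slices(subj.fu_slices)
        fake_fu = models["G_FU"].translate_slices(subj.bl_slices)
        reconstructed = models["G_BL"].translate_slices(fake_fu)
        for cond, pred in (("BL-vs-FU2BL", harmonized), ("BL-vs-BL2FU2BL", reconstructed)):
            for k in range(len(subj.bl_slices)):
                ref = subj.bl_slices[k]
                rows.append({"subject": subj.subject_id, "condition": cond,
                             "metric": "ssim", "value": metrics.ssim(ref, pred[k], cfg)})
                rows.append({"subject": subj.subject_id, "condition": cond,
                             "metric": "psnr", "value": metrics.psnr(ref, pred[k])})
                if extractor is not None:
                    rows.append({"subject": subj.subject_id, "condition": cond,
                                 "metric": "lpips",
                                 "value": metrics.lpips(ref, pred[k], extractor)})
    return pd.DataFrame(rows)


def run_ablation(
    lambda_values: list[float],
    config: TrainConfig,
    subjects: list[SubjectSlices],
    extractor=None,
    out_dir: str | os.PathLike | None = None,
) -> AblationResult:
    """Train one model per matching-loss coefficient on a shared split and
    seed, then report mean ± sd slice-wise metrics per condition."""
    presplit = split_subjects(subjects, config.val_fraction, config.seed)
    if not presplit[1]:
        raise ValueError("ablation requires at least one validation subject")
    rows = []
    for lam in lambda_values:
        weights = dataclasses.replace(config.loss_weights, lambda_oml=float(lam))
        cfg = dataclasses.replace(config, loss_weights=weights)
        result = train(cfg, subjects, presplit=presplit)
        table = evaluate_slicewise(result.models, presplit[1], extractor=extractor)
        finite = table[np.isfinite(table["value"])]
        for (cond, metric), grp in finite.groupby(["condition", "metric"]):
            rows.append({"lambda_oml": lam, "condition": cond, "metric": metric,
                         "mean": grp["value"].mean(), "sd": grp["value"].std(ddof=0)})
        if out_dir:
            os.makedirs(os.fspath(out_dir), exist_ok=True)
            save_checkpoint(
                os.path.join(os.fspath(out_dir), f"ckpt_oml{lam:g}"),
                result.models, weights, cfg.total_iterations, cfg.seed,
            )
    result_table = pd.DataFrame(rows)
    if out_dir:
        AblationResult(result_table).to_csv(os.path.join(os.fspath(out_dir), "ablation.csv"))
    return AblationResult(result_table)
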