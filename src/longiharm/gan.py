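"""Two-domain translation model and its training objective.

Generators map a slice of one scanner domain into the other; patch-level
discriminators score real vs. translated slices. The objective combines an
adversarial term, a cycle-consistency L1 term, and a four-term "original
matching" L1 penalty tying every generator/domain combination of a
registered baseline/follow-up pair back to the originals:

    L = lambda_adv * L_adv + lambda_ccl * L_ccl + lambda_oml * L_oml
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "Domain",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "LossBreakdown",
    "Generator",
    "Discriminator",
    "make_generator",
    "make_discriminator",
    "adversarial_loss",
    "cycle_consistency_loss",
    "original_matching_loss",
    "total_loss",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7  # log clamp


class Domain(enum.Enum):
    BL = "BL"
    FU = "FU"


@dataclass(frozen=True)
class GeneratorSpec:
    base_filters: int = 16
    n_residual_blocks: int = 3
    norm: str = "instance"  # "instance" | "none"
    input_skip_gain: float = 4.0  # 0 disables the input->output skip

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.n_residual_blocks < 0:
            raise ValueError("invalid generator spec")
        if self.norm not in ("instance", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    base_filters: int = 16
    n_layers: int = 3

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.n_layers < 1:
            raise ValueError("invalid discriminator spec")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the final objective plus the structural-consistency variant.

    ``variant`` selects which matching terms are active: ``"oml"`` = all four,
    ``"identity"`` = only the two same-domain terms, ``"none"`` = neither.
    """

    lambda_adv: float = 1.0
    lambda_ccl: float = 5.0
    lambda_oml: float = 10.0
    variant: str = "oml"

    def __post_init__(self) -> None:
        if min(self.lambda_adv, self.lambda_ccl, self.lambda_oml) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.variant not in ("oml", "identity", "none"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "none" and self.lambda_oml != 0:
            raise ValueError("variant 'none' requires lambda_oml = 0")


@dataclass
class LossBreakdown:
    adv_g: float = 0.0
    adv_d: float = 0.0
    ccl: float = 0.0
    oml: float = 0.0
    total: float = 0.0


# ---------------------------------------------------------------------------
# Loss terms (pure value functions; training uses matching analytic grads)
# ---------------------------------------------------------------------------


def _check_finite(name: str, *arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite values in {name}")


def adversarial_loss(real_scores: np.ndarray, fake_scores: np.ndarray) -> tuple[float, float]:
    """Cross-entropy adversarial terms from raw (pre-sigmoid) score maps.

    Scores pass through a sigmoid into (0, 1) and logs are clamped. The
    discriminator term is -(E[log D(x)] + E[log(1 - D(G(x)))]); the generator
    term, -E[log D(G(x))], decreases as the discriminator is fooled.
    """
    real_scores = np.asarray(real_scores, dtype=np.float64)
    fake_scores = np.asarray(fake_scores, dtype=np.float64)
    _check_finite("adversarial scores", real_scores, fake_scores)
    d_real = np.clip(_sigmoid(real_scores), _EPS, 1 - _EPS)
    d_fake = np.clip(_sigmoid(fake_scores), _EPS, 1 - _EPS)
    disc = -(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))
    gen = -np.mean(np.log(d_fake))
    return float(gen), float(disc)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def cycle_consistency_loss(x: np.ndarray, x_reconstructed: np.ndarray) -> float:
    """Mean absolute difference between an image and its round-trip
    reconstruction G_B(G_A(x))."""
    x = np.asarray(x, dtype=np.float64)
    r = np.asarray(x_reconstructed, dtype=np.float64)
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {r.shape}")
    return float(np.mean(np.abs(x - r)))


def original_matching_loss(
    x_A: np.ndarray,
    x_B: np.ndarray,
    g_A_of_xB: np.ndarray,
    g_A_of_xA: np.ndarray,
    g_B_of_xA: np.ndarray,
    g_B_of_xB: np.ndarray,
    variant: str = "oml",
) -> float:
    """Four-term L1 matching penalty for a registered (x_A, x_B) pair:

        ||x_A - G_A(x_B)||_1 + ||x_A - G_A(x_A)||_1
      + ||x_B - G_B(x_A)||_1 + ||x_B - G_B(x_B)||_1

    each an element-mean, summed with equal weight. ``variant="identity"``
    keeps only the two same-domain terms (the classic identity-mapping loss);
    ``variant="none"`` returns 0.
    """
    arrays = (x_A, x_B, g_A_of_xB, g_A_of_xA, g_B_of_xA, g_B_of_xB)
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"all six images must share one shape, got {shapes}")
    if variant == "none":
        return 0.0
    t_cross_A = float(np.mean(np.abs(np.asarray(x_A) - np.asarray(g_A_of_xB))))
    t_idt_A = float(np.mean(np.abs(np.asarray(x_A) - np.asarray(g_A_of_xA))))
    t_cross_B = float(np.mean(np.abs(np.asarray(x_B) - np.asarray(g_B_of_xA))))
    t_idt_B = float(np.mean(np.abs(np.asarray(x_B) - np.asarray(g_B_of_xB))))
    if variant == "identity":
        return t_idt_A + t_idt_B
    return t_cross_A + t_idt_A + t_cross_B + t_idt_B


def total_loss(breakdown: LossBreakdown, weights: LossWeights) -> float:
    """Compose the final objective from the generator-side components."""
    for v in (breakdown.adv_g, breakdown.ccl, breakdown.oml):
        if not np.isfinite(v):
            raise ValueError("non-finite loss component")
    return (
        weights.lambda_adv * breakdown.adv_g
        + weights.lambda_ccl * breakdown.ccl
        + weights.lambda_oml * breakdown.oml
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class Generator:
    """Residual encoder-decoder mapping an image to an image of the same
    shape, squashed to [0, 1] by a final sigmoid.

    A fixed-gain skip from the input into the final pre-activation
    (``sigmoid(body(x) + g*x - g/2)``) makes the untrained network start
    near the identity map, which matters for convergence at small scale;
    set ``input_skip_gain=0`` to disable it.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        layers: list[nn.Layer] = [nn.Conv2d(1, f, 3, rng=rng)]
        if spec.norm == "instance":
            layers.append(nn.InstanceNorm2d(f))
        layers.append(nn.ReLU())
        for _ in range(spec.n_residual_blocks):
            layers.append(nn.ResidualBlock(f, norm=spec.norm, rng=rng))
        head = nn.Conv2d(f, 1, 3, rng=rng)
        head.W.value *= 0.1  # start close to the skip path
        layers.append(head)
        self.body = nn.Sequential(layers)
        self.squash = nn.Sigmoid()

    def params(self) -> list[nn.Param]:
        return self.body.params()

    def forward(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"generator expects (N, 1, H, W), got {x.shape}")
        x = np.asarray(x, dtype=np.float32)
        pre, body_cache = self.body.forward(x)
        g = self.spec.input_skip_gain
        if g:
            pre = pre + g * x - g / 2.0
        y, squash_cache = self.squash.forward(pre)
        return y, (body_cache, squash_cache)

    def backward(self, cache, grad_out: np.ndarray) -> np.ndarray:
        body_cache, squash_cache = cache
        dpre = self.squash.backward(squash_cache, grad_out)
        dx = self.body.backward(body_cache, dpre)
        g = self.spec.input_skip_gain
        if g:
            dx = dx + g * dpre
        return dx

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def translate_slices(self, slices: np.ndarray, batch: int = 16) -> np.ndarray:
        """Inference helper: translate (N, H, W) slices without caching."""
        out = np.empty_like(np.asarray(slices, dtype=np.float32))
        for i in range(0, len(slices), batch):
            chunk = np.asarray(slices[i : i + batch], dtype=np.float32)[:, None]
            out[i : i + batch] = self.forward(chunk)[0][:, 0]
        return out


class Discriminator:
    """Patch-level convolutional classifier; outputs a raw score map."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        layers: list[nn.Layer] = [nn.Conv2d(1, f, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU()]
        c = f
        for _ in range(spec.n_layers - 2):
            layers += [nn.Conv2d(c, c * 2, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU()]
            c *= 2
        layers.append(nn.Conv2d(c, 1, 4, stride=1, pad=1, rng=rng))
        self.net = nn.Sequential(layers)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"discriminator expects (N, 1, H, W), got {x.shape}")
        return self.net.forward(np.asarray(x, dtype=np.float32))

    def backward(self, cache, grad_out: np.ndarray) -> np.ndarray:
        return self.net.backward(cache, grad_out)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]


def make_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed)


def make_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | os.PathLike,
    models: dict,
    weights: LossWeights,
    iteration: int,
    seed: int,
    optim_state: dict | None = None,
) -> None:
    """Persist model weights (npz) plus a JSON sidecar of specs and state.

    ``models`` maps names (e.g. ``G_BL``) to Generator/Discriminator objects.
    """
    path = os.fspath(path)
    arrays = {}
    meta = {
        "version": CHECKPOINT_VERSION,
        "iteration": iteration,
        "seed": seed,
        "weights": {
            "lambda_adv": weights.lambda_adv,
            "lambda_ccl": weights.lambda_ccl,
            "lambda_oml": weights.lambda_oml,
            "variant": weights.variant,
        },
        "models": {},
    }
    for name, model in models.items():
        spec = model.spec
        meta["models"][name] = {
            "kind": "generator" if isinstance(model, Generator) else "discriminator",
            "spec": spec.__dict__,
        }
        for i, p in enumerate(model.params()):
            arrays[f"{name}__{i}"] = p.value
    np.savez(path + ".npz", **arrays)
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path: str | os.PathLike) -> tuple[dict, LossWeights, int, int]:
    """Inverse of :func:`save_checkpoint`; returns (models, weights,
    iteration, seed)."""
    path = os.fspath(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version in {path}.json")
    arrays = np.load(path + ".npz")
    models: dict = {}
    for name, info in meta["models"].items():
        if info["kind"] == "generator":
            model = Generator(GeneratorSpec(**info["spec"]))
        else:
            model = Discriminator(DiscriminatorSpec(**info["spec"]))
        for i, p in enumerate(model.params()):
            stored = arrays[f"{name}__{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(f"checkpoint shape mismatch for {name} param {i}")
            p.value[...] = stored
        models[name] = model
    w = meta["weights"]
    weights = LossWeights(w["lambda_adv"], w["lambda_ccl"], w["lambda_oml"], w["variant"])
    return models, weights, int(meta["iteration"]), int(meta["seed"])
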