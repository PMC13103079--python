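"""Synthetic paired longitudinal two-scanner-style brain phantoms.

Procedural anatomy (nested ellipsoids plus seeded subregion blobs and a
spherical enhancing lesion), rendered under two scanner "styles" — per-tissue
mean intensities, a gamma exponent, a smooth multiplicative polynomial bias
field and additive Gaussian noise — with a known rigid misalignment between
visits and full ground truth for every generated subject.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioprep import RigidTransform, Volume, apply_rigid, save_volume

__all__ = [
    "StyleParams",
    "LesionSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "make_anatomy",
    "render_style",
    "make_longitudinal_pair",
    "make_dataset",
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
    "LABEL_LESION",
    "SUBREGION_LABEL_START",
]

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
SUBREGION_LABEL_START = 10
LABEL_LESION = 99


@dataclass(frozen=True)
class StyleParams:
    """One scanner's rendering parameters."""

    tissue_means: dict = field(
        default_factory=lambda: {
            LABEL_CSF: 0.15,
            LABEL_GM: 0.45,
            LABEL_WM: 0.65,
            LABEL_LESION: 0.90,
        }
    )
    gamma: float = 1.0
    bias_coeffs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)  # x, y, z, x², y², z²
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.noise_sd < 0:
            raise ValueError(f"noise sd must be non-negative, got {self.noise_sd}")


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float, float] | None = None  # voxel coords; None = auto
    radius: float = 4.0
    contrast: float = 0.9  # rendered lesion intensity before gamma
    radius_change_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("lesion radius must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 64
    voxel_spacing: float = 1.0
    n_regions: int = 4
    lesion: LesionSpec = field(default_factory=LesionSpec)
    style_A: StyleParams = field(default_factory=StyleParams)
    style_B: StyleParams = field(
        default_factory=lambda: StyleParams(
            tissue_means={LABEL_CSF: 0.10, LABEL_GM: 0.55, LABEL_WM: 0.60, LABEL_LESION: 0.95},
            gamma=1.3,
            # strong spatially varying bias: the regime where a global
            # monotone intensity map is fundamentally insufficient
            bias_coeffs=(0.20, -0.16, 0.22, -0.30, 0.20, -0.22),
            noise_sd=0.02,
        )
    )
    misalignment: RigidTransform = field(default_factory=RigidTransform)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be at least 16")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")

    def lesion_center(self) -> np.ndarray:
        if self.lesion.center is not None:
            return np.asarray(self.lesion.center, dtype=np.float64)
        n = self.grid_size
        return np.array([0.60 * n, 0.42 * n, 0.55 * n])


@dataclass
class PhantomGroundTruth:
    region_label_volume: Volume
    lesion_mask_bl: Volume
    lesion_mask_fu: Volume
    background_mask: Volume
    applied_transform: RigidTransform
    style_params: tuple[StyleParams, StyleParams]
    seed: int


def _coord_grids(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)  # normalized [-1, 1)
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _ellipsoid(x, y, z, center, semi, bump: float = 0.0) -> np.ndarray:
    """Ellipsoid interior test; ``bump`` adds a smooth angular modulation of
    the surface radius so the shape has no rotational self-similarity (needed
    for rigid registration to be well-posed on these phantoms)."""
    u = (x - center[0]) / semi[0]
    v = (y - center[1]) / semi[1]
    w = (z - center[2]) / semi[2]
    rho2 = u**2 + v**2 + w**2
    if not bump:
        return rho2 <= 1.0
    rho = np.sqrt(np.maximum(rho2, 1e-12))
    theta = np.arctan2(np.sqrt(u**2 + v**2), w)
    phi = np.arctan2(v, u)
    mod = 1.0 + bump * (np.sin(3 * theta + 1.1) * np.cos(2 * phi - 0.7)
                        + 0.5 * np.cos(4 * phi + 2 * theta))
    return rho <= mod


def make_anatomy(spec: PhantomSpec, lesion_radius: float | None = None) -> Volume:
    """Build the integer label volume: nested CSF/GM/WM ellipsoids,
    ``n_regions`` seeded spherical subregions, and a spherical lesion.

    ``lesion_radius`` overrides the spec radius (used for follow-up growth).
    Deterministic in ``spec.seed``.
    """
    n = spec.grid_size
    radius = spec.lesion.radius if lesion_radius is None else lesion_radius
    center_vox = spec.lesion_center()
    if radius > 0:
        if np.any(center_vox - radius < 0) or np.any(center_vox + radius > n - 1):
            raise ValueError(
                f"lesion (center {tuple(center_vox)}, radius {radius}) extends outside "
                f"the {n}^3 grid"
            )

    x, y, z = _coord_grids(n)
    labels = np.zeros((n, n, n), dtype=np.int16)

    # deliberately anisotropic semi-axes and an off-center ventricle so that
    # rotations are well constrained for registration recovery
    head = _ellipsoid(x, y, z, (0, 0, 0), (0.92, 0.74, 0.85), bump=0.03)
    gm = _ellipsoid(x, y, z, (0, 0.02, 0), (0.80, 0.62, 0.72), bump=0.05)
    wm = _ellipsoid(x, y, z, (0.03, -0.02, 0.04), (0.60, 0.44, 0.52), bump=0.08)
    vent = _ellipsoid(x, y, z, (0.06, 0.08, -0.06), (0.17, 0.09, 0.21))

    labels[head] = LABEL_CSF
    labels[gm] = LABEL_GM
    labels[wm] = LABEL_WM
    labels[vent & wm] = LABEL_CSF

    # Seeded subregion blobs inside WM, non-overlapping by construction order.
    rng = np.random.default_rng(spec.seed)
    ii, jj, kk = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    placed = 0
    attempts = 0
    while placed < spec.n_regions and attempts < 200:
        attempts += 1
        c = rng.uniform(0.25 * n, 0.75 * n, size=3)
        r = rng.uniform(0.045 * n, 0.075 * n)
        blob = ((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2) <= r**2
        inside = blob & (labels == LABEL_WM)
        # keep blobs fully in WM and clear of the lesion site
        if inside.sum() < blob.sum() * 0.9 or inside.sum() == 0:
            continue
        if np.linalg.norm(c - center_vox) < r + max(radius, spec.lesion.radius) + 2:
            continue
        labels[inside] = SUBREGION_LABEL_START + placed
        placed += 1
    if placed < spec.n_regions:
        raise RuntimeError(f"could only place {placed}/{spec.n_regions} subregions")

    if radius > 0:
        lesion = (
            (ii - center_vox[0]) ** 2 + (jj - center_vox[1]) ** 2 + (kk - center_vox[2]) ** 2
        ) <= radius**2
        labels[lesion] = LABEL_LESION

    return Volume(labels, (spec.voxel_spacing,) * 3, tag="labels")


def render_style(labels: Volume, style: StyleParams, seed: int) -> Volume:
    """Render a label volume into a [0, 1] intensity volume under one style.

    Per-tissue base means pass through ``x**gamma``, then a multiplicative
    degree-2 polynomial bias field, then additive Gaussian noise; the result
    is clipped to [0, 1].
    """
    lab = np.asarray(labels.data).astype(np.int32)
    n = lab.shape[0]
    base = np.zeros(lab.shape, dtype=np.float64)
    for tissue, mean in style.tissue_means.items():
        base[lab == tissue] = mean
    # subregions render slightly off their host WM intensity so they are visible
    wm_mean = style.tissue_means.get(LABEL_WM, 0.65)
    sub = lab >= SUBREGION_LABEL_START
    sub &= lab != LABEL_LESION
    if sub.any():
        offsets = 0.04 * (1 + (lab[sub] - SUBREGION_LABEL_START) % 3)
        base[sub] = np.clip(wm_mean + offsets * np.where((lab[sub] % 2) == 0, 1, -1), 0, 1)

    styled = np.power(np.clip(base, 0, 1), style.gamma)

    x, y, z = _coord_grids(n)
    cx, cy, cz, cxx, cyy, czz = style.bias_coeffs
    bias = 1.0 + cx * x + cy * y + cz * z + cxx * x**2 + cyy * y**2 + czz * z**2
    out = styled * bias
    if style.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, style.noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 1.0)
    return Volume(out.astype(np.float32), labels.spacing, labels.affine.copy())


def make_longitudinal_pair(
    spec: PhantomSpec,
) -> tuple[Volume, Volume, PhantomGroundTruth]:
    """Generate one subject: baseline (style A), follow-up (style B, lesion
    radius scaled by 1 + radius_change_fraction, then rigidly misaligned),
    and the full ground truth."""
    labels_bl = make_anatomy(spec)
    fu_radius = spec.lesion.radius * (1.0 + spec.lesion.radius_change_fraction)
    labels_fu = make_anatomy(spec, lesion_radius=fu_radius)

    bl = render_style(labels_bl, spec.style_A, seed=spec.seed * 7919 + 1)
    fu_aligned = render_style(labels_fu, spec.style_B, seed=spec.seed * 7919 + 2)

    lesion_bl = (np.asarray(labels_bl.data) == LABEL_LESION).astype(np.uint8)
    lesion_fu = (np.asarray(labels_fu.data) == LABEL_LESION).astype(np.uint8)

    t = spec.misalignment
    if t.is_identity():
        fu = fu_aligned
        lesion_fu_moved = lesion_fu
    else:
        fu = apply_rigid(fu_aligned, t, order=1)
        lesion_fu_moved = (
            apply_rigid(Volume(lesion_fu.astype(np.float32), bl.spacing), t, order=0).data
            > 0.5
        ).astype(np.uint8)

    bl = Volume(bl.data, bl.spacing, bl.affine, tag="bl")
    fu = Volume(fu.data, fu.spacing, fu.affine, tag="fu")
    truth = PhantomGroundTruth(
        region_label_volume=labels_bl,
        lesion_mask_bl=Volume(lesion_bl, bl.spacing, tag="lesion_bl"),
        lesion_mask_fu=Volume(lesion_fu_moved, fu.spacing, tag="lesion_fu"),
        background_mask=Volume(
            (np.asarray(labels_bl.data) == LABEL_BACKGROUND).astype(np.uint8),
            bl.spacing,
            tag="background",
        ),
        applied_transform=t,
        style_params=(spec.style_A, spec.style_B),
        seed=spec.seed,
    )
    return bl, fu, truth


def make_dataset(
    n_subjects: int,
    spec_template: PhantomSpec,
    seed: int,
    out_dir: str | os.PathLike,
) -> pd.DataFrame:
    """Write ``n_subjects`` phantom pairs plus masks as NIfTI and a CSV
    manifest (columns subject_id, visit, style, file, seed)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n_subjects):
        sid = f"sub-{i:03d}"
        sub_seed = seed * 100003 + i
        spec = dataclasses.replace(spec_template, seed=sub_seed)
        bl, fu, truth = make_longitudinal_pair(spec)
        files = {
            ("bl", "A"): (bl, f"{sid}_bl.nii.gz"),
            ("fu", "B"): (fu, f"{sid}_fu.nii.gz"),
            ("labels", "-"): (truth.region_label_volume, f"{sid}_labels.nii.gz"),
            ("lesion_bl", "-"): (truth.lesion_mask_bl, f"{sid}_lesion_bl.nii.gz"),
            ("lesion_fu", "-"): (truth.lesion_mask_fu, f"{sid}_lesion_fu.nii.gz"),
            ("background", "-"): (truth.background_mask, f"{sid}_background.nii.gz"),
        }
        for (visit, style), (vol, fname) in files.items():
            path = os.path.join(out_dir, fname)
            try:
                save_volume(vol, path)
            except Exception as exc:
                raise IOError(f"failed writing {path}: {exc}") from exc
            rows.append(
                {"subject_id": sid, "visit": visit, "style": style, "file": path, "seed": sub_seed}
            )
        with open(os.path.join(out_dir, f"{sid}_transform.json"), "w") as fh:
            fh.write(truth.applied_transform.to_json())
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
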