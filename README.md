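# longiharm

Paired longitudinal harmonization of interscanner 3D T1-weighted MR volumes
with a cycle-consistent adversarial translation model, plus a synthetic
longitudinal phantom generator and a full quantitative evaluation suite.

A subject's baseline (BL) and follow-up (FU) scans acquired on different
scanners differ in contrast and intensity even when anatomy is stable. This
package trains a two-domain translation model on registered BL/FU axial
slice pairs whose objective combines:

- an **adversarial loss** (cross-entropy patch discriminator),
- a **cycle-consistency loss** (L1 on A→B→A round trips), and
- an **original matching loss** — a four-term L1 penalty tying every
  generator/domain combination of a registered pair back to the originals
  (`||x_A − G_A(x_B)|| + ||x_A − G_A(x_A)|| + ||x_B − G_B(x_A)|| +
  ||x_B − G_B(x_B)||`), weighted λ_oml (default 10, with λ_adv = 1 and
  λ_ccl = 5),

trained with Adam (β₁ = 0.5, β₂ = 0.99), learning rate 2·10⁻⁴ decayed
linearly to 0. Inference translates each retained axial slice, re-stacks
the volume (top/bottom 10 % pass through unchanged) and restores the
original intensity range.

The neural network layer stack is a small self-contained numpy
implementation (`longiharm.nn`) with explicit forward/backward passes —
no GPU or deep-learning framework required.

## Modules

| Module | Contents |
| --- | --- |
| `longiharm.phantom` | paired longitudinal two-scanner-style phantoms with ground truth (labels, lesions, styles, rigid misalignment) |
| `longiharm.ioprep` | NIfTI I/O, grid resampling, invertible min-max normalization, rigid registration, axial slice extraction/pairing |
| `longiharm.metrics` | SSIM (global/sliding, 2D/3D), PSNR, LPIPS (injected extractor), CNR + difference tables, Dice, average Hausdorff |
| `longiharm.gan` | generators/discriminators, the loss terms, checkpointing |
| `longiharm.train` | training loop, LR schedule, subject-level 8:2 split, λ_oml ablation runner |
| `longiharm.evaluate` | volume harmonization/reconstruction, histogram-matching baseline, three-condition evaluation, Wilcoxon signed-rank and paired t tests, reports |
| `longiharm.cli` | `longiharm` command-line entry point |

## CLI

```bash
longiharm phantom --n 20 --size 64 --seed 7 --out data/            # synthetic dataset
longiharm preprocess --bl bl.nii.gz --fu fu.nii.gz --out prep/     # resample/normalize/register/slice
longiharm train --data data/manifest.csv --out run/ --preset ci    # ci: 64³ tiny model; full: paper-scale
longiharm ablate --data data/manifest.csv --lambdas 0,1,5,10,15 --out ablation/
longiharm harmonize --fu fu.nii.gz --ckpt run/ckpt_final --out harmonized.nii.gz
longiharm baseline-histmatch --src fu.nii.gz --ref bl.nii.gz --out matched.nii.gz
longiharm evaluate --bl bl.nii.gz --fu fu.nii.gz --harmonized harmonized.nii.gz \
    --regions labels.nii.gz --background bg.nii.gz --out report/
```

Every output directory receives a `run_config.json` with the resolved
configuration and seed needed to reproduce the run.

## Notes and limitations

- Phantom noise is Gaussian, not Rician; scanner styles are per-tissue
  contrast + gamma + polynomial bias field, not MR physics.
- Registration maximizes edge-masked gradient-magnitude NCC; the contract
  is parameter recovery on phantoms, not parity with any external package.
- LPIPS is interface-only: a feature extractor is injected; published
  pretrained-weight parity is out of scope.
- No multiple-testing correction is applied (raw p-values, α = 0.05).
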