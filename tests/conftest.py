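"""Shared fixtures.

The expensive fixtures (registration recovery, the scaled-down ablation
study) are session-scoped and shared between the unit tests and the
acceptance tests so the whole suite stays inside its CPU budget.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from longiharm import evaluate as ev
from longiharm import ioprep, metrics
from longiharm import phantom as ph
from longiharm import train as tr
from longiharm.gan import DiscriminatorSpec, GeneratorSpec, LossWeights

# scaled-down study dimensions (one CPU budget)
N_TRAIN, N_VAL = 10, 4
ABLATION_SEEDS = (0, 1, 2)
ABLATION_ITERATIONS = 1200
ABLATION_LAMBDAS = (0.0, 10.0)


def small_train_config(seed: int, lambda_oml: float,
                       iterations: int = ABLATION_ITERATIONS) -> tr.TrainConfig:
    # discriminator is deliberately not undersized: without real adversarial
    # pressure the lambda_oml=0 arm never degrades and the ablation
    # direction collapses into a tie
    return tr.TrainConfig(
        batch_size=4,
        total_iterations=iterations,
        seed=seed,
        loss_weights=LossWeights(lambda_oml=lambda_oml),
        gen_spec=GeneratorSpec(base_filters=8, n_residual_blocks=1, norm="none"),
        disc_spec=DiscriminatorSpec(base_filters=16, n_layers=3),
    )


@pytest.fixture(scope="session")
def default_phantom_pair():
    spec = ph.PhantomSpec(seed=11)
    return spec, ph.make_longitudinal_pair(spec)


@pytest.fixture(scope="session")
def registration_results():
    """Recover two known misalignments (translation-only; rotation +
    translation) once for both the unit and the acceptance tests."""
    results = {}
    for name, mis in (
        ("shift", ioprep.RigidTransform((0.0, 0.0, 0.0), (3.0, 0.0, 0.0))),
        ("rot", ioprep.RigidTransform((5.0, 0.0, 0.0), (3.0, 0.0, 0.0))),
    ):
        spec = dataclasses.replace(ph.PhantomSpec(seed=3), misalignment=mis)
        bl, fu, _ = ph.make_longitudinal_pair(spec)
        _, recovered = ioprep.rigid_register(fu, bl)
        results[name] = {
            "expected": mis.inverse().params,
            "recovered": recovered.params,
        }
    return results


@pytest.fixture(scope="session")
def ablation_study():
    """Scaled-down replication: train both matching-loss arms on 64-cubed
    phantoms over three seeds, then evaluate the held-out subjects slice-
    and volume-wise, including CNR differences and the histogram-matching
    baseline. Shared by the training-convergence and acceptance tests."""
    ssim_cfg = metrics.SSIMConfig()
    per_seed = []
    for seed in ABLATION_SEEDS:
        subjects, truths = tr.subjects_from_phantoms(N_TRAIN + N_VAL, seed=seed + 50)
        split = tr.split_subjects(subjects, N_VAL / (N_TRAIN + N_VAL), seed)
        val_ids = {s.subject_id for s in split[1]}
        arms = {}
        for lam in ABLATION_LAMBDAS:
            result = tr.train(small_train_config(seed, lam), subjects, presplit=split)
            slice_rows = {"ssim_harm": [], "ssim_orig": [], "ssim_recon": [],
                          "psnr_harm": [], "psnr_orig": []}
            for s in split[1]:
                harm = result.models["G_BL"].translate_slices(s.fu_slices)
                recon = result.models["G_BL"].translate_slices(
                    result.models["G_FU"].translate_slices(s.bl_slices)
                )
                for k in range(0, len(s.bl_slices), 6):
                    ref = s.bl_slices[k]
                    slice_rows["ssim_orig"].append(metrics.ssim(ref, s.fu_slices[k], ssim_cfg))
                    slice_rows["ssim_harm"].append(metrics.ssim(ref, harm[k], ssim_cfg))
                    slice_rows["ssim_recon"].append(metrics.ssim(ref, recon[k], ssim_cfg))
                    slice_rows["psnr_orig"].append(metrics.psnr(ref, s.fu_slices[k]))
                    slice_rows["psnr_harm"].append(metrics.psnr(ref, harm[k]))
            arms[lam] = {"log": result.log,
                         "slice": {k: float(np.mean(v)) for k, v in slice_rows.items()},
                         "models": result.models}
        # volume-level evaluation with the lambda=10 model
        models = arms[10.0]["models"]
        vol = {"ssim_orig": [], "ssim_harm": [], "ssim_hist": [],
               "psnr_orig": [], "psnr_harm": [], "psnr_hist": [],
               "cnr_orig": [], "cnr_harm": []}
        idx = [i for i, s in enumerate(subjects) if s.subject_id in val_ids]
        for i in idx:
            spec = dataclasses.replace(ph.PhantomSpec(), seed=(seed + 50) * 1000 + i)
            bl, fu, truth = ph.make_longitudinal_pair(spec)
            harm = ev.harmonize_volume(fu, models["G_BL"])
            hist = ev.histogram_match(fu, bl)
            b, f, h, m = (np.asarray(v.data, dtype=np.float64)
                          for v in (bl, fu, harm, hist))
            cfg3 = metrics.SSIMConfig()
            vol["ssim_orig"].append(metrics.ssim(b, f, cfg3))
            vol["ssim_harm"].append(metrics.ssim(b, h, cfg3))
            vol["ssim_hist"].append(metrics.ssim(b, m, cfg3))
            vol["psnr_orig"].append(metrics.psnr(b, f))
            vol["psnr_harm"].append(metrics.psnr(b, h))
            vol["psnr_hist"].append(metrics.psnr(b, m))
            labels = np.asarray(truth.region_label_volume.data)
            regions = {
                f"region_{lab}": labels == lab
                for lab in np.unique(labels)
                if lab >= ph.SUBREGION_LABEL_START and lab != ph.LABEL_LESION
            }
            bg = np.asarray(truth.background_mask.data) > 0
            t_orig = metrics.cnr_difference_table(b, f, regions, bg)
            t_harm = metrics.cnr_difference_table(b, h, regions, bg)
            vol["cnr_orig"].append(float(t_orig["cnr_difference"].mean()))
            vol["cnr_harm"].append(float(t_harm["cnr_difference"].mean()))
        arms[10.0].pop("models")
        arms[0.0].pop("models")
        per_seed.append({"seed": seed, "arms": arms, "volume": vol})
    return per_seed
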