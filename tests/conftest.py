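"""Shared fixtures: synthetic half-map studies and the smoke-trained model.

The expensive objects (64^3 SSNR-1 study, the 20-epoch smoke training
run) are session-scoped so the property, unit and acceptance tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import crefdenoise as cd

#: generator seed of the 64^3 flat-SSNR-1 study used across the suite
STUDY_SEED = 11

#: smoke-training conditions: tiny U-Net, 32^3 patches, short schedule
SMOKE_MODEL = dict(depth=2, base_filters=4, seed=42)
SMOKE_TRAIN = dict(lr0=3e-3, epochs=20, batch=6, seed=42)


@pytest.fixture(scope="session")
def synth64() -> cd.SyntheticSet:
    """64^3 blob phantom with two half-maps at flat SSNR 1."""
    spec = cd.SyntheticSpec(shape=(64,) * 3, ssnr=1.0, seed=STUDY_SEED)
    truth = cd.make_phantom(spec)
    return cd.make_half_maps(truth, spec)


@pytest.fixture(scope="session")
def bias64() -> cd.SyntheticSet:
    """Same study with injected denoised-like maps D_i = S + B + 0.5 N_i,
    var_B = 0.25 var_S per shell."""
    spec = cd.SyntheticSpec(
        shape=(64,) * 3,
        ssnr=1.0,
        seed=STUDY_SEED,
        bias_scale=0.25,
        bias_mode="match_signal",
        leftover_noise=0.5,
    )
    truth = cd.make_phantom(spec)
    sset = cd.make_half_maps(truth, spec)
    return cd.inject_bias(truth, sset, spec)


@pytest.fixture(scope="session")
def smoke_run() -> dict:
    """One 20-epoch smoke training run on 60 synthetic 32^3 patch pairs.

    Returns the trained model, its history, and everything needed to
    measure denoising gain against the known ground truth.
    """
    spec = cd.SyntheticSpec(shape=(128,) * 3, ssnr=1.0, seed=7)
    truth = cd.make_phantom(spec)
    sset = cd.make_half_maps(truth, spec)
    m1s = cd.standardize(sset.m1, sset.mask)
    m2s = cd.standardize(sset.m2, sset.mask)
    pairs = cd.tile_patches(m1s, m2s, sset.mask, edge=32, source_id="sim")[:60]
    assert len(pairs) == 60
    dcfg = cd.DenoiserConfig(**SMOKE_MODEL)
    tcfg = cd.TrainConfig(**SMOKE_TRAIN)
    model, history = cd.train_denoiser(pairs, dcfg, tcfg)
    mean_map = m1s.with_values(0.5 * (m1s.values + m2s.values))
    return {
        "model": model,
        "history": history,
        "dcfg": dcfg,
        "tcfg": tcfg,
        "pairs": pairs,
        "m1": m1s,
        "m2": m2s,
        "mean_map": mean_map,
        "truth": cd.standardize(sset.truth, sset.mask),
        "partition": sset.partition,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
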