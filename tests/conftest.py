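"""Shared fixtures: small-geometry synthetic datasets reused across tests.

Frames are simulated at reduced size (256 x 320 with a proportionally
scaled-down fiber bundle) so the full optics chain stays fast; the geometry
(mosaic, comb pitch, bundle coverage) is the same as at full sensor size.
"""

from __future__ import annotations

import numpy as np
import pytest

import snapmsi as sm
from snapmsi.workflow import process_dataset

SMALL_SHAPE = (256, 320)
SMALL_CORES = int(10000 * SMALL_SHAPE[0] * SMALL_SHAPE[1] / (1024 * 1280))


def small_dataset(**overrides):
    kw = dict(
        seed=1,
        separation=0.3,
        n_patients=3,
        regions_per_patient=3,
        cubes_per_region=2,
        sigma_patient=0.02,
        sigma_image=0.02,
        sigma_pixel=0.05,
    )
    sim_kw = dict(
        frame_shape=SMALL_SHAPE,
        n_cores=SMALL_CORES,
        n_white_frames=3,
    )
    for k in list(overrides):
        if k in sim_kw or k in (
            "illumination_falloff",
            "specular",
            "dark_level",
            "white_level",
        ):
            sim_kw[k] = overrides.pop(k)
    kw.update(overrides)
    seed = kw.pop("seed")
    separation = kw.pop("separation")
    model = sm.generate_class_spectra(seed, separation, **kw)
    return model, sm.simulate_procedure_dataset(model, **sim_kw)


@pytest.fixture(scope="session")
def tissue_dataset():
    """18-cube noisy tissue dataset (3 patients x 3 regions x 2 cubes)."""
    return small_dataset()


@pytest.fixture(scope="session")
def processed_tissue(tissue_dataset):
    _, ds = tissue_dataset
    return process_dataset(ds, block=32)


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise, flat-illumination, specular-free dataset for recovery
    tests: downstream values should match the class means."""
    return small_dataset(
        n_patients=1,
        regions_per_patient=3,
        cubes_per_region=1,
        sigma_patient=0.0,
        sigma_image=0.0,
        sigma_pixel=0.0,
        illumination_falloff=0.0,
        specular=False,
    )


@pytest.fixture(scope="session")
def processed_clean(clean_dataset):
    _, ds = clean_dataset
    return process_dataset(ds, block=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
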