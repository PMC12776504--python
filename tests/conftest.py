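"""Shared fixtures.

The cohort fixture runs the complete forward + inverse + connectivity chain
once per session at the default study conditions (22 subjects per group,
180 s at 500 Hz, 64 sensors); the heavyweight acceptance checks share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdcnet import synth
from pdcnet.atlas import default_atlas
from pdcnet.config import PipelineConfig
from pdcnet.pipeline import localize, preprocess_sensor, subject_connectivity

COHORT_SEED = 42


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def cohort(default_config):
    """HC + stroke-pre cohort (22 subjects each) with per-subject band-wise
    PDC connectivity, ground truth and the leadfield."""
    cfg = default_config
    recordings, truth, lf = synth.generate_cohort(
        22, ("HC", "stroke_pre"), seed=COHORT_SEED,
    )
    conn = {}
    for rec in recordings:
        epochs = localize(preprocess_sensor(rec, cfg), lf, cfg)
        conn[(rec.subject_id, rec.session)] = subject_connectivity(
            epochs, cfg)
    return {"connectivity": conn, "truth": truth, "leadfield": lf,
            "recordings": recordings}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_stable_mvar(rng, n_regions=4, order=2, radius=0.8):
    """Random MVAR coefficient stack rescaled to a target spectral radius.

    Scaling lag r by gamma^r multiplies every companion eigenvalue by gamma,
    so the returned system has spectral radius exactly ``radius`` (up to
    float error) whenever the draw is not degenerate.
    """
    from pdcnet.synth import companion_spectral_radius

    A = rng.standard_normal((order, n_regions, n_regions)) * 0.5
    sr = companion_spectral_radius(A)
    if sr <= 0:
        return A
    gamma = radius / sr
    return A * gamma ** np.arange(1, order + 1)[:, None, None]
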