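"""Shared fixtures: phantoms and (expensive) full pipeline runs.

Pipeline results are session-scoped so the acceptance tests and the
stage-level tests share one run per preset.
"""

from __future__ import annotations

import numpy as np
import pytest

from thoraxseg.phantom import generate_phantom, preset
from thoraxseg.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def clean_phantom():
    return generate_phantom(preset("clean", seed=1))


@pytest.fixture(scope="session")
def clean_result(clean_phantom):
    ct, _ = clean_phantom
    return run_pipeline(ct)


@pytest.fixture(scope="session")
def fused_phantom():
    return generate_phantom(preset("fused", seed=1))


@pytest.fixture(scope="session")
def fused_result(fused_phantom):
    ct, _ = fused_phantom
    return run_pipeline(ct)


@pytest.fixture(scope="session")
def open_ring_phantom():
    return generate_phantom(preset("open-ring", seed=1))


@pytest.fixture(scope="session")
def open_ring_result(open_ring_phantom):
    ct, _ = open_ring_phantom
    return run_pipeline(ct)


@pytest.fixture(scope="session")
def tumor_phantoms():
    """Both tumour presets, with their pipeline results with and without
    the pathology-inclusion stage."""
    out = {}
    for name in ("tumor-small", "tumor-large"):
        ct, truth = generate_phantom(preset(name, seed=1))
        out[name] = {
            "ct": ct,
            "truth": truth,
            "with": run_pipeline(ct),
            "without": run_pipeline(ct, PipelineConfig(include_pathology=False)),
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape, p=0.5, smooth=1.0):
    """Random connected-ish boolean mask for property tests."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.standard_normal(shape), smooth)
    return field > np.quantile(field, p)
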