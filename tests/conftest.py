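"""Shared fixtures: phantom datasets and pipeline records are generated
in-memory once per session so the heavier end-to-end tests reuse them."""

from __future__ import annotations

import numpy as np
import pytest

from masseg import PhantomSpec, generate_phantom


def cases_to_records(cases):
    """Convert PhantomCase objects to the record dicts run_pipeline uses."""
    return [
        {
            "image_id": c.image_id,
            "image": c.image,
            "boxes": list(c.boxes),
            "masks": list(c.masks),
            "severities": [l.severity_label for l in c.lesions],
        }
        for c in cases
    ]


@pytest.fixture(scope="session")
def phantom_cases():
    """30-image phantom study set: contrast >= 0.4, noise sigma 0.03."""
    spec = PhantomSpec(
        n_images=30, noise_sigma=0.03, contrast_range=(0.4, 0.6), seed=11
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_records(phantom_cases):
    return cases_to_records(phantom_cases)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
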