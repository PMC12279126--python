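"""Shared fixtures: phantoms and small survival datasets, generated on the fly."""
from __future__ import annotations

import numpy as np
import pytest

from apexfa.phantom import PhantomParams, generate_phantom
from apexfa.pipeline import PipelineConfig, segment_radiograph


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free circular phantom: D=10 mm, w=0.4 mm, analytic profile."""
    params = PhantomParams(
        lesion_diameter=10.0, transition_width=0.4, noise_sd=0.0,
        trabecular_amplitude=0.0, seed=0,
    )
    image, contour = generate_phantom(params)
    return params, image, contour


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with trabecular texture and detector noise."""
    params = PhantomParams(lesion_diameter=10.0, transition_width=0.4, seed=3)
    image, contour = generate_phantom(params)
    return params, image, contour


@pytest.fixture(scope="session")
def segmented_phantom(noisy_phantom):
    """Canny contour and S1/S2/S3 masks of the noisy phantom."""
    params, image, _ = noisy_phantom
    cfg = PipelineConfig()
    contour, rois = segment_radiograph(
        image, (image.shape[0] // 2, image.shape[1] // 2), cfg
    )
    return image, contour, rois


def weibull_ph_sample(rng, X, beta, shape=1.3, scale=2.0, censor_q=0.8):
    """Latent Weibull-PH times with admin censoring at a quantile (test helper)."""
    lp = X @ np.asarray(beta)
    T = scale * (-np.log(rng.random(len(X))) / np.exp(lp)) ** (1.0 / shape)
    C = np.quantile(T, censor_q)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return time, event
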