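"""Shared fixtures: small phantom exams generated programmatically."""

import numpy as np
import pytest

from aortaflow.io import PCSeries, SegmentationMap
from aortaflow.phantom import PhantomSpec, generate


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Noiseless 64x64 phantom, 6 frames — fast enough for every module."""
    return PhantomSpec(n_frames=6, noise_sigma=0.0, exam_id="fixture-exam")


@pytest.fixture(scope="session")
def small_exam(small_spec):
    return generate(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_series_and_mask(rng, n_frames, h, w):
    """Random (series, mask) pair for oracle-equivalence tests."""
    series = PCSeries(
        magnitude=rng.uniform(0, 1000, (n_frames, h, w)),
        phase=rng.uniform(-4096, 4096, (n_frames, h, w)),
        venc=float(rng.uniform(100, 300)),
        recon_scale=1.0,
        pixel_area=float(rng.uniform(0.005, 0.05)),
        frame_interval=float(rng.uniform(0.02, 0.06)),
    )
    mask = SegmentationMap((rng.random((n_frames, h, w)) < 0.2).astype(np.uint8))
    return series, mask
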