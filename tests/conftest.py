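"""Shared fixtures: small synthetic datasets and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import ecgi_bench as eb
from ecgi_bench.inverse import SVDCache


def shaw(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Classic severely ill-conditioned 1-D image-restoration test problem
    (discretized first-kind Fredholm equation); returns (A, x_true)."""
    h = np.pi / n
    t = -np.pi / 2 + (np.arange(n) + 0.5) * h
    co = np.cos(t)
    psi = np.pi * np.sin(t)
    A = np.empty((n, n))
    for i in range(n):
        ps = psi[i] + psi
        s = np.where(np.abs(ps) < 1e-14, 1.0, np.sin(ps) / np.where(ps == 0, 1.0, ps))
        A[i] = h * ((co[i] + co) * s) ** 2
    x = 2 * np.exp(-6 * (t - 0.8) ** 2) + np.exp(-2 * (t + 0.5) ** 2)
    return A, x


@pytest.fixture(scope="session")
def noisy_config() -> eb.StudyConfig:
    return eb.StudyConfig(seed=7)


@pytest.fixture(scope="session")
def noisy_dataset(noisy_config) -> "eb.pipeline.StudyDataset":
    """Default desk-scale noisy dataset (162 epi nodes, 162 torso leads,
    5 beats at 1000 Hz, 50 Hz line)."""
    return eb.build_dataset(noisy_config)


@pytest.fixture(scope="session")
def clean_dataset() -> "eb.pipeline.StudyDataset":
    cfg = eb.StudyConfig(
        seed=7, noise=eb.NoiseSpec(line_amp_mV=0.0, white_sd_mV=0.0, drift_amp_mV=0.0)
    )
    return eb.build_dataset(cfg)


@pytest.fixture(scope="session")
def forward_svd(noisy_dataset) -> SVDCache:
    return SVDCache.of(noisy_dataset.forward.A)


@pytest.fixture(scope="session")
def beat_recording() -> eb.PotentialRecording:
    """Small multi-lead paced recording with ground-truth segmentation
    (no forward projection, no noise)."""
    mesh = eb.icosphere(1, 30.0)
    act = eb.simulate_activation(mesh, 0, 1.0)
    return eb.simulate_epicardial_beats(act, eb.BeatTemplate(), n_beats=5, fs_hz=1000.0, seed=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
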