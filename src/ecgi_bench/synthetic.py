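"""Synthetic torso-tank data generation.

Produces ground-truth epicardial electrograms from a paced activation
sequence, projects them to the torso surface through a forward model, and
contaminates the torso signals with the noise classes that ECG processing
targets: power-line interference, broadband channel noise, and
low-frequency baseline drift.  Every generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .bem import ForwardModel
from .mesh import ActivationMap, SurfaceMesh, generate_concentric_meshes  # noqa: F401
from .recording import BeatSegmentation, BeatTemplate, NoiseSpec, PotentialRecording


def simulate_activation(
    mesh: SurfaceMesh, pacing_node: int, velocity_mm_per_ms: float
) -> ActivationMap:
    """Activation times from single-site pacing: geodesic (shortest-path on
    the edge graph) distance from the pacing node divided by the conduction
    velocity.  The pacing node activates at t = 0."""
    if not 0 <= pacing_node < mesh.n_nodes:
        raise ValueError(f"pacing_node {pacing_node} out of range")
    if velocity_mm_per_ms <= 0:
        raise ValueError("velocity must be positive")
    e = mesh.edges()
    w = np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=-1)
    n = mesh.n_nodes
    g = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    dist = dijkstra(g, directed=False, indices=pacing_node)
    if np.any(np.isinf(dist)):
        unreachable = np.nonzero(np.isinf(dist))[0]
        raise ValueError(f"mesh has disconnected component; unreachable nodes: {unreachable.tolist()}")
    return ActivationMap(dist / velocity_mm_per_ms, mesh, mesh.nodes[pacing_node].copy())


def simulate_epicardial_beats(
    act_map: ActivationMap,
    template: BeatTemplate,
    n_beats: int,
    fs_hz: float,
    jitter_ms: float = 0.0,
    seed: int = 0,
    line_freq_hz: float = 50.0,
) -> PotentialRecording:
    """Render paced epicardial electrograms: lead i shows the template
    time-shifted by its activation time in every beat.

    Beat onsets are separated by the template cycle length plus Gaussian
    jitter; the recording carries the true beat segmentation (QRS windows
    and pre-QRS isoelectric windows).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs_hz < 4 * template.max_freq_hz():
        raise ValueError(
            f"fs {fs_hz} Hz below 4x template frequency content ({template.max_freq_hz():.0f} Hz)"
        )
    at = act_map.times_ms
    at_span = at.max() - at.min()
    if template.qrs_duration_ms + at_span >= template.cycle_length_ms:
        raise ValueError("QRS window (activation span + QRS duration) exceeds cycle length")

    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_ms, size=n_beats) if jitter_ms > 0 else np.zeros(n_beats)
    jitter[0] = 0.0

    half = template.qrs_duration_ms / 2
    t0 = half - at.min() + 100.0  # leave room for the pre-QRS isoelectric window
    onsets_ms = t0 + np.arange(n_beats) * template.cycle_length_ms + jitter
    tail = at.max() + template.t_delay_ms + template.t_duration_ms + 60.0
    n_samples = int(np.ceil((onsets_ms[-1] + tail) * fs_hz / 1000.0))
    t_ms = np.arange(n_samples) * 1000.0 / fs_hz

    values = np.zeros((len(at), n_samples))
    for onset in onsets_ms:
        # lead i activates at onset + at[i]
        rel = t_ms[None, :] - (onset + at[:, None])
        values += template.render(rel)

    iso_len = int(round((20.0 if line_freq_hz <= 55 else 17.0) * fs_hz / 1000.0))
    qrs_on = np.round((onsets_ms + at.min() - half) * fs_hz / 1000.0).astype(int)
    # constant QRS window length across beats (jitter shifts onsets only)
    qrs_len = int(round((at_span + template.qrs_duration_ms) * fs_hz / 1000.0))
    qrs_off = qrs_on + qrs_len
    iso_start = qrs_on - iso_len - int(round(0.002 * fs_hz))
    qrst_off = np.minimum(
        np.round((onsets_ms + at.max() + template.t_delay_ms + template.t_duration_ms / 2) * fs_hz / 1000.0).astype(int),
        n_samples,
    )
    seg = BeatSegmentation(qrs_on, qrs_off, iso_start, iso_len, qrst_off)
    return PotentialRecording(values, fs_hz, segmentation=seg, line_freq_hz=line_freq_hz)


def _noise_components(
    noise: NoiseSpec, n_leads: int, n_samples: int, fs_hz: float
) -> dict[str, np.ndarray]:
    """The three additive noise fields, each (n_leads, n_samples)."""
    rng = np.random.default_rng(noise.seed)
    t = np.arange(n_samples) / fs_hz
    # line interference: independent phase per lead, optional harmonics
    line = np.zeros((n_leads, n_samples))
    for k in range(1, noise.harmonics + 2):
        phases = rng.uniform(0, 2 * np.pi, size=n_leads)
        amp = noise.line_amp_mV / k
        line += amp * np.sin(2 * np.pi * k * noise.line_freq_hz * t[None, :] + phases[:, None])
    # broadband channel noise
    white = rng.normal(0.0, noise.white_sd_mV, size=(n_leads, n_samples)) if noise.white_sd_mV > 0 else np.zeros((n_leads, n_samples))
    # baseline drift: three random-phase sinusoids below drift_freq_hz
    drift = np.zeros((n_leads, n_samples))
    freqs = rng.uniform(noise.drift_freq_hz / 4, noise.drift_freq_hz, size=3)
    for f in freqs:
        phases = rng.uniform(0, 2 * np.pi, size=n_leads)
        drift += (noise.drift_amp_mV / 3) * np.sin(2 * np.pi * f * t[None, :] + phases[:, None])
    return {"line": line, "white": white, "drift": drift}


def generate_torso_recording(
    forward: ForwardModel, epi: PotentialRecording, noise: NoiseSpec
) -> PotentialRecording:
    """Project epicardial potentials to the torso (y = A x) and add
    measurement noise per the noise specification.

    Setting all noise amplitudes to zero recovers the clean projection
    exactly; the beat segmentation is copied from the epicardial record.
    """
    A = forward.A
    if A.shape[1] != epi.n_leads:
        raise ValueError(
            f"forward source dimension {A.shape[1]} does not match epicardial lead count {epi.n_leads}"
        )
    y = A @ epi.values
    comps = _noise_components(noise, y.shape[0], y.shape[1], epi.fs_hz)
    y = y + comps["line"] + comps["white"] + comps["drift"]
    return PotentialRecording(
        y,
        epi.fs_hz,
        segmentation=epi.segmentation,
        line_freq_hz=noise.line_freq_hz,
    )
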