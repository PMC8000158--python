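"""Multi-lead potential recordings and beat segmentation.

Potentials are stored leads x samples in mV; sampling rates in Hz; times in
ms.  A :class:`BeatSegmentation` carries per-beat QRS windows and the
pre-QRS isoelectric windows that the baseline metrics and the simple
baseline correction rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class BeatSegmentation:
    """Per-beat sample indices: QRS windows and pre-QRS isoelectric windows.

    ``iso_start[k] .. iso_start[k] + iso_len`` must end at or before
    ``qrs_onset[k]``.  ``qrst_offset`` bounds the window used for beat
    averaging (QRST interval).
    """

    qrs_onset: np.ndarray
    qrs_offset: np.ndarray
    iso_start: np.ndarray
    iso_len: int
    qrst_offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.qrs_onset = np.asarray(self.qrs_onset, dtype=np.int64)
        self.qrs_offset = np.asarray(self.qrs_offset, dtype=np.int64)
        self.iso_start = np.asarray(self.iso_start, dtype=np.int64)
        if self.qrst_offset is not None:
            self.qrst_offset = np.asarray(self.qrst_offset, dtype=np.int64)
        if np.any(self.iso_start + self.iso_len > self.qrs_onset):
            raise ValueError("isoelectric window must end at or before QRS onset")
        if np.any(np.diff(self.qrs_onset) <= 0):
            raise ValueError("beats must be ordered")
        if np.any(self.qrs_offset[:-1] > self.qrs_onset[1:]):
            raise ValueError("beats must not overlap")
        if np.any(self.qrs_offset <= self.qrs_onset):
            raise ValueError("QRS offset must follow onset")

    @property
    def n_beats(self) -> int:
        return len(self.qrs_onset)

    def qrs_window(self, beat: int) -> slice:
        return slice(int(self.qrs_onset[beat]), int(self.qrs_offset[beat]))

    def iso_window(self, beat: int) -> slice:
        s = int(self.iso_start[beat])
        return slice(s, s + int(self.iso_len))

    def beat_regions(self, n_samples: int) -> list[slice]:
        """Partition of the record into per-beat regions (midpoints between
        consecutive QRS onsets; first/last regions extend to the ends)."""
        on = self.qrs_onset
        bounds = [0] + [int((on[i] + on[i + 1]) // 2) for i in range(len(on) - 1)] + [n_samples]
        return [slice(bounds[i], bounds[i + 1]) for i in range(len(on))]

    def to_dict(self) -> dict:
        d = {
            "qrs_onset": self.qrs_onset.tolist(),
            "qrs_offset": self.qrs_offset.tolist(),
            "iso_start": self.iso_start.tolist(),
            "iso_len": int(self.iso_len),
        }
        if self.qrst_offset is not None:
            d["qrst_offset"] = self.qrst_offset.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BeatSegmentation":
        return cls(
            np.array(d["qrs_onset"]),
            np.array(d["qrs_offset"]),
            np.array(d["iso_start"]),
            int(d["iso_len"]),
            np.array(d["qrst_offset"]) if "qrst_offset" in d else None,
        )


@dataclass
class PotentialRecording:
    """Leads x samples potential matrix with sampling rate and metadata."""

    values: np.ndarray  # (n_leads, n_samples), mV
    fs_hz: float
    lead_ids: list[str] | None = None
    bad_leads: np.ndarray | None = None  # boolean mask, True = bad
    segmentation: BeatSegmentation | None = None
    line_freq_hz: float = 50.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (leads, samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.lead_ids is None:
            self.lead_ids = [f"L{i:03d}" for i in range(self.n_leads)]
        if len(self.lead_ids) != self.n_leads:
            raise ValueError("lead_ids length mismatch")
        if self.bad_leads is None:
            self.bad_leads = np.zeros(self.n_leads, dtype=bool)
        self.bad_leads = np.asarray(self.bad_leads, dtype=bool)
        if self.segmentation is not None:
            if self.segmentation.qrs_offset[-1] > self.n_samples:
                raise ValueError("segmentation window exceeds record length")
        good = self.values[~self.bad_leads]
        if good.size and not np.all(np.isfinite(good)):
            raise ValueError("non-finite values on good leads")

    @property
    def n_leads(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.fs_hz

    def with_values(self, values: np.ndarray) -> "PotentialRecording":
        """Copy carrying new sample values (same layout/metadata)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def good_values(self) -> np.ndarray:
        return self.values[~self.bad_leads]

    def copy(self) -> "PotentialRecording":
        return replace(self, values=self.values.copy())

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Leads x samples CSV with a header row of lead IDs (transposed to
        samples-as-rows for readability); segmentation in a JSON sidecar."""
        df = pd.DataFrame(self.values.T, columns=self.lead_ids)
        df.to_csv(path, index=False, float_format="%.9g")
        meta = {
            "fs_hz": self.fs_hz,
            "line_freq_hz": self.line_freq_hz,
            "bad_leads": self.bad_leads.nonzero()[0].tolist(),
        }
        if self.segmentation is not None:
            meta["segmentation"] = self.segmentation.to_dict()
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PotentialRecording":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed recording CSV {path}: {exc}") from exc
        if df.isna().any().any():
            bad_row = int(df.isna().any(axis=1).idxmax())
            raise ValueError(f"malformed recording CSV {path}: missing field at data row {bad_row}")
        sidecar = Path(str(path) + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"fs_hz": 1000.0}
        bad = np.zeros(df.shape[1], dtype=bool)
        bad[meta.get("bad_leads", [])] = True
        seg = None
        if "segmentation" in meta:
            seg = BeatSegmentation.from_dict(meta["segmentation"])
        return cls(
            df.to_numpy().T,
            float(meta["fs_hz"]),
            list(df.columns),
            bad,
            seg,
            float(meta.get("line_freq_hz", 50.0)),
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.attrs["fs_hz"] = self.fs_hz
            f.attrs["line_freq_hz"] = self.line_freq_hz
            f.create_dataset("lead_ids", data=np.array(self.lead_ids, dtype="S"))
            f.create_dataset("bad_leads", data=self.bad_leads)
            if self.segmentation is not None:
                f.attrs["segmentation"] = json.dumps(self.segmentation.to_dict())

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PotentialRecording":
        with h5py.File(path, "r") as f:
            seg = None
            if "segmentation" in f.attrs:
                seg = BeatSegmentation.from_dict(json.loads(f.attrs["segmentation"]))
            return cls(
                f["values"][()],
                float(f.attrs["fs_hz"]),
                [s.decode() for s in f["lead_ids"][()]],
                f["bad_leads"][()],
                seg,
                float(f.attrs.get("line_freq_hz", 50.0)),
            )


@dataclass
class NoiseSpec:
    """Additive torso-measurement noise: line interference, broadband
    channel noise, and low-frequency baseline drift.

    Amplitudes in mV; ``drift_freq_hz`` is the upper edge of the drift band
    (must stay well below the line frequency).  The same seed always yields
    bit-identical noise.
    """

    line_freq_hz: float = 50.0
    line_amp_mV: float = 0.05
    white_sd_mV: float = 0.05
    drift_amp_mV: float = 1.0
    drift_freq_hz: float = 0.4
    harmonics: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.line_amp_mV, self.white_sd_mV, self.drift_amp_mV) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not self.drift_freq_hz < 0.5 * self.line_freq_hz:
            raise ValueError("drift_freq_hz must be < 0.5 * line_freq_hz")
        if self.harmonics < 0:
            raise ValueError("harmonics must be >= 0")

    def silent(self) -> "NoiseSpec":
        """Copy with all amplitudes zero (clean signal recovery)."""
        return replace(self, line_amp_mV=0.0, white_sd_mV=0.0, drift_amp_mV=0.0)


@dataclass
class BeatTemplate:
    """Parametric unipolar electrogram used to render synthetic beats.

    A biphasic RS wave: smooth sigmoid (tanh) downstroke — the intrinsic
    deflection — under a Gaussian envelope, with an optional T wave.  The
    steepest downslope sits exactly at the activation time, and the rendered
    peak-to-peak amplitude equals ``rs_amplitude_mV``.
    """

    qrs_duration_ms: float = 80.0
    rs_amplitude_mV: float = 10.0
    cycle_length_ms: float = 600.0
    t_wave: bool = True
    t_duration_ms: float = 160.0
    t_amplitude_frac: float = 0.15
    t_delay_ms: float = 180.0  # centre of T wave after activation
    sharpness: float = 6.0  # qrs_duration / downstroke time constant / 2

    def __post_init__(self) -> None:
        if self.qrs_duration_ms <= 0:
            raise ValueError("qrs_duration_ms must be positive")
        if self.cycle_length_ms <= self.qrs_duration_ms:
            raise ValueError("cycle length must exceed QRS duration")

    def max_freq_hz(self) -> float:
        """Rough upper edge of the template's frequency content."""
        tau_ms = self.qrs_duration_ms / (2 * self.sharpness)
        return 1000.0 / tau_ms

    def render(self, t_ms: np.ndarray) -> np.ndarray:
        """Waveform (mV) at times ``t_ms`` relative to the activation time."""
        t = np.asarray(t_ms, dtype=float)
        tau = self.qrs_duration_ms / (2 * self.sharpness)
        sigma = self.qrs_duration_ms / 5.0
        w = -np.tanh(t / tau) * np.exp(-(t**2) / (2 * sigma**2))
        if self.t_wave:
            ts = self.t_duration_ms / 4.0
            w = w + self.t_amplitude_frac * np.exp(
                -((t - self.t_delay_ms) ** 2) / (2 * ts**2)
            )
        # normalize so rendered peak-to-peak equals rs_amplitude exactly
        tf = np.linspace(-self.qrs_duration_ms, self.qrs_duration_ms + self.t_delay_ms, 4096)
        wf = -np.tanh(tf / tau) * np.exp(-(tf**2) / (2 * sigma**2))
        if self.t_wave:
            wf = wf + self.t_amplitude_frac * np.exp(
                -((tf - self.t_delay_ms) ** 2) / (2 * (self.t_duration_ms / 4.0) ** 2)
            )
        p2p = wf.max() - wf.min()
        return w * (self.rs_amplitude_mV / p2p)
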