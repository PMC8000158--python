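"""The torso-signal processing bank: 49 variants.

Seven high-frequency removal methods (HFR1-7), five baseline-drift removal
methods (BDR1-5), their 35 ordered combinations (HFR first, then BDR), the
unprocessed signal (RAW), and PCA-based signal averaging (SA).

Conventions
-----------
* Line-frequency dialects: at 50 Hz the one-cycle window is 20 ms and the
  two-cycle (Pipberger) window 40 ms; at 60 Hz, 17 ms and 33 ms.
* HFR1/HFR2 windows span an exact integer number of line cycles
  (``round(fs / f_line)`` samples), which makes full-cycle annihilation of
  the line frequency exact; their outputs are centre-aligned to the window.
* Savitzky-Golay windows are rounded to the nearest odd sample count.
* Moving-window FIR filters use symmetric reflection padding; IIR
  Butterworth filters are applied forward-backward (zero phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .recording import BeatSegmentation, PotentialRecording

HFR_METHODS = ("HFR1", "HFR2", "HFR3", "HFR4", "HFR5", "HFR6", "HFR7")
BDR_METHODS = ("BDR1", "BDR2", "BDR3", "BDR4", "BDR5")

NOTCH_HALF_WIDTH_HZ = 1.0
BDR3_FRAME_MS = 3000.0
WAVELET = "coif2"  # Coiflet, four vanishing moments
WAVELET_LEVELS = 20
WAVELET_BAND_HZ = (0.5, 150.0)
# 11-tap weighted running average: normalized triangular weights
RTF_KERNEL = np.bartlett(13)[1:-1] / np.bartlett(13)[1:-1].sum()


class UnsupportedOperatorError(ValueError):
    """Filter has no time-invariant linear-operator representation."""


@dataclass(frozen=True)
class FilterSpec:
    """One entry of the processing bank.

    ``fid`` is the canonical ID (``RAW``, ``HFR3``, ``HFR2+BDR4``, ``SA``);
    ``category`` one of RAW / HFR / BDR / HFR+BDR / SA.
    """

    fid: str
    category: str
    hfr: str | None = None
    bdr: str | None = None
    params: dict = field(default_factory=dict, compare=False)

    @property
    def is_lti(self) -> bool:
        """Representable as a fixed matrix acting on the time axis.

        BDR1/BDR4 depend on the beat segmentation and SA is nonlinear in
        the alignment step; everything else in the bank is a linear map.
        """
        if self.category == "SA":
            return False
        if self.bdr in ("BDR1", "BDR4"):
            return False
        return True

    @classmethod
    def from_id(cls, fid: str) -> "FilterSpec":
        for spec in enumerate_methods():
            if spec.fid == fid:
                return spec
        raise ValueError(f"unknown method ID {fid!r}")


def enumerate_methods() -> list[FilterSpec]:
    """The full bank in canonical order: RAW, HFR1-7, BDR1-5, the 35
    HFR+BDR combinations (HFR-major), and SA.  49 entries, unique IDs."""
    out = [FilterSpec("RAW", "RAW")]
    out += [FilterSpec(h, "HFR", hfr=h) for h in HFR_METHODS]
    out += [FilterSpec(b, "BDR", bdr=b) for b in BDR_METHODS]
    out += [
        FilterSpec(f"{h}+{b}", "HFR+BDR", hfr=h, bdr=b)
        for h in HFR_METHODS
        for b in BDR_METHODS
    ]
    out.append(FilterSpec("SA", "SA"))
    return out


# ---------------------------------------------------------------------------
# shared low-level pieces


def _cycle_samples(fs_hz: float, line_freq_hz: float) -> int:
    return max(1, int(round(fs_hz / line_freq_hz)))


def _odd_window(fs_hz: float, window_ms: float) -> int:
    """Nearest odd sample count for a window given in ms."""
    n = int(round(window_ms * fs_hz / 1000.0))
    return n if n % 2 == 1 else n + 1


def _fir_smooth(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each lead with ``kernel`` (centre-aligned), symmetric
    reflection padding at the edges."""
    w = len(kernel)
    if w > values.shape[-1]:
        raise ValueError(f"filter frame ({w} samples) longer than record ({values.shape[-1]})")
    left, right = w // 2, w - 1 - w // 2
    padded = np.pad(values, [(0, 0), (left, right)], mode="symmetric")
    if w > 64:
        out = sps.fftconvolve(padded, kernel[None, ::-1], mode="valid", axes=-1)
    else:
        out = np.apply_along_axis(lambda x: np.convolve(x, kernel[::-1], mode="valid"), -1, padded)
    return out


def _sav_gol_smooth(values: np.ndarray, fs_hz: float, window_ms: float, order: int = 3) -> np.ndarray:
    w = _odd_window(fs_hz, window_ms)
    kernel = sps.savgol_coeffs(w, order)[::-1]  # symmetric for deriv=0
    return _fir_smooth(values, kernel)


def _butter_zero_phase(values: np.ndarray, fs_hz: float, cutoff_hz: float, order: int, btype: str) -> np.ndarray:
    sos = sps.butter(order, cutoff_hz, btype=btype, fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, values, axis=-1)


def _require_segmentation(rec: PotentialRecording, method: str) -> BeatSegmentation:
    if rec.segmentation is None or rec.segmentation.n_beats == 0:
        raise ValueError(f"{method} requires a beat segmentation with isoelectric windows")
    return rec.segmentation


# ---------------------------------------------------------------------------
# HFR methods


def _hfr1(rec: PotentialRecording) -> np.ndarray:
    w = _cycle_samples(rec.fs_hz, rec.line_freq_hz)
    return _fir_smooth(rec.values, np.ones(w) / w)


def _hfr2(rec: PotentialRecording) -> np.ndarray:
    # Pipberger: cosine-weighted mean over two line cycles.  The periodic
    # raised-cosine kernel nulls the line frequency exactly when two full
    # cycles fit the window.
    w = 2 * _cycle_samples(rec.fs_hz, rec.line_freq_hz)
    n = np.arange(w)
    kernel = 1.0 - np.cos(2 * np.pi * n / w)
    return _fir_smooth(rec.values, kernel / kernel.sum())


def _hfr3(rec: PotentialRecording) -> np.ndarray:
    n = rec.n_samples
    spec = np.fft.rfft(rec.values, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs_hz)
    nyq = rec.fs_hz / 2
    kill = np.zeros(len(freqs), dtype=bool)
    k = 1
    while k * rec.line_freq_hz <= nyq:
        kill |= np.abs(freqs - k * rec.line_freq_hz) <= NOTCH_HALF_WIDTH_HZ
        k += 1
    spec[:, kill] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _hfr4(rec: PotentialRecording) -> np.ndarray:
    window_ms = 20.0 if rec.line_freq_hz <= 55 else 17.0
    return _sav_gol_smooth(rec.values, rec.fs_hz, window_ms, order=3)


def _hfr5(rec: PotentialRecording) -> np.ndarray:
    return _fir_smooth(rec.values, RTF_KERNEL)


def _hfr6(rec: PotentialRecording) -> np.ndarray:
    return _butter_zero_phase(rec.values, rec.fs_hz, 30.0, order=7, btype="low")


def _hfr7(rec: PotentialRecording) -> np.ndarray:
    return _butter_zero_phase(rec.values, rec.fs_hz, 60.0, order=7, btype="low")


# ---------------------------------------------------------------------------
# BDR methods


def _bdr1(rec: PotentialRecording) -> np.ndarray:
    seg = _require_segmentation(rec, "BDR1")
    out = rec.values.copy()
    for beat, region in enumerate(seg.beat_regions(rec.n_samples)):
        iso = seg.iso_window(beat)
        out[:, region] -= rec.values[:, iso].mean(axis=-1, keepdims=True)
    return out


def _wavelet_keep(fs_hz: float, level: int) -> list[bool]:
    """Which detail levels (1..level, fine to coarse) to retain."""
    lo, hi = WAVELET_BAND_HZ
    keep = []
    for j in range(1, level + 1):
        band_lo, band_hi = fs_hz / 2 ** (j + 1), fs_hz / 2**j
        keep.append(not (band_hi <= lo or band_lo >= hi))
    return keep


def _bdr2(rec: PotentialRecording) -> np.ndarray:
    n = rec.n_samples
    level = min(WAVELET_LEVELS, int(np.floor(np.log2(max(n, 2)))))
    with warnings.catch_warnings():
        # deep decomposition of a finite record: boundary effects accepted
        warnings.filterwarnings("ignore", message="Level value .* is too high")
        coeffs = pywt.wavedec(rec.values, WAVELET, mode="symmetric", level=level, axis=-1)
    coeffs[0] = np.zeros_like(coeffs[0])  # approximation: below the 0.5 Hz edge
    keep = _wavelet_keep(rec.fs_hz, level)
    for j in range(1, level + 1):  # coeffs[1] is the coarsest detail (level L)
        if not keep[level - j]:
            coeffs[j] = np.zeros_like(coeffs[j])
    out = pywt.waverec(coeffs, WAVELET, mode="symmetric", axis=-1)
    return out[:, :n]


def _bdr3(rec: PotentialRecording) -> np.ndarray:
    if _odd_window(rec.fs_hz, BDR3_FRAME_MS) > rec.n_samples:
        raise ValueError("record shorter than the 3000 ms Savitzky-Golay baseline frame")
    baseline = _sav_gol_smooth(rec.values, rec.fs_hz, BDR3_FRAME_MS, order=3)
    return rec.values - baseline


def _bdr4(rec: PotentialRecording) -> np.ndarray:
    from scipy.interpolate import CubicSpline

    seg = _require_segmentation(rec, "BDR4")
    # isoelectric-point values sampled at each window's centre (point values,
    # not window means: a cubic drift is then removed exactly)
    centers = np.array(
        [(s.start + s.stop - 1) // 2 for s in (seg.iso_window(b) for b in range(seg.n_beats))]
    )
    iso_means = rec.values[:, centers]  # (leads, beats)
    t = np.arange(rec.n_samples, dtype=float)
    if len(centers) >= 4:
        spline = CubicSpline(centers, iso_means, axis=-1, bc_type="not-a-knot", extrapolate=True)
        baseline = spline(t)
    else:  # too few knots for a spline: single cubic (or lower-order) fit
        deg = min(3, len(centers) - 1)
        coef = np.polynomial.polynomial.polyfit(centers, iso_means.T, deg)
        baseline = np.polynomial.polynomial.polyval(t, coef)
    return rec.values - baseline


def _bdr5(rec: PotentialRecording) -> np.ndarray:
    return _butter_zero_phase(rec.values, rec.fs_hz, 0.5, order=5, btype="high")


_HFR_FUNCS = {"HFR1": _hfr1, "HFR2": _hfr2, "HFR3": _hfr3, "HFR4": _hfr4,
              "HFR5": _hfr5, "HFR6": _hfr6, "HFR7": _hfr7}
_BDR_FUNCS = {"BDR1": _bdr1, "BDR2": _bdr2, "BDR3": _bdr3, "BDR4": _bdr4, "BDR5": _bdr5}


def apply_hfr(rec: PotentialRecording, method: str) -> PotentialRecording:
    """Apply one high-frequency removal method (HFR1..HFR7)."""
    if method not in _HFR_FUNCS:
        raise ValueError(f"unknown HFR method {method!r}")
    return rec.with_values(_HFR_FUNCS[method](rec))


def apply_bdr(rec: PotentialRecording, method: str) -> PotentialRecording:
    """Apply one baseline-drift removal method (BDR1..BDR5)."""
    if method not in _BDR_FUNCS:
        raise ValueError(f"unknown BDR method {method!r}")
    return rec.with_values(_BDR_FUNCS[method](rec))


def apply_combined(rec: PotentialRecording, hfr: str, bdr: str) -> PotentialRecording:
    """HFR on the raw signal first, then BDR on the result."""
    return apply_bdr(apply_hfr(rec, hfr), bdr)


def apply_filter(rec: PotentialRecording, spec: FilterSpec | str) -> PotentialRecording:
    """Apply any bank entry by spec or ID (RAW returns a copy)."""
    if isinstance(spec, str):
        spec = FilterSpec.from_id(spec)
    if spec.category == "RAW":
        return rec.copy()
    if spec.category == "HFR":
        return apply_hfr(rec, spec.hfr)
    if spec.category == "BDR":
        return apply_bdr(rec, spec.bdr)
    if spec.category == "HFR+BDR":
        return apply_combined(rec, spec.hfr, spec.bdr)
    if spec.category == "SA":
        return signal_average(rec)
    raise ValueError(f"unknown category {spec.category!r}")


# ---------------------------------------------------------------------------
# signal averaging


def signal_average(
    rec: PotentialRecording,
    qrst_window: slice | None = None,
    return_info: bool = False,
):
    """PCA-based beat averaging; returns a single-beat recording.

    Baseline wander is first removed with the wavelet method (BDR2).  The
    first principal component across leads is the virtual lead; its QRST
    window is the virtual template.  Each beat is aligned to the template
    at the lag of maximum cross-correlation and the per-lead mean over
    aligned beats is returned.  Beats whose alignment shift exceeds half a
    cycle length are dropped and logged.
    """
    seg = _require_segmentation(rec, "signal averaging")
    if seg.n_beats < 2:
        raise ValueError("signal averaging needs at least 2 beats")
    work = apply_bdr(rec, "BDR2")
    x = work.values - work.values.mean(axis=-1, keepdims=True)
    # first PC across leads as the virtual lead
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    virtual = vt[0]
    if virtual[np.argmax(np.abs(virtual))] < 0:
        virtual = -virtual

    if qrst_window is None:
        end = seg.qrst_offset[0] if seg.qrst_offset is not None else seg.qrs_offset[0]
        qrst_window = slice(int(seg.qrs_onset[0]), int(end))
    template = virtual[qrst_window]
    pre = int(seg.qrs_onset[0] - (seg.iso_start[0] - seg.iso_len))  # pre-QRS context kept
    cycle = int(np.median(np.diff(seg.qrs_onset))) if seg.n_beats > 1 else rec.n_samples

    xc = sps.correlate(virtual, template, mode="valid")  # xc[p] = match at start p
    out_len = (qrst_window.stop - qrst_window.start) + pre
    acc = np.zeros((rec.n_leads, out_len))
    shifts, used = [], 0
    for k in range(seg.n_beats):
        expected = int(seg.qrs_onset[k])
        lo = max(0, expected - cycle // 2 + 1)
        hi = min(len(xc), expected + cycle // 2)
        if lo >= hi:
            warnings.warn(f"beat {k}: no alignment search range; dropped")
            continue
        p = lo + int(np.argmax(xc[lo:hi]))
        shift = p - expected
        if abs(shift) > cycle / 2:
            warnings.warn(f"beat {k}: alignment shift {shift} exceeds half a cycle; dropped")
            continue
        start = p - pre
        if start < 0 or start + out_len > rec.n_samples:
            warnings.warn(f"beat {k}: aligned window leaves the record; dropped")
            continue
        acc += work.values[:, start : start + out_len]
        shifts.append(shift)
        used += 1
    if used == 0:
        raise ValueError("signal averaging: no beat could be aligned")
    avg = acc / used
    qrs_len = int(seg.qrs_offset[0] - seg.qrs_onset[0])
    new_seg = BeatSegmentation(
        np.array([pre]),
        np.array([pre + qrs_len]),
        np.array([max(0, pre - int(seg.iso_len) - int(round(0.002 * rec.fs_hz)))]),
        int(seg.iso_len),
        np.array([out_len]),
    )
    out = PotentialRecording(
        avg, rec.fs_hz, list(rec.lead_ids), rec.bad_leads.copy(), new_seg, rec.line_freq_hz
    )
    if return_info:
        return out, {"n_beats_averaged": used, "shifts": shifts}
    return out


# ---------------------------------------------------------------------------
# linear-operator view


def as_operator(
    spec: FilterSpec | str,
    n_samples: int,
    fs_hz: float,
    line_freq_hz: float = 50.0,
) -> np.ndarray:
    """Matrix ``M`` with ``M @ s == filter(s)`` for every lead.

    Only defined for the linear members of the bank (all HFR; BDR2/3/5 and
    their combinations); BDR1/BDR4 depend on the segmentation and SA on
    data-driven alignment, so they raise ``UnsupportedOperatorError``.
    """
    if isinstance(spec, str):
        spec = FilterSpec.from_id(spec)
    if not spec.is_lti:
        raise UnsupportedOperatorError(
            f"{spec.fid} has no linear time-operator representation"
        )
    eye = PotentialRecording(np.eye(n_samples), fs_hz, line_freq_hz=line_freq_hz)
    resp = apply_filter(eye, spec)
    return resp.values.T.copy()
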