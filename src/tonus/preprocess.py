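"""sEMG preprocessing: band-pass/notch filtering, EMD-based interference
removal and MVC normalization.

The pipeline order is filter -> EMD -> normalize.  All filtering is
zero-phase (forward-backward), appropriate for an offline pipeline.

EMD here is the classical sifting algorithm: a candidate mode is repeatedly
refined by subtracting the mean of its cubic-spline upper and lower extrema
envelopes until the normalized squared change between sifts falls below a
threshold (Cauchy-type criterion, default 0.2).  Interference removal keeps
only the intrinsic mode functions (IMFs) whose power-weighted mean frequency
lies inside the EMG band and always discards the residual trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import signal as sps
from scipy.interpolate import CubicSpline


class FilterSpec(BaseModel):
    """Band-pass + notch filter configuration.

    Defaults follow common sEMG practice: 4th-order Butterworth 20--500 Hz
    band-pass and a 60 Hz notch of quality 30.
    """

    band_low: float = 20.0
    band_high: float = 500.0
    notch_freq: float = 60.0
    butter_order: int = 4
    notch_quality: float = 30.0

    @model_validator(mode="after")
    def _check(self) -> "FilterSpec":
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if not self.band_low <= self.notch_freq <= self.band_high:
            raise ValueError("notch frequency must lie inside the pass band")
        return self


@dataclass(frozen=True)
class MvcReference:
    """Per-muscle MVC normalization denominators (signal units)."""

    biceps: float
    triceps: float

    def __post_init__(self) -> None:
        for name in ("biceps", "triceps"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"MVC reference for {name} must be positive")

    def for_muscle(self, muscle: str) -> float:
        return getattr(self, muscle)


def bandpass_notch(
    signal: np.ndarray, sampling_rate: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase Butterworth band-pass plus notch filtering of one channel."""
    spec = spec or FilterSpec()
    nyq = sampling_rate / 2.0
    high = spec.band_high
    if spec.band_low >= nyq:
        raise ValueError("band_low must be below the Nyquist frequency")
    if high >= nyq:  # 500 Hz upper edge at fs=2000 hugs Nyquist/2; stay feasible
        high = 0.999 * nyq
    sos = sps.butter(
        spec.butter_order,
        (spec.band_low, high),
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    out = sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))
    b, a = sps.iirnotch(spec.notch_freq, spec.notch_quality, fs=sampling_rate)
    return sps.filtfilt(b, a, out)


# ---------------------------------------------------------------------------
# empirical mode decomposition
# ---------------------------------------------------------------------------

def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (interior samples)."""
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    maxima = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    minima = np.flatnonzero(falling[:-1] & rising[1:]) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored end conditions."""
    # mirror the two outermost extrema about the signal ends so the spline
    # does not swing wildly at the boundaries
    t = idx.astype(float)
    v = x[idx]
    t_ext = np.concatenate(([-t[1], -t[0]], t, [2 * (n - 1) - t[-1], 2 * (n - 1) - t[-2]]))
    v_ext = np.concatenate(([v[1], v[0]], v, [v[-1], v[-2]]))
    # mirroring can produce duplicate abscissae for extrema at the ends
    t_ext, keep = np.unique(t_ext, return_index=True)
    return CubicSpline(t_ext, v_ext[keep])(np.arange(n))


def _sift(x: np.ndarray, sd_threshold: float, max_siftings: int) -> np.ndarray | None:
    """Extract one IMF from ``x``; None when too few extrema remain."""
    n = x.size
    h = x
    for _ in range(max_siftings):
        maxima, minima = _extrema_indices(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        upper = _envelope(h, maxima, n)
        lower = _envelope(h, minima, n)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = np.sum(h**2)
        if denom > 0 and np.sum(mean**2) / denom < sd_threshold:
            return h_new
        h = h_new
    return h


def emd(
    signal: np.ndarray,
    max_imfs: int = 10,
    sd_threshold: float = 0.2,
    max_siftings: int = 12,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``signal`` into IMFs plus a residual trend.

    Returns ``(imfs, residual)`` with ``sum(imfs) + residual == signal`` to
    floating-point accuracy.  A signal without enough extrema (e.g. constant)
    yields zero IMFs and the signal itself as residual.
    """
    x = np.asarray(signal, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        imf = _sift(residual, sd_threshold, max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
        maxima, minima = _extrema_indices(residual)
        if maxima.size + minima.size < 4:
            break
    return imfs, residual


def mean_frequency(x: np.ndarray, sampling_rate: float) -> float:
    """Power-weighted mean frequency of a signal (Hz); 0 for a null signal."""
    freqs, power = sps.periodogram(x, fs=sampling_rate, scaling="spectrum")
    total = power.sum()
    if total <= 0:
        return 0.0
    return float(np.sum(freqs * power) / total)


def emd_denoise(
    signal: np.ndarray,
    sampling_rate: float,
    keep_band: tuple[float, float] = (20.0, 500.0),
    max_imfs: int = 10,
) -> np.ndarray:
    """Reconstruct a signal from the IMFs whose mean frequency is in-band.

    The residual trend is always discarded.  Decomposition stops early once
    an extracted IMF falls below the band's lower edge, since sifting
    produces modes of (roughly) monotonically decreasing frequency; anything
    later is interference by construction.  A signal that yields no IMFs
    (constant input) returns zeros with a warning.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return x.copy()
    out = np.zeros_like(x)
    residual = x.copy()
    got_any = False
    for _ in range(max_imfs):
        imf = _sift(residual, sd_threshold=0.2, max_siftings=12)
        if imf is None:
            break
        got_any = True
        residual = residual - imf
        mnf = mean_frequency(imf, sampling_rate)
        if mnf < keep_band[0]:
            break  # this and all later modes are below-band interference
        if mnf <= keep_band[1]:
            out += imf
    if not got_any:
        warnings.warn(
            "EMD produced no intrinsic mode functions; returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# MVC normalization
# ---------------------------------------------------------------------------

def moving_rms(x: np.ndarray, sampling_rate: float, window_s: float = 0.1) -> np.ndarray:
    """RMS over a sliding rectangular window (default 100 ms)."""
    w = max(int(round(window_s * sampling_rate)), 1)
    if x.size < w:
        w = x.size
    kernel = np.ones(w) / w
    ms = np.convolve(np.asarray(x, dtype=float) ** 2, kernel, mode="valid")
    return np.sqrt(np.maximum(ms, 0.0))


def compute_mvc_reference(
    mvc_trials: list[np.ndarray], sampling_rate: float, window_s: float = 0.1
) -> float:
    """Normalization denominator for one muscle: the maximum over trials of
    the peak 100 ms moving-window RMS.  Trials must already be filtered with
    the same :class:`FilterSpec` as the signals they will normalize."""
    if not mvc_trials:
        raise ValueError("at least one MVC trial is required")
    peaks = [float(moving_rms(t, sampling_rate, window_s).max()) for t in mvc_trials]
    ref = max(peaks)
    if ref <= 0:
        raise ValueError("all MVC trials are zero; normalization undefined")
    return ref


def mvc_normalize(signal: np.ndarray, reference: float) -> np.ndarray:
    """Scale a signal to the %MVC scale (unitless): signal / reference."""
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError("MVC reference must be positive and finite")
    return np.asarray(signal, dtype=float) / reference


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

def preprocess_movement(
    emg: np.ndarray,
    mvc: dict[str, list[np.ndarray]],
    sampling_rate: float,
    spec: FilterSpec | None = None,
    *,
    apply_emd: bool = True,
) -> tuple[np.ndarray, MvcReference]:
    """Filter -> EMD-denoise -> MVC-normalize a 2-channel movement recording.

    ``emg`` has channel order (biceps, triceps).  MVC trials are filtered
    with the same spec (no EMD) before the peak moving-RMS reference is
    taken.  Returns the normalized movement channels and the reference used.
    """
    spec = spec or FilterSpec()
    refs = {}
    for muscle in ("biceps", "triceps"):
        filtered = [bandpass_notch(t, sampling_rate, spec) for t in mvc[muscle]]
        refs[muscle] = compute_mvc_reference(filtered, sampling_rate)
    reference = MvcReference(**refs)
    out = np.empty_like(emg, dtype=float)
    for j, muscle in enumerate(("biceps", "triceps")):
        x = bandpass_notch(emg[:, j], sampling_rate, spec)
        if apply_emd:
            x = emd_denoise(x, sampling_rate, (spec.band_low, spec.band_high))
        out[:, j] = mvc_normalize(x, reference.for_muscle(muscle))
    return out, reference
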