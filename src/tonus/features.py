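"""The eleven per-window sEMG descriptors and the labeled feature table.

Time domain (8): mean absolute value (MAV), modified MAV (MMAV, mean of
per-sub-window MAVs over M equal contiguous sub-windows), standard deviation
(STD, population 1/N divisor), waveform length (WL), zero crossings (ZC),
slope-sign changes (SSC, with a 1/N prefactor), root mean square (RMS) and
the log detector LD = log((1/N) * sum(x^2) + 1) (natural log).

Frequency domain (3), computed on the one-sided periodogram restricted to
the analysis band (default 20--500 Hz): total in-band power (PSD), the
power-weighted mean frequency (MNF) and the median frequency (MDF, linear
interpolation of the cumulative power).

Conventions fixed here: sgn(0) counts as positive for ZC; ZC uses no
amplitude threshold; MMAV defaults to M = 4 sub-windows (M = 1 recovers
MAV).  The periodogram is in mean-square (power) units so that an
amplitude-A tone carries total one-sided power A^2/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .segment import SignalWindow
from .synth import MUSCLES

#: Fixed feature order used in every table and report.
FEATURE_NAMES = (
    "mav", "mmav", "std", "wl", "zc", "ssc", "rms", "ld", "psd", "mnf", "mdf",
)

#: features.csv column order: 11 biceps, 11 triceps, label.
TABLE_COLUMNS = tuple(
    f"{muscle}_{feat}" for muscle in MUSCLES for feat in FEATURE_NAMES
) + ("label",)

DEFAULT_BAND = (20.0, 500.0)


@dataclass(frozen=True)
class Spectrum:
    """One-sided periodogram: frequency grid (Hz) and power per bin."""

    frequencies: np.ndarray
    power: np.ndarray


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def mav(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def mmav(x: np.ndarray, m: int = 4) -> float:
    """Mean of the per-sub-window MAVs over ``m`` equal contiguous segments."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    if m < 1:
        raise ValueError("m must be >= 1")
    parts = np.array_split(x, min(m, x.size))
    return float(np.mean([np.mean(np.abs(p)) for p in parts]))


def std(x: np.ndarray) -> float:
    """Population standard deviation (1/N divisor)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.std(x))


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x**2)))


def log_detector(x: np.ndarray) -> float:
    """LD = log((1/N) * sum(x_i^2) + 1); zero for a null signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.log(np.mean(x**2) + 1.0))


def waveform_length(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def _sgn(x: np.ndarray) -> np.ndarray:
    """Sign with sgn(0) = +1."""
    return np.where(np.asarray(x, dtype=float) >= 0, 1, -1)


def zero_crossings(x: np.ndarray) -> int:
    """Count of strict sign changes between consecutive samples."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("zero crossings need at least 2 samples")
    s = _sgn(x)
    return int(np.sum(s[:-1] != s[1:]))


def slope_sign_changes(x: np.ndarray) -> float:
    """Count of slope-sign changes scaled by 1/N."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("slope sign changes need at least 3 samples")
    d = np.diff(x)
    return float(np.sum(d[:-1] * d[1:] < 0) / x.size)


def amplitude_features(x: np.ndarray, m: int = 4) -> tuple[float, float, float, float, float]:
    """(MAV, MMAV, STD, RMS, LD) of one window."""
    return mav(x), mmav(x, m), std(x), rms(x), log_detector(x)


def complexity_features(x: np.ndarray) -> tuple[float, int, float]:
    """(WL, ZC, SSC) of one window."""
    return waveform_length(x), zero_crossings(x), slope_sign_changes(x)


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def periodogram(x: np.ndarray, sampling_rate: float) -> Spectrum:
    """One-sided periodogram in power (mean-square) units.

    Parseval: the powers sum to the signal's mean square, so an on-grid tone
    of amplitude A carries total power A^2/2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("periodogram needs at least 2 samples")
    freqs, power = sps.periodogram(
        x, fs=sampling_rate, window="boxcar", detrend=False, scaling="spectrum"
    )
    return Spectrum(frequencies=freqs, power=power)


def spectral_features(
    spectrum: Spectrum, band: tuple[float, float] = DEFAULT_BAND
) -> tuple[float, float, float]:
    """(total in-band power, MNF, MDF) of a spectrum restricted to ``band``.

    MNF is the power-weighted mean frequency.  MDF is the smallest frequency
    at which the cumulative in-band power reaches half the total, with
    linear interpolation between bins.
    """
    f, p = spectrum.frequencies, spectrum.power
    mask = (f >= band[0]) & (f <= band[1])
    f, p = f[mask], p[mask]
    if f.size < 2:
        raise ValueError("fewer than 2 spectral bins in band")
    total = float(p.sum())
    if total <= 0:
        raise ValueError("zero in-band power; MNF/MDF undefined")
    mnf = float(np.sum(f * p) / total)
    cum = np.cumsum(p)
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        mdf = float(f[0])
    else:
        prev = cum[k - 1]
        frac = (half - prev) / (cum[k] - prev) if cum[k] > prev else 0.0
        mdf = float(f[k - 1] + frac * (f[k] - f[k - 1]))
    return total, mnf, mdf


# ---------------------------------------------------------------------------
# feature vectors and the labeled table
# ---------------------------------------------------------------------------

def feature_vector(
    window: SignalWindow,
    sampling_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    mmav_subwindows: int = 4,
) -> dict[str, float]:
    """All eleven descriptors of one window, keyed by FEATURE_NAMES."""
    x = window.samples
    mav_, mmav_, std_, rms_, ld_ = amplitude_features(x, mmav_subwindows)
    wl_, zc_, ssc_ = complexity_features(x)
    psd_, mnf_, mdf_ = spectral_features(periodogram(x, sampling_rate), band)
    return {
        "mav": mav_, "mmav": mmav_, "std": std_, "wl": wl_, "zc": float(zc_),
        "ssc": ssc_, "rms": rms_, "ld": ld_, "psd": psd_, "mnf": mnf_, "mdf": mdf_,
    }


def build_feature_table(
    windows: list[SignalWindow],
    sampling_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    mmav_subwindows: int = 4,
) -> pd.DataFrame:
    """Labeled table: one row per repetition, 11 biceps + 11 triceps features.

    Every repetition must be present for both muscles; a repetition missing
    one muscle raises an error naming it.
    """
    by_key: dict[tuple[str, int], dict[str, SignalWindow]] = {}
    for w in windows:
        by_key.setdefault((w.subject_id, w.repetition_index), {})[w.muscle] = w
    rows = []
    index: list[str] = []
    for (subject, rep) in sorted(by_key):
        pair = by_key[(subject, rep)]
        if set(pair) != set(MUSCLES):
            missing = set(MUSCLES) - set(pair)
            raise ValueError(
                f"repetition {rep} of subject {subject} missing muscle(s): "
                f"{sorted(missing)}"
            )
        row: dict[str, object] = {}
        for muscle in MUSCLES:
            feats = feature_vector(pair[muscle], sampling_rate, band, mmav_subwindows)
            for name in FEATURE_NAMES:
                row[f"{muscle}_{name}"] = feats[name]
        row["label"] = pair[MUSCLES[0]].tone_class.value
        rows.append(row)
        index.append(subject)
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    df.index = pd.Index(index, name="subject_id")
    return df


def write_feature_table(df: pd.DataFrame, path, include_subjects: bool = True) -> None:
    """Write features.csv with the fixed 23-column order; subject ids go to
    the leading index column (needed for subject-level splits) unless
    ``include_subjects`` is false."""
    df.to_csv(path, index=include_subjects)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df[list(TABLE_COLUMNS)]
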