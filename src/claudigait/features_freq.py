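"""Frequency-domain gait features: 85 values per 10 s window.

All spectral features are computed from the window's Earth-frame acceleration
magnitude ``||a||``: Welch PSD summaries (max, mean, min), normalized spectral
entropy, spectral energy, and 40 FFT plus 40 DCT coefficients covering
0.1-4.0 Hz at 0.1 Hz resolution — the band containing human walking
kinematics.  The window mean is removed before every transform so the
excluded-DC convention is exact.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import welch

N_COEFFS = 40


def psd_welch(
    mag: np.ndarray,
    fs: float,
    nperseg: int = 128,
    noverlap: int | None = None,
) -> tuple:
    """(max, mean, min) of the Welch power spectral density of ``||a||``.

    Hann window, 128-sample segments, 50% overlap.  Windows shorter than one
    segment fall back to a single periodogram with a warning.
    """
    x = np.asarray(mag, dtype=float)
    if len(x) < nperseg:
        warnings.warn("window shorter than one Welch segment; using a single periodogram")
        nperseg = len(x)
    if noverlap is None:
        noverlap = nperseg // 2
    _, p = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    return float(np.max(p)), float(np.mean(p)), float(np.min(p))


def spectral_entropy(mag: np.ndarray) -> float:
    """Normalized entropy of FFT coefficient magnitudes (DC excluded), in [0, 1].

    The positive-frequency magnitudes are normalized to a distribution
    p_i = |X_i| / sum |X_j|; H = -sum p_i ln p_i / ln M.  NaN on a constant
    series (all non-DC bins zero).
    """
    x = np.asarray(mag, dtype=float)
    spec = np.abs(rfft(x - x.mean()))[1:]
    total = spec.sum()
    if total <= 0 or len(spec) < 2:
        return float("nan")
    p = spec / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(len(p)))


def spectral_energy(mag: np.ndarray) -> float:
    """Sum of squared two-sided FFT coefficients over the window length.

    By Parseval this equals the sum of squared (mean-removed) samples.
    """
    x = np.asarray(mag, dtype=float)
    x = x - x.mean()
    X = np.fft.fft(x)
    return float(np.sum(np.abs(X) ** 2) / len(x))


def _check_window_length(x: np.ndarray, fs: float) -> None:
    expected = int(round(10.0 * fs))
    if len(x) != expected:
        raise ValueError(
            f"coefficient features need a 10 s window ({expected} samples at "
            f"{fs} Hz) for exact 0.1 Hz bin spacing; got {len(x)} samples"
        )


def fft_coefficients(mag: np.ndarray, fs: float = 50.0) -> np.ndarray:
    """Magnitudes of FFT bins 1..40, i.e. 0.1-4.0 Hz at 0.1 Hz resolution.

    Requires the canonical 10 s window so the bin spacing is exactly 0.1 Hz;
    magnitudes are scaled by 2/N (a unit sinusoid on an exact bin gives 1.0).
    """
    x = np.asarray(mag, dtype=float)
    _check_window_length(x, fs)
    spec = np.abs(rfft(x - x.mean()))
    return 2.0 / len(x) * spec[1:N_COEFFS + 1]


def dct_coefficients(mag: np.ndarray, fs: float = 50.0) -> np.ndarray:
    """Orthonormal type-II DCT coefficients on the 0.1 Hz grid up to 4.0 Hz.

    DCT bin k maps to frequency k*fs/(2N) = 0.05*k Hz for a 10 s window at
    50 Hz, so bins 2, 4, ..., 80 land exactly on 0.1-4.0 Hz.
    """
    x = np.asarray(mag, dtype=float)
    _check_window_length(x, fs)
    coeffs = dct(x - x.mean(), type=2, norm="ortho")
    return coeffs[2:2 * N_COEFFS + 1:2]


def freq_feature_names() -> list:
    return (["psd_max", "psd_mean", "psd_min", "entropy", "spectral_energy"]
            + [f"fft_{k:02d}" for k in range(1, N_COEFFS + 1)]
            + [f"dct_{k:02d}" for k in range(1, N_COEFFS + 1)])


def extract_freq_features(mag: np.ndarray, fs: float) -> dict:
    """The full ordered 85-entry frequency-domain block for one window."""
    out = {}
    out["psd_max"], out["psd_mean"], out["psd_min"] = psd_welch(mag, fs)
    out["entropy"] = spectral_entropy(mag)
    out["spectral_energy"] = spectral_energy(mag)
    for k, v in enumerate(fft_coefficients(mag, fs), start=1):
        out[f"fft_{k:02d}"] = float(v)
    for k, v in enumerate(dct_coefficients(mag, fs), start=1):
        out[f"dct_{k:02d}"] = float(v)
    assert list(out.keys()) == freq_feature_names()
    return out
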