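"""PCA-derived column signal and median-STFT power spectral density.

Raw (unfiltered) multichannel activity is reduced to a single "column
signal" — the first principal component score across channels — and its
power spectral density is estimated as the per-frequency *median* over
short-time Fourier transform windows (2 s Hamming windows, 0.5 s overlap).
The median is robust to transient windows and preserves the ~1 Hz slow-wave
peak used as the anesthetized-state marker.  Curves are interpolated onto a
log-spaced frequency axis (0.5 Hz - 3 kHz), smoothed with a 10-point moving
average, and expressed in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["PSDCurve", "column_signal", "median_stft_psd", "log_interp_smooth",
           "band_power_db", "peak_frequency"]


@dataclass
class PSDCurve:
    frequencies: np.ndarray  # Hz, log-spaced, strictly increasing
    power_db: np.ndarray     # dB re 1 uV^2/Hz
    epoch: str | None = None
    idc_amplitude_ua: float | None = None


def column_signal(segment: np.ndarray) -> np.ndarray:
    """First-principal-component score time series of a channels x time array.

    Channels are mean-centered over time; the PC1 loading sign is fixed so
    the sum of channel loadings is positive (an in-phase column signal).
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (channels >= 2, samples >= 2) array")
    xc = x - x.mean(axis=1, keepdims=True)
    if not np.any(xc):
        raise ValueError("zero-variance input")
    # PC1 of the channel covariance via SVD of the centered data
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    w = u[:, 0]
    if w.sum() < 0:
        w = -w
    return w @ xc


def median_stft_psd(trace: np.ndarray, fs: float, window_s: float = 2.0,
                    overlap_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency median of |STFT|^2 over time (Hamming taper).

    ``overlap_s`` is the overlap between consecutive windows (hop =
    window_s - overlap_s).  Returns ``(frequencies_hz, power)`` in power
    spectral density units of the input (uV^2/Hz for uV input).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_s * fs))
    if trace.shape[-1] < nperseg:
        raise ValueError("trace shorter than one STFT window")
    f, _, sxx = signal.spectrogram(trace, fs=fs, window="hamming",
                                   nperseg=nperseg, noverlap=noverlap,
                                   detrend=False, scaling="density",
                                   mode="psd")
    return f, np.median(sxx, axis=-1)


def log_interp_smooth(frequencies: np.ndarray, power: np.ndarray,
                      f_min: float = 0.5, f_max: float = 3000.0,
                      n_points: int = 300, ma_window: int = 10,
                      epoch: str | None = None,
                      idc_amplitude_ua: float | None = None) -> PSDCurve:
    """Interpolate a raw PSD onto a log frequency axis, smooth, convert to dB.

    Linear interpolation is performed in log-frequency; the moving average is
    a centered ``ma_window``-point boxcar (shrinking symmetrically at the
    edges).  Nonpositive power is floored at machine epsilon before the dB
    conversion.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    pos = f > 0
    f, p = f[pos], p[pos]
    if f.size == 0 or f.min() > f_min or f.max() < f_max:
        raise ValueError(f"raw PSD does not cover [{f_min}, {f_max}] Hz")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    f_log = np.logspace(np.log10(f_min), np.log10(f_max), n_points)
    p_i = np.interp(np.log10(f_log), np.log10(f), p)
    if ma_window > 1 and n_points > 1:
        half_lo = (ma_window - 1) // 2
        half_hi = ma_window // 2
        sm = np.empty_like(p_i)
        for i in range(p_i.size):
            a = max(0, i - half_lo)
            b = min(p_i.size, i + half_hi + 1)
            sm[i] = p_i[a:b].mean()
        p_i = sm
    p_i = np.maximum(p_i, np.finfo(float).eps)
    return PSDCurve(frequencies=f_log, power_db=10.0 * np.log10(p_i),
                    epoch=epoch, idc_amplitude_ua=idc_amplitude_ua)


def band_power_db(curve: PSDCurve, band_hz: tuple[float, float]) -> float:
    """Mean dB power of a curve within a frequency band."""
    lo, hi = band_hz
    mask = (curve.frequencies >= lo) & (curve.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} outside curve frequencies")
    return float(curve.power_db[mask].mean())


def peak_frequency(curve: PSDCurve, band_hz: tuple[float, float]) -> float:
    """Frequency of maximum power within a band (slow-wave peak locator)."""
    lo, hi = band_hz
    mask = (curve.frequencies >= lo) & (curve.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band_hz} outside curve frequencies")
    idx = np.argmax(curve.power_db[mask])
    return float(curve.frequencies[mask][idx])
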