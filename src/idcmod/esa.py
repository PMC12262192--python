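"""Entire Spiking Activity (ESA) analysis of multi-unit recordings.

ESA avoids threshold-based spike detection: the 300-5000 Hz band-passed MUA
is full-wave rectified and smoothed bidirectionally with a Gaussian kernel
(sigma = 1 ms, length 6 sigma), yielding a continuous, nonnegative envelope
of population spiking.  Envelopes are binned over time, summarized per epoch
as percent change versus the pre-iDC baseline, and aggregated by cortical
layer across animals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording
from .rods import LAYER_BANDS

__all__ = [
    "bandpass_mua",
    "gaussian_kernel",
    "esa_transform",
    "bin_esa",
    "percent_change",
    "epoch_mean",
    "assign_layer",
    "layer_summary",
]


def bandpass_mua(rec: Recording, low: float = 300.0, high: float = 5000.0,
                 order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel (forward-backward)."""
    if not (0 < low < high < rec.sampling_rate / 2):
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={rec.sampling_rate}")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return Recording(samples=filtered.astype(rec.samples.dtype, copy=False),
                     sampling_rate=rec.sampling_rate,
                     channel_depths_mm=rec.channel_depths_mm,
                     epochs=rec.epochs, onsets_s=rec.onsets_s,
                     intensity_ma=rec.intensity_ma,
                     idc_amplitude_ua=rec.idc_amplitude_ua)


def gaussian_kernel(fs: float, sigma_ms: float = 1.0,
                    kernel_len_sigmas: float = 6.0) -> np.ndarray:
    """Discrete unit-sum Gaussian, truncated at +-(len/2) sigmas."""
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    sigma = sigma_ms * 1e-3 * fs  # samples
    half = max(int(round(kernel_len_sigmas / 2 * sigma)), 1)
    t = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(t**2) / (2 * sigma**2))
    return k / k.sum()


def _smooth_bidirectional(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Forward then backward convolution with reflect padding (zero phase)."""
    pad = k.size - 1
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    fwd = signal.oaconvolve(xp, k[(np.newaxis,) * (x.ndim - 1)], mode="same", axes=-1)
    bwd = signal.oaconvolve(fwd[..., ::-1], k[(np.newaxis,) * (x.ndim - 1)],
                            mode="same", axes=-1)[..., ::-1]
    return bwd[..., pad:pad + x.shape[-1]]


def esa_transform(mua, fs: float, sigma_ms: float = 1.0,
                  kernel_len_sigmas: float = 6.0) -> np.ndarray:
    """Full-wave rectify and bidirectionally Gaussian-smooth MUA.

    Works on 1-D traces or (channels, time) arrays along the last axis;
    output is nonnegative with the input's shape.
    """
    mua = np.asarray(mua)
    if not np.issubdtype(mua.dtype, np.floating):
        mua = mua.astype(float)
    if mua.size == 0:
        raise ValueError("empty input")
    k = gaussian_kernel(fs, sigma_ms, kernel_len_sigmas).astype(mua.dtype)
    out = _smooth_bidirectional(np.abs(mua), k)
    return np.maximum(out, 0.0)


def bin_esa(trace: np.ndarray, fs: float, bin_ms: float,
            window_s: tuple[float, float]) -> np.ndarray:
    """Mean of ESA samples in non-overlapping bins tiling ``window_s``.

    A trailing partial bin is dropped.  Works along the last axis.
    """
    trace = np.asarray(trace, dtype=float)
    t0, t1 = window_s
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > trace.shape[-1] or i1 <= i0:
        raise ValueError(f"window {window_s} s outside trace")
    bin_samp = bin_ms * 1e-3 * fs
    n_bins = int(np.floor((t1 - t0) * 1000.0 / bin_ms))
    if n_bins < 1:
        raise ValueError("bin does not fit in window")
    edges = i0 + np.round(bin_samp * np.arange(n_bins + 1)).astype(int)
    counts = np.diff(edges)
    sums = np.add.reduceat(trace, edges[:-1], axis=-1)
    # reduceat's final slice runs to the array end; restrict it to edges[-1]
    sums[..., -1] = trace[..., edges[-2]:edges[-1]].sum(axis=-1)
    return sums / counts


def epoch_mean(trace: np.ndarray, fs: float,
               window_s: tuple[float, float]) -> np.ndarray:
    """Mean of a trace over a time window (last axis)."""
    t0, t1 = window_s
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > np.asarray(trace).shape[-1] or i1 <= i0:
        raise ValueError(f"window {window_s} s outside trace")
    return np.asarray(trace)[..., i0:i1].mean(axis=-1)


def percent_change(during_mean, pre_mean):
    """Relative percent change, 100 * (during - pre) / pre.  pre must be > 0."""
    pre = np.asarray(pre_mean, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("degenerate baseline: pre_mean must be positive")
    out = 100.0 * (np.asarray(during_mean, dtype=float) - pre) / pre
    return float(out) if out.ndim == 0 else out


def assign_layer(depth_mm: float, bands: dict[str, tuple[float, float]] = LAYER_BANDS) -> str | None:
    """Layer label of a contact depth, or None outside all bands."""
    for name, (lo, hi) in bands.items():
        if lo <= depth_mm < hi:
            return name
    return None


def layer_summary(changes: pd.DataFrame,
                  bands: dict[str, tuple[float, float]] = LAYER_BANDS,
                  layers: tuple[str, ...] = ("L2/3", "L4", "L5", "L6")) -> pd.DataFrame:
    """Per-layer mean +- SEM of percent change across animals.

    ``changes`` needs columns animal, depth_mm, amplitude_ua, percent_change.
    The layer value of one animal is the mean over that layer's channels;
    mean and SEM are then taken across animals.  With a single animal the
    SEM is reported as 0 with ``n_animals`` flagging the degenerate case;
    empty layers are omitted.
    """
    df = changes.copy()
    df["layer"] = [assign_layer(d, bands) for d in df["depth_mm"]]
    df = df[df["layer"].isin(layers)]
    per_animal = (df.groupby(["layer", "amplitude_ua", "animal"], observed=True)
                  ["percent_change"].mean().reset_index())
    rows = []
    for (layer, amp), grp in per_animal.groupby(["layer", "amplitude_ua"], observed=True):
        vals = grp["percent_change"].to_numpy()
        n = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else 0.0
        rows.append((layer, amp, float(vals.mean()), sem, n))
    out = pd.DataFrame(rows, columns=["layer", "amplitude_ua", "mean",
                                      "sem", "n_animals"])
    return out.sort_values(["layer", "amplitude_ua"]).reset_index(drop=True)
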