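"""Trial-averaged evoked-response heatmaps and MSE gain-shift analysis.

Foot-stimulation evoked MUA is aligned to stimulus onsets, a 5 ms
post-stimulus artifact window is excluded, and ESA is computed on a padded
5-55 ms segment then cropped to the 10-50 ms analysis window and binned at
1 ms.  Averaging the depth-aligned channel segments over trials gives one
heatmap per condition.  Pairwise mean-squared-error (MSE) matrices between
intensity-ordered heatmap families quantify gain shifts: under multiplicative
gain > 1, a query response resembles a *higher*-intensity baseline, moving
the per-column MSE minimum below the diagonal; gain < 1 moves it above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .esa import esa_transform
from .recording import Recording

__all__ = [
    "EvokedHeatmap",
    "MSEMatrix",
    "extract_evoked",
    "heatmap_mse",
    "mse_matrix",
    "diagonal_shift_summary",
]


@dataclass
class EvokedHeatmap:
    values: np.ndarray           # (channels, bins), microvolts
    bin_ms: float = 1.0
    window_ms: tuple[float, float] = (10.0, 50.0)
    n_trials: int = 0
    intensity_ma: float | None = None
    idc_amplitude_ua: float | None = None


@dataclass
class MSEMatrix:
    values: np.ndarray           # uV^2, (n_reference, n_query)
    row_labels: list             # reference identifiers (matrix rows)
    col_labels: list             # query identifiers (columns)


def extract_evoked(rec: Recording, onsets_s=None, artifact_ms: float = 5.0,
                   window_ms: tuple[float, float] = (10.0, 50.0),
                   pad_ms: float = 5.0, bin_ms: float = 1.0,
                   sigma_ms: float = 1.0) -> EvokedHeatmap:
    """Trial-averaged ESA heatmap around stimulus onsets.

    ``rec`` holds band-passed MUA.  Onsets default to ``rec.onsets_s``.
    Trials whose padded segment overruns the recording are dropped with a
    warning; if all are dropped an error is raised.
    """
    if onsets_s is None:
        onsets_s = rec.onsets_s
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if onsets_s.size == 0:
        raise ValueError("at least one stimulus onset required")
    fs = rec.sampling_rate
    w0, w1 = window_ms
    if w0 < artifact_ms:
        raise ValueError("analysis window must start after the artifact window")
    seg0_ms, seg1_ms = w0 - pad_ms, w1 + pad_ms
    n_seg = int(round((seg1_ms - seg0_ms) * 1e-3 * fs))
    n_bins = int(round((w1 - w0) / bin_ms))
    crop0 = int(round(pad_ms * 1e-3 * fs))

    trial_maps = []
    for t in onsets_s:
        i0 = int(round((t + seg0_ms * 1e-3) * fs))
        i1 = i0 + n_seg
        if i0 < 0 or i1 > rec.samples.shape[1]:
            warnings.warn(f"dropping trial at {t:.3f} s: outside recording")
            continue
        env = esa_transform(rec.samples[:, i0:i1], fs, sigma_ms=sigma_ms)
        env = env[:, crop0:crop0 + int(round((w1 - w0) * 1e-3 * fs))]
        # 1 ms binning of the cropped window
        edges = np.round(np.arange(n_bins + 1) * bin_ms * 1e-3 * fs).astype(int)
        sums = np.add.reduceat(env, edges[:-1], axis=-1)
        sums[:, -1] = env[:, edges[-2]:edges[-1]].sum(axis=-1)
        trial_maps.append(sums / np.diff(edges))
    if not trial_maps:
        raise ValueError("all trials dropped: no onset fits the recording")
    values = np.mean(trial_maps, axis=0)
    return EvokedHeatmap(values=values, bin_ms=bin_ms, window_ms=window_ms,
                         n_trials=len(trial_maps),
                         intensity_ma=rec.intensity_ma,
                         idc_amplitude_ua=rec.idc_amplitude_ua)


def heatmap_mse(a: EvokedHeatmap | np.ndarray, b: EvokedHeatmap | np.ndarray) -> float:
    """Mean squared difference (uV^2) between two vectorized heatmaps."""
    va = a.values if isinstance(a, EvokedHeatmap) else np.asarray(a)
    vb = b.values if isinstance(b, EvokedHeatmap) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch {va.shape} vs {vb.shape}")
    return float(np.mean((va - vb) ** 2))


def mse_matrix(reference_maps, query_maps) -> MSEMatrix:
    """Pairwise MSE between intensity-ordered reference (rows) and query
    (columns) heatmap families."""
    reference_maps = list(reference_maps)
    query_maps = list(query_maps)
    if not reference_maps or not query_maps:
        raise ValueError("both map lists must be nonempty")
    vals = np.array([[heatmap_mse(r, q) for q in query_maps]
                     for r in reference_maps])

    def _label(m, i):
        return getattr(m, "intensity_ma", None) if isinstance(m, EvokedHeatmap) else i

    return MSEMatrix(
        values=vals,
        row_labels=[_label(m, i) for i, m in enumerate(reference_maps)],
        col_labels=[_label(m, i) for i, m in enumerate(query_maps)],
    )


def diagonal_shift_summary(matrix: MSEMatrix | np.ndarray) -> tuple[float, float]:
    """(mean above diagonal, mean below diagonal) of an MSE matrix.

    With intensities ascending along both axes, mass above the diagonal
    means queries resemble lower-intensity references, below the diagonal
    higher-intensity references.
    """
    v = matrix.values if isinstance(matrix, MSEMatrix) else np.asarray(matrix)
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("matrix must be at least 2x2")
    rows, cols = np.indices(v.shape)
    above = v[rows < cols]
    below = v[rows > cols]
    return float(above.mean()), float(below.mean())
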