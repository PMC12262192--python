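"""Synthetic recordings and behavioral tables with the structure the
analyses assume.

Three generators emulate the study's data:

* ``simulate_spontaneous`` — 32-channel laminar MUA at 24.414 kHz for 90 s:
  per channel, inhomogeneous Poisson spiking whose rate follows a ~1 Hz
  slow-wave envelope (strongest in deep layers), convolved with a biphasic
  spike template, plus a shared slow-wave LFP component and Gaussian noise.
  A per-channel multiplicative gain applies during the 30-60 s epoch,
  standing in for the iDC-induced excitability change.
* ``simulate_evoked`` — stimulus-locked rate transients at ~20 ms latency
  whose amplitude saturates with foot-shock intensity and scales with gain;
  ipsilateral mode adds no response.
* ``simulate_vonfrey`` — Von Frey staircase blocks: a latent withdrawal
  threshold with rat and session random intercepts and amplitude-dependent
  shifts drives a five-trial SUDO staircase.

All generators are pure functions of their config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import (DESIGN_AMPLITUDES, FilamentLadder, run_staircase,
                       sudo_threshold)
from .esa import assign_layer
from .kernel import GainKernelMap
from .recording import EpochWindows, Recording, default_channel_depths

__all__ = [
    "SpontaneousSimConfig",
    "EvokedSimConfig",
    "BehaviorSimConfig",
    "simulate_spontaneous",
    "simulate_evoked",
    "simulate_vonfrey",
    "spike_template",
    "gain_profile_from_kernel",
]

#: Default foot-shock intensity family (mA): spans the steep part of the
#: saturating intensity-response map so adjacent levels are distinct.
DEFAULT_INTENSITIES_MA = (0.8, 1.2, 1.6, 2.0, 2.4)

#: Layer-wise spontaneous rates (Hz) under urethane; L5-dominant.
DEFAULT_BASE_RATES = {"L1": 1.0, "L2/3": 5.0, "L4": 8.0, "L5": 25.0, "L6": 6.0}

#: Reported contralateral threshold shifts (g) vs 0 uA, by amplitude.
CONTRA_EFFECTS_G = {-40: 4.213, -20: 0.250, 20: -3.794, 40: -4.329}


def spike_template(fs: float, width_ms: float = 1.0, peak_uv: float = 80.0) -> np.ndarray:
    """Biphasic ms-scale extracellular spike waveform (near-zero net area)."""
    n = max(int(round(width_ms * 1e-3 * fs)), 2)
    return peak_uv * np.sin(2 * np.pi * np.arange(n) / n)


@dataclass(frozen=True)
class SpontaneousSimConfig:
    fs: float = 24414.0
    duration_s: float = 90.0
    n_channels: int = 32
    depth_pitch_mm: float = 0.05
    top_depth_mm: float = 0.1
    slow_wave_hz: float = 1.0
    modulation_depth: float = 0.8
    base_rates_hz: dict = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    spike_peak_uv: float = 80.0
    spike_width_ms: float = 1.0
    noise_sd_uv: float = 5.0
    lfp_amplitude_uv: float = 150.0
    gain_profile: tuple | None = None      # per-channel multiplier, during epoch
    gain_window_s: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise ValueError("modulation_depth must be in [0, 1]")
        if any(r < 0 for r in self.base_rates_hz.values()):
            raise ValueError("base rates must be >= 0")
        if self.gain_profile is not None and len(self.gain_profile) != self.n_channels:
            raise ValueError("gain_profile length must equal n_channels")


def _channel_rates(cfg: SpontaneousSimConfig, depths: np.ndarray) -> np.ndarray:
    rates = np.empty(depths.size)
    for i, d in enumerate(depths):
        layer = assign_layer(d)
        rates[i] = cfg.base_rates_hz.get(layer, 0.0) if layer else 0.0
    return rates


def simulate_spontaneous(cfg: SpontaneousSimConfig) -> Recording:
    """Generate a spontaneous laminar MUA recording (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    dt = 1.0 / cfg.fs
    depths = default_channel_depths(cfg.n_channels, cfg.depth_pitch_mm,
                                    cfg.top_depth_mm)
    base = _channel_rates(cfg, depths)
    t = np.arange(n) * dt
    envelope = 1.0 + cfg.modulation_depth * np.sin(2 * np.pi * cfg.slow_wave_hz * t)
    g0, g1 = cfg.gain_window_s
    in_gain = (t >= g0) & (t < g1)
    lfp_phase = rng.uniform(0, 2 * np.pi)
    lfp = cfg.lfp_amplitude_uv * np.sin(2 * np.pi * cfg.slow_wave_hz * t + lfp_phase)
    template = spike_template(cfg.fs, cfg.spike_width_ms, cfg.spike_peak_uv)
    gains = (np.asarray(cfg.gain_profile, dtype=float)
             if cfg.gain_profile is not None else np.ones(cfg.n_channels))

    out = np.empty((cfg.n_channels, n), dtype=np.float32)
    for c in range(cfg.n_channels):
        rate = base[c] * envelope
        if gains[c] != 1.0:
            rate = rate.copy()
            rate[in_gain] *= gains[c]
        np.clip(rate, 0.0, None, out=rate)
        spikes = (rng.random(n) < rate * dt).astype(float)
        sig = signal.oaconvolve(spikes, template)[:n] if spikes.any() else np.zeros(n)
        sig += lfp
        if cfg.noise_sd_uv > 0:
            sig += rng.normal(0.0, cfg.noise_sd_uv, n)
        out[c] = sig
    return Recording(samples=out, sampling_rate=cfg.fs,
                     channel_depths_mm=depths, epochs=EpochWindows())


def amplitude_vs_intensity(intensity_ma, i50_ma: float = 1.5, hill: float = 2.0):
    """Monotone saturating intensity -> relative response amplitude map."""
    i = np.asarray(intensity_ma, dtype=float)
    out = i**hill / (i**hill + i50_ma**hill)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EvokedSimConfig:
    fs: float = 24414.0
    n_channels: int = 32
    depth_pitch_mm: float = 0.05
    top_depth_mm: float = 0.1
    onset_start_s: float = 1.0
    onset_interval_s: float = 2.0
    n_onsets: int = 10
    latency_ms: float = 20.0
    latency_jitter_ms: float = 0.5
    response_sigma_ms: float = 4.0
    peak_rate_hz: float = 1500.0
    intensity_ma: float = 2.0
    i50_ma: float = 1.5
    gain: float = 1.0
    contralateral: bool = True
    response_center_mm: float = 1.0
    response_sigma_mm: float = 0.35
    background_rate_hz: float = 2.0
    spike_peak_uv: float = 80.0
    spike_width_ms: float = 1.0
    noise_sd_uv: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latency_ms <= 5.0:
            raise ValueError("latency must exceed the 5 ms artifact window")
        tail = self.latency_ms * 1e-3 + 0.1
        if self.onset_start_s + self.onset_interval_s * (self.n_onsets - 1) + tail \
                > self.duration_s:
            raise ValueError("onset schedule does not fit the recording")

    @property
    def duration_s(self) -> float:
        return self.onset_start_s + self.onset_interval_s * self.n_onsets


def simulate_evoked(cfg: EvokedSimConfig, base: Recording | None = None) -> Recording:
    """Generate an evoked-response recording with its onset schedule.

    If ``base`` is given, transients are added on top of it; otherwise a
    noise-plus-background recording of the schedule's duration is created.
    Response peak rate = peak_rate * A(intensity) * gain, depth-weighted;
    ipsilateral mode (``contralateral=False``) adds no evoked response.
    """
    rng = np.random.default_rng(cfg.seed)
    onsets = cfg.onset_start_s + cfg.onset_interval_s * np.arange(cfg.n_onsets)
    if base is None:
        n = int(round(cfg.duration_s * cfg.fs))
        depths = default_channel_depths(cfg.n_channels, cfg.depth_pitch_mm,
                                        cfg.top_depth_mm)
        samples = np.zeros((cfg.n_channels, n), dtype=np.float32)
    else:
        samples = base.samples.astype(np.float32).copy()
        depths = base.channel_depths_mm
        n = samples.shape[1]
    t = np.arange(n) / cfg.fs
    template = spike_template(cfg.fs, cfg.spike_width_ms, cfg.spike_peak_uv)
    amp = amplitude_vs_intensity(cfg.intensity_ma, cfg.i50_ma) * cfg.gain
    depth_w = np.exp(-((depths - cfg.response_center_mm) ** 2)
                     / (2 * cfg.response_sigma_mm**2))
    dt = 1.0 / cfg.fs
    sigma_s = cfg.response_sigma_ms * 1e-3

    jitters = rng.normal(0.0, cfg.latency_jitter_ms * 1e-3, cfg.n_onsets)
    for c in range(samples.shape[0]):
        rate = np.full(n, cfg.background_rate_hz)
        if cfg.contralateral and amp > 0:
            for k, on in enumerate(onsets):
                center = on + cfg.latency_ms * 1e-3 + jitters[k]
                i0 = max(int((center - 5 * sigma_s) * cfg.fs), 0)
                i1 = min(int((center + 5 * sigma_s) * cfg.fs), n)
                rate[i0:i1] += (cfg.peak_rate_hz * amp * depth_w[c]
                                * np.exp(-((t[i0:i1] - center) ** 2)
                                         / (2 * sigma_s**2)))
        spikes = (rng.random(n) < rate * dt).astype(float)
        sig = signal.oaconvolve(spikes, template)[:n]
        if cfg.noise_sd_uv > 0:
            sig += rng.normal(0.0, cfg.noise_sd_uv, n)
        samples[c] += sig.astype(np.float32)
    return Recording(samples=samples, sampling_rate=cfg.fs,
                     channel_depths_mm=depths, onsets_s=onsets,
                     intensity_ma=cfg.intensity_ma,
                     idc_amplitude_ua=None)


@dataclass(frozen=True)
class BehaviorSimConfig:
    n_rats: int = 2
    n_sessions: int = 7
    blocks_per_amplitude: int = 2          # per session per paw
    amplitudes_ua: tuple = DESIGN_AMPLITUDES
    paws: tuple = ("contra", "ipsi")
    baseline_g: float = 8.0
    contra_effects_g: dict = field(default_factory=lambda: dict(CONTRA_EFFECTS_G))
    ipsi_effects_g: dict = field(default_factory=dict)
    rat_sd_g: float = 1.0
    session_sd_g: float = 0.5
    residual_sd_g: float = 2.0
    response_rule: str = "deterministic"   # or "logistic"
    logistic_slope: float = 0.2            # log-force units
    start_force_g: float = 8.0
    ladder: FilamentLadder = field(default_factory=FilamentLadder)
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.rat_sd_g, self.session_sd_g, self.residual_sd_g):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if any(a not in DESIGN_AMPLITUDES for a in self.amplitudes_ua):
            raise ValueError("amplitudes must come from the design set")
        if self.response_rule not in ("deterministic", "logistic"):
            raise ValueError("response_rule must be deterministic or logistic")


def simulate_vonfrey(cfg: BehaviorSimConfig) -> pd.DataFrame:
    """Generate a Von Frey block table with SUDO thresholds.

    Latent block threshold = baseline + effect(amplitude, paw) + rat
    intercept + session intercept + residual; the staircase is run with the
    configured response rule to produce five outcomes, then scored by SUDO.
    """
    rng = np.random.default_rng(cfg.seed)
    start_index = cfg.ladder.index_nearest(cfg.start_force_g)
    effects = {"contra": cfg.contra_effects_g, "ipsi": cfg.ipsi_effects_g}
    rows = []
    for r in range(cfg.n_rats):
        b_rat = rng.normal(0.0, cfg.rat_sd_g)
        for s in range(cfg.n_sessions):
            b_sess = rng.normal(0.0, cfg.session_sd_g)
            for paw in cfg.paws:
                for a in cfg.amplitudes_ua:
                    for _ in range(cfg.blocks_per_amplitude):
                        theta = (cfg.baseline_g + effects[paw].get(a, 0.0)
                                 + b_rat + b_sess
                                 + rng.normal(0.0, cfg.residual_sd_g))
                        theta = max(theta, cfg.ladder[0])
                        if cfg.response_rule == "deterministic":
                            respond = lambda f, th=theta: f >= th
                        else:
                            def respond(f, th=theta):
                                z = (np.log(f) - np.log(th)) / cfg.logistic_slope
                                return rng.random() < 1.0 / (1.0 + np.exp(-z))
                        outcomes = run_staircase(cfg.ladder, start_index, respond)
                        thr = sudo_threshold(cfg.ladder, start_index, outcomes)
                        rows.append((f"rat{r}", f"s{s}", s, paw, a, start_index,
                                     outcomes, thr, theta))
    return pd.DataFrame(rows, columns=["rat", "session", "day", "paw",
                                       "amplitude_ua", "start_index",
                                       "outcomes", "threshold_g",
                                       "true_threshold_g"])


def gain_profile_from_kernel(kmap: GainKernelMap, lateral_mm: float,
                             channel_depths_mm: np.ndarray,
                             coupling: float = 0.3) -> np.ndarray:
    """Per-channel gain multiplier from a gain-kernel column.

    S is a polarization score, not a rate: the column at ``lateral_mm`` is
    normalized by the map's peak magnitude and mapped linearly to a
    multiplicative gain ``1 + coupling * S_norm``, linking the forward model
    to the recording generator end-to-end.
    """
    col_idx = int(np.argmin(np.abs(kmap.lateral_axis - lateral_mm)))
    col = kmap.values[col_idx]
    peak = np.max(np.abs(kmap.values))
    if peak == 0:
        return np.ones(len(channel_depths_mm))
    s_norm = np.interp(channel_depths_mm, kmap.depth_axis, col / peak)
    return 1.0 + coupling * s_norm
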