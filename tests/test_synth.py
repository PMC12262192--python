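"""Synthetic-data generators: determinism, structure, and recovery hooks."""

import numpy as np
import pytest

from idcmod.behavior import FilamentLadder
from idcmod.esa import bandpass_mua, esa_transform
from idcmod.evoked import extract_evoked
from idcmod.kernel import GainKernelMap
from idcmod.synth import (BehaviorSimConfig, EvokedSimConfig,
                          SpontaneousSimConfig, amplitude_vs_intensity,
                          gain_profile_from_kernel, simulate_evoked,
                          simulate_spontaneous, simulate_vonfrey,
                          spike_template)

SMALL = dict(fs=2000.0, duration_s=3.0, n_channels=4,
             gain_window_s=(1.0, 2.0))


class TestSpontaneous:
    def test_same_seed_bit_identical(self):
        cfg = SpontaneousSimConfig(seed=5, **SMALL)
        r1 = simulate_spontaneous(cfg)
        r2 = simulate_spontaneous(cfg)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_different_seeds_differ(self):
        r1 = simulate_spontaneous(SpontaneousSimConfig(seed=1, **SMALL))
        r2 = simulate_spontaneous(SpontaneousSimConfig(seed=2, **SMALL))
        assert np.any(r1.samples != r2.samples)

    def test_silent_config_all_zero(self):
        cfg = SpontaneousSimConfig(
            noise_sd_uv=0.0, lfp_amplitude_uv=0.0,
            base_rates_hz={"L1": 0.0, "L2/3": 0.0, "L4": 0.0, "L5": 0.0,
                           "L6": 0.0},
            seed=0, **SMALL)
        rec = simulate_spontaneous(cfg)
        assert not np.any(rec.samples)

    def test_depths_follow_probe_layout(self):
        rec = simulate_spontaneous(SpontaneousSimConfig(seed=0, **SMALL))
        np.testing.assert_allclose(np.diff(rec.channel_depths_mm), 0.05)

    def test_modulation_depth_validated(self):
        with pytest.raises(ValueError):
            SpontaneousSimConfig(modulation_depth=1.5)

    def test_gain_profile_length_validated(self):
        with pytest.raises(ValueError):
            SpontaneousSimConfig(n_channels=4, gain_profile=(1.0, 1.0))

    def test_slow_wave_modulates_spike_density(self):
        # spiking concentrates on the rising half of the ~1 Hz envelope
        cfg = SpontaneousSimConfig(
            fs=5000.0, duration_s=10.0, n_channels=1, top_depth_mm=1.2,
            base_rates_hz={"L5": 60.0}, modulation_depth=1.0,
            noise_sd_uv=0.0, lfp_amplitude_uv=0.0, seed=4,
            gain_window_s=(4.0, 6.0))
        rec = simulate_spontaneous(cfg)
        t = np.arange(rec.samples.shape[1]) / cfg.fs
        phase = np.sin(2 * np.pi * cfg.slow_wave_hz * t)
        power = rec.samples[0] ** 2
        up = power[phase > 0.5].mean()
        down = power[phase < -0.5].mean()
        assert up > 5 * down


class TestEvoked:
    def test_monotone_intensity_monotone_response(self):
        def peak(intensity):
            cfg = EvokedSimConfig(fs=12000.0, n_channels=4, n_onsets=4,
                                  intensity_ma=intensity, noise_sd_uv=0.2,
                                  seed=11)
            rec = simulate_evoked(cfg)
            hm = extract_evoked(bandpass_mua(rec))
            return hm.values.max()

        p1, p2 = peak(1.0), peak(2.4)
        assert p2 > p1

    def test_ipsilateral_mode_near_zero(self):
        cfg = EvokedSimConfig(fs=12000.0, n_channels=4, n_onsets=4,
                              contralateral=False, background_rate_hz=0.0,
                              noise_sd_uv=0.2, seed=3)
        rec = simulate_evoked(cfg)
        hm = extract_evoked(bandpass_mua(rec))
        # envelope stays at the rectified-noise floor
        assert hm.values.max() < 5 * 0.2

    def test_latency_respects_artifact_window(self):
        with pytest.raises(ValueError):
            EvokedSimConfig(latency_ms=3.0)

    def test_onset_schedule_recorded(self):
        cfg = EvokedSimConfig(fs=12000.0, n_channels=2, n_onsets=3, seed=0)
        rec = simulate_evoked(cfg)
        np.testing.assert_allclose(rec.onsets_s, [1.0, 3.0, 5.0])

    def test_amplitude_map_monotone_saturating(self):
        i = np.linspace(0.1, 5.0, 50)
        a = amplitude_vs_intensity(i)
        assert np.all(np.diff(a) > 0) and a[-1] < 1.0

    def test_template_biphasic_near_zero_area(self):
        k = spike_template(24414.0)
        assert k.max() == pytest.approx(80.0, rel=0.01)
        assert abs(k.sum()) < 0.05 * np.abs(k).sum()


class TestVonFrey:
    def test_same_seed_identical_table(self):
        cfg = BehaviorSimConfig(seed=9, n_sessions=2)
        df1 = simulate_vonfrey(cfg)
        df2 = simulate_vonfrey(cfg)
        assert df1.equals(df2)

    def test_design_shape(self):
        cfg = BehaviorSimConfig(seed=0, n_sessions=2)
        df = simulate_vonfrey(cfg)
        assert len(df) == 2 * 2 * 2 * 5 * 2  # rats x sessions x paws x amps x blocks
        assert set(df["paw"]) == {"contra", "ipsi"}
        assert df["outcomes"].str.fullmatch("[XO]{5}").all()

    def test_noise_free_thresholds_near_baseline(self):
        cfg = BehaviorSimConfig(seed=1, n_sessions=2, rat_sd_g=0.0,
                                session_sd_g=0.0, residual_sd_g=0.0,
                                contra_effects_g={}, ipsi_effects_g={})
        df = simulate_vonfrey(cfg)
        ladder = np.asarray(cfg.ladder.forces)
        i_base = cfg.ladder.index_nearest(cfg.baseline_g)
        for thr in df["threshold_g"]:
            i_est = int(np.argmin(np.abs(ladder - thr)))
            assert abs(i_est - i_base) <= 1

    def test_amplitude_set_validated(self):
        with pytest.raises(ValueError):
            BehaviorSimConfig(amplitudes_ua=(0, 30))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            BehaviorSimConfig(residual_sd_g=-1.0)


class TestGainLinkage:
    def test_kernel_column_maps_to_gain_profile(self):
        lat = np.linspace(0, 2.2, 200)
        dep = np.linspace(0, 2.2, 200)
        vals = np.zeros((200, 200))
        vals[100, :] = np.linspace(0, 1.0, 200)  # column peaking at depth
        kmap = GainKernelMap(values=vals, lateral_axis=lat, depth_axis=dep)
        depths = np.array([0.1, 1.1, 2.1])
        g = gain_profile_from_kernel(kmap, lat[100], depths, coupling=0.3)
        assert g[0] < g[1] < g[2]
        assert g[2] == pytest.approx(1.0 + 0.3 * (2.1 / 2.2), rel=0.05)

    def test_zero_map_gives_unit_gains(self):
        kmap = GainKernelMap(values=np.zeros((10, 10)),
                             lateral_axis=np.linspace(0, 2.2, 10),
                             depth_axis=np.linspace(0, 2.2, 10))
        np.testing.assert_array_equal(
            gain_profile_from_kernel(kmap, 1.1, np.array([0.5, 1.0])), 1.0)


def test_esa_gain_recovery_small_scale():
    """A 1.5x during-epoch gain is read back by the ESA percent change."""
    pcs = []
    for seed in range(3):
        cfg = SpontaneousSimConfig(
            fs=12000.0, duration_s=9.0, n_channels=2, top_depth_mm=1.2,
            base_rates_hz={"L5": 40.0}, noise_sd_uv=0.05,
            gain_profile=(1.5, 1.5), gain_window_s=(3.0, 6.0), seed=seed)
        rec = simulate_spontaneous(cfg)
        mua = bandpass_mua(rec)
        env = esa_transform(mua.samples, cfg.fs)
        pre = env[:, int(0.2 * cfg.fs):int(2.8 * cfg.fs)].mean()
        dur = env[:, int(3.2 * cfg.fs):int(5.8 * cfg.fs)].mean()
        pcs.append(100.0 * (dur - pre) / pre)
    assert np.mean(pcs) == pytest.approx(50.0, abs=12.0)
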