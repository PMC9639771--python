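"""Synthetic-trial generator: pool, protocol, spikes, mechanics, EMG, imaging."""

import dataclasses

import numpy as np
import pytest

import neuromech as nm
from neuromech.simdata import (
    ImagingConfig,
    _geometry_at,
    make_template_library,
    render_ultrasound,
    seed_streams,
)


class TestPool:
    def test_threshold_ladder(self):
        pool = nm.build_pool(nm.PoolConfig(n_units=7))
        assert pool.thresholds.size == 7
        assert np.all(np.diff(pool.thresholds) > 0)
        assert pool.thresholds[-1] / pool.thresholds[0] == pytest.approx(30.0)

    def test_rate_at_threshold_is_min_rate(self):
        cfg = nm.PoolConfig()
        pool = nm.build_pool(cfg)
        for u in range(cfg.n_units):
            assert pool.rate(u, pool.thresholds[u]) == pytest.approx(cfg.min_rate)
            assert pool.rate(u, pool.thresholds[u] - 1e-9) == 0.0

    def test_rate_saturates_at_peak(self):
        pool = nm.build_pool(nm.PoolConfig(rate_gain=5.0))
        assert pool.rate(0, 100.0) == pytest.approx(35.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            nm.PoolConfig(n_units=0)

    def test_pooled_plateau_rate_near_fifteen_hz(self):
        """Monte-Carlo calibration: mean unit rate on a 20 %MVC plateau."""
        fs = 2048.0
        exc = np.full(int(30 * fs), 20.0)
        rates = []
        for seed in range(10):
            pool = nm.build_pool(nm.PoolConfig())
            spikes = nm.sample_spikes(pool, exc, fs, seed)
            for t in spikes:
                r, _ = nm.discharge_rate_stats(t, (0, exc.size))
                rates.append(r)
        assert 13.0 < np.mean(rates) < 18.0


class TestExcitation:
    def test_sustained_ramp_durations(self):
        p = nm.ProtocolConfig(target_level=20.0)
        assert p.ramp_samples == pytest.approx(2.0 * p.fs)
        p40 = nm.ProtocolConfig(target_level=40.0)
        assert p40.n_samples == pytest.approx(38.0 * p40.fs)  # 4 + 30 + 4 s

    def test_sinusoidal_plateau_span(self):
        p = nm.ProtocolConfig(mode="sinusoidal")
        exc = nm.generate_excitation(p)
        lo, hi = p.segments()["plateau"]
        assert exc[lo:hi].min() == pytest.approx(17.5, abs=1e-3)
        assert exc[lo:hi].max() == pytest.approx(22.5, abs=1e-3)

    def test_nonpositive_plateau_rejected(self):
        with pytest.raises(ValueError):
            nm.ProtocolConfig(plateau_s=0.0)


class TestSpikes:
    def test_subthreshold_drive_gives_empty_trains(self):
        pool = nm.build_pool(nm.PoolConfig())
        spikes = nm.sample_spikes(pool, np.zeros(4096), 2048.0, 0)
        assert spikes.total_discharges() == 0

    def test_deterministic_renewal_isis(self):
        # cv = 0 at constant drive with 10-Hz rate and fs chosen so the
        # interval is an integer number of samples: ISIs exactly 100 ms
        fs = 2000.0
        cfg = nm.PoolConfig(n_units=1, min_threshold=10.0, min_rate=10.0, isi_cv=0.0)
        pool = nm.build_pool(cfg)
        spikes = nm.sample_spikes(pool, np.full(int(5 * fs), 10.0), fs, 0)
        isis = spikes.trains[0].isi_ms()
        assert np.allclose(isis, 100.0)

    def test_isi_cv_matches_configuration(self):
        fs = 2048.0
        cfg = nm.PoolConfig(n_units=1, min_threshold=2.0, isi_cv=0.15)
        pool = nm.build_pool(cfg)
        isis = []
        for seed in range(3):
            spikes = nm.sample_spikes(pool, np.full(int(30 * fs), 20.0), fs, seed)
            isis.append(spikes.trains[0].isi_ms())
        isis = np.concatenate(isis)
        assert isis.size > 200
        cv = isis.std() / isis.mean()
        assert cv == pytest.approx(0.15, abs=0.03)

    def test_no_discharges_below_threshold(self):
        pool = nm.build_pool(nm.PoolConfig())
        p = nm.ProtocolConfig(plateau_s=5.0)
        exc = nm.generate_excitation(p)
        spikes = nm.sample_spikes(pool, exc, p.fs, 1)
        for u, train in enumerate(spikes):
            assert np.all(exc[train.discharges] >= pool.thresholds[u])


class TestMechanics:
    def test_pure_shift_places_response_at_exact_delay(self):
        """A drive bump reappears in fascicle at +Df and in torque at +Df+Dt."""
        p = nm.ProtocolConfig(target_level=10.0, plateau_s=20.0)
        exc = nm.generate_excitation(p)
        lo, hi = p.segments()["plateau"]
        mid = (lo + hi) // 2
        t = np.arange(exc.size)
        exc = exc + 5.0 * np.exp(-((t - mid) ** 2) / (2 * (0.05 * p.fs) ** 2))
        mech = dataclasses.replace(
            nm.SHORT_TA, torque_noise_pct=0.0, fascicle_noise_mm=0.0
        )
        res = nm.synthesize_mechanics(exc, mech, p)
        nf = int(round(75.0 / 1000.0 * p.fs))
        assert np.argmax(res.delta_mm_fs) == np.argmax(res.drive_pct) + nf
        assert np.argmax(res.torque_pct) == np.argmax(res.drive_pct) + 2 * nf
        assert res.applied_delays_ms[0] == pytest.approx(75.0, abs=0.5)

    def test_plateau_shortening_calibration(self):
        """CST-driven 20 %MVC plateau shortens by the configured 7.5 mm."""
        mech = dataclasses.replace(nm.SHORT_TA, fascicle_noise_mm=0.0)
        p = nm.ProtocolConfig(plateau_s=15.0)
        lo, hi = p.segments()["plateau"]
        means = []
        for seed in range(10):
            trial = nm.simulate_trial(protocol=p, mechanics=mech, seed=seed)
            means.append(trial.truth_delta_fs[lo:hi].mean())
        assert np.mean(means) == pytest.approx(7.5, rel=0.05)

    def test_rest_and_contracted_lengths_match_architecture(self):
        mech = dataclasses.replace(nm.SHORT_TA, fascicle_noise_mm=0.0)
        p = nm.ProtocolConfig(plateau_s=15.0, rest_s=0.5)
        trial = nm.simulate_trial(protocol=p, mechanics=mech, seed=0)
        trace = trial.truth_fascicle
        assert trace.length_mm[0] == pytest.approx(60.2, abs=0.2)
        lo, hi = p.segments()["plateau"]
        on_plateau = (trial.frame_samples >= lo) & (trial.frame_samples < hi)
        assert trace.length_mm[on_plateau].mean() == pytest.approx(52.7, abs=0.8)
        assert trace.pennation_deg[on_plateau].mean() == pytest.approx(19.2, abs=0.8)

    def test_excessive_delay_rejected(self):
        p = nm.ProtocolConfig(plateau_s=1.0, target_level=20.0)
        mech = dataclasses.replace(nm.SHORT_TA, delay_drive_to_fascicle_ms=1e6)
        with pytest.raises(ValueError):
            nm.synthesize_mechanics(nm.generate_excitation(p), mech, p)


class TestEmg:
    def test_noise_only_when_no_spikes(self, rng):
        spikes = nm.SpikeTrainSet((), 2048.0)
        emg = nm.synthesize_emg(spikes, [], 4096, noise_sd=0.05, rng=rng)
        assert emg.std(axis=0) == pytest.approx(np.full(32, 0.05), rel=0.15)

    def test_single_discharge_reproduces_template(self):
        lib = make_template_library(1, rng=7)
        train = nm.SpikeTrain(0, np.array([1000]), 2048.0)
        spikes = nm.SpikeTrainSet((train,), 2048.0)
        emg = nm.synthesize_emg(spikes, lib, 4096, noise_sd=0.0)
        ln = lib[0].shape[1]
        lo = 1000 - ln // 2
        assert np.allclose(emg[lo : lo + ln, :].T, lib[0])
        mask = np.ones(4096, dtype=bool)
        mask[lo : lo + ln] = False
        assert np.all(emg[mask] == 0.0)

    def test_superposition_of_overlapping_units(self):
        lib = make_template_library(2, rng=7)
        a = nm.SpikeTrainSet((nm.SpikeTrain(0, np.array([1000]), 2048.0),), 2048.0)
        b = nm.SpikeTrainSet((nm.SpikeTrain(0, np.array([1005]), 2048.0),), 2048.0)
        both = nm.SpikeTrainSet(
            (nm.SpikeTrain(0, np.array([1000]), 2048.0),
             nm.SpikeTrain(1, np.array([1005]), 2048.0)),
            2048.0,
        )
        e1 = nm.synthesize_emg(a, [lib[0]], 4096, noise_sd=0.0)
        e2 = nm.synthesize_emg(b, [lib[1]], 4096, noise_sd=0.0)
        e12 = nm.synthesize_emg(both, lib, 4096, noise_sd=0.0)
        assert np.allclose(e12, e1 + e2)

    def test_template_longer_than_recording_rejected(self):
        lib = make_template_library(1, rng=0)
        spikes = nm.SpikeTrainSet((nm.SpikeTrain(0, np.array([5]), 2048.0),), 2048.0)
        with pytest.raises(ValueError):
            nm.synthesize_emg(spikes, lib, 10, noise_sd=0.0)


class TestRenderer:
    def test_static_geometry_gives_identical_frames(self):
        trace = nm.FascicleTrace(
            length_mm=np.full(5, 60.2),
            pennation_deg=np.full(5, 15.2),
            frame_rate=80.0,
            rest_length_mm=60.2,
        )
        frames, trigger, _ = render_ultrasound(trace, rng=0)
        for k in range(1, 5):
            assert np.array_equal(frames[k], frames[0])

    def test_frame_and_trigger_counts(self):
        n = 800  # 10 s at 80 fps
        trace = nm.FascicleTrace(np.full(n, 60.2), np.full(n, 15.2), 80.0, 60.2)
        frames, trigger, _ = render_ultrasound(trace, rng=0)
        assert frames.shape[0] == n
        edges = np.flatnonzero((trigger[1:] > 0) & (trigger[:-1] == 0)) + 1
        if trigger[0] > 0:
            edges = np.concatenate([[0], edges])
        assert edges.size == n

    def test_commanded_endpoints_encode_length(self):
        cfg = ImagingConfig()
        for L, pen in [(60.2, 15.2), (52.7, 19.2), (74.5, 12.0)]:
            g = _geometry_at(cfg, L, pen)
            assert abs(g.length_px - L / cfg.mm_per_px) < 0.1
            assert nm.pennation_angle(g) == pytest.approx(pen, abs=1e-9)

    def test_geometry_outside_image_rejected(self):
        trace = nm.FascicleTrace(np.full(3, 200.0), np.full(3, 15.0), 80.0, 200.0)
        with pytest.raises(ValueError):
            render_ultrasound(trace, rng=0)


class TestTrialAssembly:
    def test_bit_identical_under_fixed_seed(self):
        p = nm.ProtocolConfig(plateau_s=1.0)
        img = ImagingConfig(width=200, height=96, mm_per_px=0.4)
        kw = dict(protocol=p, seed=11, with_emg=True, with_frames=True, imaging=img)
        a = nm.simulate_trial(**kw)
        b = nm.simulate_trial(**kw)
        assert np.array_equal(a.torque_pct, b.torque_pct)
        assert np.array_equal(a.emg, b.emg)
        assert np.array_equal(a.frames, b.frames)
        assert all(
            np.array_equal(x.discharges, y.discharges)
            for x, y in zip(a.spikes, b.spikes)
        )

    def test_spike_count_conservation_in_cst(self, default_trial):
        cst = nm.cumulative_spike_train(default_trial.spikes, default_trial.n_samples)
        assert cst.total() == default_trial.spikes.total_discharges()

    def test_trigger_edges_match_frame_count(self, default_trial):
        tm = nm.align_trigger(default_trial.trigger, default_trial.fs, 80.0)
        assert tm.n_frames == default_trial.truth_fascicle.n_frames

    def test_hdf5_roundtrip(self, tmp_path):
        trial = nm.simulate_trial(protocol=nm.ProtocolConfig(plateau_s=1.0), seed=5)
        path = tmp_path / "trial.h5"
        trial.save_h5(path)
        back = nm.TrialRecording.load_h5(path)
        assert np.array_equal(back.torque_pct, trial.torque_pct)
        assert np.array_equal(back.truth_fascicle.length_mm, trial.truth_fascicle.length_mm)
        assert back.truth_delays_ms == pytest.approx(trial.truth_delays_ms)
        assert back.protocol == trial.protocol
        assert back.spikes.total_discharges() == trial.spikes.total_discharges()

    def test_named_seed_streams_are_independent(self):
        s1 = seed_streams(1)
        s2 = seed_streams(1)
        assert s1["isi"].standard_normal() == s2["isi"].standard_normal()
        assert s1["isi"].standard_normal() != s1["speckle"].standard_normal()
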