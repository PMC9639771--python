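"""Spike-train cleaning, CST, rate statistics, SIL and MUAP matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neuromech as nm
from neuromech.simdata import make_template_library
from neuromech.spiketools import CleaningFlags

FS = 2048.0


def train(indices, unit=0, fs=FS):
    return nm.SpikeTrain(unit, np.asarray(indices, dtype=np.int64), fs)


class TestCleaning:
    def test_duplicate_within_refractory_collapsed_to_first(self):
        cleaned, flags = nm.clean_discharges(train([1000, 1010, 3000]))
        assert list(cleaned.discharges) == [1000, 3000]
        assert flags.n_duplicates_removed == 1

    def test_regular_train_untouched(self):
        t = train(np.arange(0, 20480, 205))  # ~10 Hz
        cleaned, flags = nm.clean_discharges(t)
        assert np.array_equal(cleaned.discharges, t.discharges)
        assert flags.n_duplicates_removed == 0 and flags.n_gaps == 0

    def test_long_isi_flagged_not_modified(self):
        # one 300-ms ISI: flag only, the train itself is unchanged
        t = train([0, 205, 410, 1025, 1230])
        cleaned, flags = nm.clean_discharges(t)
        assert np.array_equal(cleaned.discharges, t.discharges)
        assert flags.n_gaps == 1 and flags.gap_indices == [2]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=100000), min_size=1, max_size=80)
    )
    def test_idempotent_and_never_increases(self, raw):
        t = train(np.unique(np.asarray(raw)))
        once, _ = nm.clean_discharges(t)
        twice, flags2 = nm.clean_discharges(once)
        assert once.n_discharges <= t.n_discharges
        assert np.array_equal(once.discharges, twice.discharges)
        assert flags2.n_duplicates_removed == 0


class TestCumulativeSpikeTrain:
    def test_empty_set_is_all_zero(self):
        cst = nm.cumulative_spike_train(nm.SpikeTrainSet((), FS), 100)
        assert cst.total() == 0 and cst.counts.size == 100

    def test_coincident_discharges_sum(self):
        s = nm.SpikeTrainSet((train([50], 0), train([50], 1)), FS)
        cst = nm.cumulative_spike_train(s, 100)
        assert cst.counts[50] == 2

    def test_conservation_invariant_under_reordering(self, rng):
        trains = tuple(
            train(np.sort(rng.choice(10000, size=50, replace=False)), u)
            for u in range(4)
        )
        a = nm.cumulative_spike_train(nm.SpikeTrainSet(trains, FS), 10000)
        b = nm.cumulative_spike_train(nm.SpikeTrainSet(trains[::-1], FS), 10000)
        assert np.array_equal(a.counts, b.counts)
        assert a.total() == sum(t.n_discharges for t in trains)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            nm.cumulative_spike_train(nm.SpikeTrainSet((train([100]),), FS), 100)

    def test_total_count_within_poisson_bounds(self):
        """5 units at a constant 15 Hz for 30 s: ~2250 discharges."""
        fs = 2048.0
        cfg = nm.PoolConfig(n_units=5, min_rate=15.0, rate_gain=0.0, isi_cv=0.15)
        pool = nm.build_pool(cfg)
        exc = np.full(int(30 * fs), 20.0)
        spikes = nm.sample_spikes(pool, exc, fs, 0)
        expected = 5 * 15 * 30
        assert abs(spikes.total_discharges() - expected) < 3 * np.sqrt(expected)


class TestRateStats:
    def test_regular_isis_give_exact_rate(self):
        t = train(np.arange(0, 20480, 205))
        rate, _ = nm.discharge_rate_stats(t, (0, 20480))
        assert rate == pytest.approx(FS / 205, rel=1e-9)

    def test_single_discharge_degenerate(self):
        t = train([5000])
        rate, smoothed = nm.discharge_rate_stats(t, (0, 10240))
        assert rate == 0.0
        assert smoothed.sum() / FS == pytest.approx(1.0, rel=1e-6)

    def test_smoothed_trace_integrates_to_spike_count(self):
        t = train(np.arange(1000, 40000, 137))
        _, smoothed = nm.discharge_rate_stats(t, (0, 41000))
        assert smoothed.sum() / FS == pytest.approx(t.n_discharges, rel=1e-3)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            nm.discharge_rate_stats(train([10]), (500, 500))

    def test_simulated_plateau_unit_rate_in_band(self, default_trial, default_analysis):
        rates = list(default_analysis.mean_rates_hz.values())
        active = [r for r in rates if r > 0]
        assert np.mean(active) == pytest.approx(15.3, abs=3.0)


class TestSil:
    @staticmethod
    def _source(sigma, seed, n=int(10 * FS), n_peaks=150):
        rng = np.random.default_rng(seed)
        src = rng.standard_normal(n) * sigma
        peaks = np.sort(rng.choice(np.arange(100, n - 100), n_peaks, replace=False))
        src[peaks] += 1.0
        return src, peaks

    def test_clean_source_accepted(self):
        src, peaks = self._source(0.05, 0)
        res = nm.compute_sil(src, peaks)
        assert res.sil >= 0.95 and res.accepted

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(1)
        src = rng.standard_normal(int(10 * FS)) * 0.2
        peaks = np.sort(rng.choice(np.arange(100, src.size - 100), 150, replace=False))
        res = nm.compute_sil(src, peaks)
        assert res.sil < 0.5 and not res.accepted

    def test_acceptance_boundary_is_inclusive(self):
        src, peaks = self._source(0.05, 2)
        res = nm.compute_sil(src, peaks)
        assert res.accepted == (res.sil >= res.threshold)
        # the gate itself: just below the threshold must reject
        res_lo = nm.compute_sil(src, peaks, threshold=res.sil + 1e-6)
        assert not res_lo.accepted
        res_hi = nm.compute_sil(src, peaks, threshold=res.sil)
        assert res_hi.accepted

    def test_degenerate_identical_amplitudes_score_zero(self):
        src = np.zeros(5000)
        peaks = np.array([100, 200, 300])
        src[peaks] = 1.0
        src[np.array([150, 250, 350])] = 1.0  # identical non-claimed maxima
        res = nm.compute_sil(src, peaks)
        assert res.sil == 0.0

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            nm.compute_sil(np.zeros(100), np.array([5]))


class TestMuap:
    def test_noise_free_sta_recovers_template(self):
        lib = make_template_library(1, rng=3)
        idx = np.arange(2000, 30000, 500)
        spikes = nm.SpikeTrainSet((train(idx),), FS)
        emg = nm.synthesize_emg(spikes, lib, 32000, noise_sd=0.0)
        ln = lib[0].shape[1]
        half_ms = ln / 2 / FS * 1000.0
        tpl = nm.sta_muap(emg, spikes.trains[0], (half_ms, half_ms))
        # align: sta window is centred on the discharge as is the template
        k = (tpl.waveforms.shape[1] - ln) // 2
        assert np.abs(tpl.waveforms[:, k : k + ln] - lib[0]).max() < 1e-9
        assert tpl.n_averaged == idx.size

    def test_boundary_discharges_skipped(self):
        lib = make_template_library(1, rng=3)
        spikes = nm.SpikeTrainSet((train([0, 5000]),), FS)
        emg = nm.synthesize_emg(spikes, lib, 10000, noise_sd=0.0)
        tpl = nm.sta_muap(emg, spikes.trains[0], (25.0, 25.0))
        assert tpl.n_averaged == 1

    def test_residual_noise_scales_as_inverse_sqrt_n(self, rng):
        lib = make_template_library(1, rng=3)
        idx = np.arange(2000, 200000, 400)
        spikes = nm.SpikeTrainSet((train(idx),), FS)
        sigma = 0.2
        emg = nm.synthesize_emg(spikes, lib, 201000, noise_sd=sigma, rng=rng)
        ln = lib[0].shape[1]
        half_ms = ln / 2 / FS * 1000.0
        tpl = nm.sta_muap(emg, spikes.trains[0], (half_ms, half_ms))
        k = (tpl.waveforms.shape[1] - ln) // 2
        resid = tpl.waveforms[:, k : k + ln] - lib[0]
        expected = sigma / np.sqrt(idx.size)
        assert expected / 2 < resid.std() < expected * 2

    def test_no_usable_discharge_rejected(self):
        with pytest.raises(ValueError):
            nm.sta_muap(np.zeros((100, 32)), train([1]), (25.0, 25.0))


class TestMatchMuaps:
    @staticmethod
    def _template(seed):
        lib = make_template_library(1, rng=seed)
        return nm.MuapTemplate(lib[0], FS, 7.5, 7.5, 1)

    def test_self_match_is_unity(self):
        a = self._template(0)
        coef, matched = nm.match_muaps(a, a)
        assert coef == pytest.approx(1.0, abs=1e-12) and matched

    def test_shift_invariance_within_window(self):
        from neuromech.spiketools import _shift_zero_pad

        a = self._template(1)
        shifted = _shift_zero_pad(a.waveforms, 8)
        b = nm.MuapTemplate(shifted, FS, 7.5, 7.5, 1)
        coef, matched = nm.match_muaps(a, b)
        # shift is undone by the search; only the truncated window tail
        # (a few 1e-3 of the energy) keeps the coefficient below 1
        assert coef > 0.99 and matched

    def test_symmetry(self):
        a, b = self._template(2), self._template(3)
        ab, _ = nm.match_muaps(a, b)
        ba, _ = nm.match_muaps(b, a)
        assert abs(ab - ba) < 1e-12

    def test_independent_templates_rarely_match(self):
        low = 0
        for k in range(100):
            lib = make_template_library(2, rng=1000 + k)
            a = nm.MuapTemplate(lib[0], FS, 7.5, 7.5, 1)
            b = nm.MuapTemplate(lib[1], FS, 7.5, 7.5, 1)
            coef, matched = nm.match_muaps(a, b)
            if coef < 0.5:
                low += 1
                assert not matched
        assert low >= 95

    def test_channel_mismatch_rejected(self):
        a = self._template(0)
        b = nm.MuapTemplate(a.waveforms[:16], FS, 7.5, 7.5, 1)
        with pytest.raises(ValueError):
            nm.match_muaps(a, b)
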