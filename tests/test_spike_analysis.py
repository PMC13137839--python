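"""Spike pipeline: state detection, IPIS/center-spike extraction, correlogram
properties, partner classification, spike labeling, SNR, and rates."""

import numpy as np
import pytest

from ipis import spike_analysis as sa
from ipis import synthetic_data as sd


class TestDetectStates:
    def test_recovers_truth_intervals(self, healthy_recording, detected_states):
        j = sd.interval_jaccard(
            detected_states.of_label("I"),
            healthy_recording.truth_states.of_label("I"),
        )
        assert j >= 0.8

    def test_constant_rate_population_fabricates_little_state_time(self):
        # stationary Poisson: the 5th-percentile threshold necessarily sits
        # below some smoothed-rate bins, but fabricated I time stays a small
        # fraction of the recording (vs the ~30% duty cycle of real states)
        rng = np.random.default_rng(0)
        trains = [
            sd.SpikeTrain(f"u{k}", "BNST", np.sort(rng.uniform(0, 60, 480)))
            for k in range(16)
        ]
        states = sa.detect_states_from_spikes(trains, 60.0, low_pct=5.0)
        assert states.total_duration("I") < 6.0

    def test_empty_spike_set_rejected(self):
        trains = [sd.SpikeTrain("a", "BNST", []), sd.SpikeTrain("b", "BNST", [])]
        with pytest.raises(ValueError):
            sa.detect_states_from_spikes(trains, 10.0)

    def test_minimum_duration_respected(self, detected_states):
        assert all(e - s >= 0.1 for s, e, _ in detected_states.intervals)


class TestExtractIpis:
    def test_single_spike_in_interval_is_ipis(self):
        states = sd.StateIntervals(((0.0, 1.0, "E"), (1.0, 1.3, "I")), 2.0)
        train = sd.SpikeTrain("u", "BNST", [0.5, 1.1])
        events = sa.extract_ipis([train], states)
        assert len(events) == 1 and events[0].spike_time_s == 1.1

    def test_count_above_kmax_excluded(self):
        states = sd.StateIntervals(((0.0, 1.0, "E"), (1.0, 1.3, "I")), 2.0)
        train = sd.SpikeTrain("u", "BNST", [1.05, 1.1, 1.2])
        assert sa.extract_ipis([train], states, k_max=2) == []
        assert len(sa.extract_ipis([train], states, k_max=3)) == 3

    def test_ipis_subset_of_i_spikes_and_idempotent(self, healthy_recording):
        rec = healthy_recording
        events = sa.extract_ipis(rec.spikes, rec.truth_states)
        i_mask = rec.truth_states.label_mask(
            np.array([ev.spike_time_s for ev in events]), "I"
        )
        assert i_mask.all()
        # re-extracting from the IPIS-only trains returns the same events
        ipis_trains = [
            sd.SpikeTrain(
                t.unit_id,
                t.region,
                sorted(ev.spike_time_s for ev in events if ev.unit_id == t.unit_id),
            )
            for t in rec.spikes
        ]
        again = sa.extract_ipis(ipis_trains, rec.truth_states)
        assert {(e.unit_id, e.spike_time_s) for e in again} == {
            (e.unit_id, e.spike_time_s) for e in events
        }

    def test_about_one_third_of_units_emit_ipis(self):
        rec = sd.simulate_recording("healthy", duration_s=120.0, seed=3)
        events = sa.extract_ipis(rec.spikes, rec.truth_states)
        per_unit = {t.unit_id: 0 for t in rec.spikes}
        for ev in events:
            per_unit[ev.unit_id] += 1
        frac = np.mean([n / 2.0 >= 1.0 for n in per_unit.values()])  # >=1 per minute
        assert 0.2 <= frac <= 0.55


class TestECenterSpikes:
    def test_tie_breaks_to_earlier_spike(self):
        states = sd.StateIntervals(((0.0, 0.4, "E"),), 1.0)
        train = sd.SpikeTrain("u", "BNST", [0.1, 0.3])
        events = sa.extract_e_center_spikes([train], states)
        assert events[0].spike_time_s == 0.1

    def test_empty_interval_produces_no_event(self):
        states = sd.StateIntervals(((0.0, 0.4, "E"), (0.4, 0.6, "I")), 1.0)
        train = sd.SpikeTrain("u", "BNST", [0.5])
        assert sa.extract_e_center_spikes([train], states) == []

    def test_center_events_outnumber_ipis_when_e_rate_dominates(self, healthy_recording):
        rec = healthy_recording
        centers = sa.extract_e_center_spikes(rec.spikes, rec.truth_states)
        ipis = sa.extract_ipis(rec.spikes, rec.truth_states)
        assert len(centers) > len(ipis)


class TestCorrelogram:
    def test_delta_coupled_train_concentrates_in_one_bin(self):
        ref = np.arange(1.0, 59.0, 1.0)  # widely spaced references
        cg = sa.cross_correlogram(ref, ref + 0.008, n_surr=100, seed=0)
        k = int(np.argmax(cg.counts))
        assert cg.lags_s[k] == pytest.approx(0.0075)  # bin [5, 10) ms
        assert cg.counts[k] == ref.size
        assert cg.counts.sum() == ref.size

    def test_count_conservation(self, rng):
        ref = np.sort(rng.uniform(0, 30, 100))
        target = np.sort(rng.uniform(0, 30, 200))
        cg = sa.cross_correlogram(ref, target, n_surr=10, seed=1)
        brute = sum(
            np.sum((target - r >= -0.2) & (target - r < 0.2)) for r in ref
        )
        assert cg.counts.sum() == brute

    def test_time_reversal_mirror_symmetry(self, rng):
        ref = np.sort(rng.uniform(0, 30, 80))
        target = np.sort(rng.uniform(0, 30, 90))
        a = sa.cross_correlogram(ref, target, n_surr=10, seed=2)
        b = sa.cross_correlogram(target, ref, n_surr=10, seed=2)
        # counts at lag tau equal counts at -tau with roles swapped; the
        # half-open binning shifts exact-boundary pairs by one bin at most
        assert abs(a.counts.sum() - b.counts.sum()) <= 2
        assert np.abs(a.counts - b.counts[::-1]).sum() <= 4

    def test_low_reference_count_flagged(self):
        cg = sa.cross_correlogram(np.array([1.0, 2.0]), np.array([1.5]), n_surr=20, seed=3)
        assert cg.low_n_warning

    def test_lag_zero_counted_in_positive_bin(self):
        ref = np.array([10.0])
        cg = sa.cross_correlogram(ref, np.array([10.0]), n_surr=10, seed=4)
        assert cg.counts[cg.lags_s > 0].sum() == 1
        assert cg.counts[cg.lags_s < 0].sum() == 0


class TestPartnerCells:
    def test_generator_partners_recovered(self, healthy_recording):
        rec = healthy_recording
        pm = sa.classify_partner_cells(
            rec.trains("BNST"), rec.trains("NAc"), rec.truth_states,
            n_surr=200, seed=0,
        )
        truth = {
            (s.unit_id, s.partner_id)
            for s in rec.neuron_specs
            if s.region == "BNST" and s.is_partner
        }
        found = {(b, n) for b, n, _, _ in pm.pairs}
        assert truth <= found
        assert len(found - truth) <= 1
        for (_, _), (w0, w1) in pm.partner_windows.items():
            assert -0.05 <= w0 < w1 <= 0.05

    def test_uncoupled_population_yields_no_partners(self):
        states = sd.simulate_state_sequence(60.0, seed=5)
        specs = sd.default_neuron_specs(coupling_prob=0.0)
        trains = sd.simulate_spikes(states, specs, "healthy", seed=6)
        bnst = [t for t in trains if t.region == "BNST"]
        nac = [t for t in trains if t.region == "NAc"]
        pm = sa.classify_partner_cells(bnst, nac, states, n_surr=200, seed=7)
        assert len(pm.pairs) <= 1  # chance-level false positives at alpha=0.05


class TestClassifySpikes:
    def test_no_nac_spikes_means_all_other(self):
        pm = sa.PartnerMap((("b", "n", 0.008, 0.01),), frozenset(["b"]),
                           {("b", "n"): (0.0, 0.05)})
        bnst = [sd.SpikeTrain("b", "BNST", [1.0, 2.0])]
        nac = [sd.SpikeTrain("n", "NAc", [])]
        labels = sa.classify_spikes(pm, bnst, nac)
        assert not labels["b"].any()

    def test_saturated_pairing_labels_all_partner(self):
        pm = sa.PartnerMap((("b", "n", 0.008, 0.01),), frozenset(["b"]),
                           {("b", "n"): (0.0, 0.05)})
        t = np.arange(1.0, 10.0, 0.5)
        bnst = [sd.SpikeTrain("b", "BNST", t)]
        nac = [sd.SpikeTrain("n", "NAc", t + 0.008)]
        labels = sa.classify_spikes(pm, bnst, nac)
        assert labels["b"].all()

    def test_partner_spike_fraction_tracks_coupling_prob(self, healthy_recording):
        rec = healthy_recording
        pm = sa.classify_partner_cells(
            rec.trains("BNST"), rec.trains("NAc"), rec.truth_states,
            n_surr=200, seed=1,
        )
        labels = sa.classify_spikes(pm, rec.trains("BNST"), rec.trains("NAc"))
        # among partner-unit IPIS spikes the labeled fraction approximates
        # coupling_prob (plus chance coincidences)
        ipis = sa.extract_ipis(
            [rec.train(u) for u in pm.partner_bnst_units], rec.truth_states
        )
        hit = 0
        for ev in ipis:
            t = rec.train(ev.unit_id).times
            k = int(np.searchsorted(t, ev.spike_time_s))
            hit += bool(labels[ev.unit_id][min(k, t.size - 1)])
        frac = hit / len(ipis)
        assert 0.4 <= frac <= 0.85


class TestSpikeSnr:
    def test_all_partner_spikes_give_maximal_snr_everywhere(self):
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(0, 30, 3000))  # 100 Hz Poisson
        trains = [sd.SpikeTrain("b", "BNST", spikes)]
        labels = {"b": np.ones(spikes.size, dtype=bool)}
        events = np.arange(5.0, 25.0, 1.0)
        res = sa.spike_snr(events, trains, labels, 30.0, n_shift=20, seed=0)
        # (rate + eps) / eps with no other spikes: large at every lag
        assert res.snr.min() > 100.0

    def test_zero_events_rejected(self):
        trains = [sd.SpikeTrain("b", "BNST", [1.0])]
        with pytest.raises(ValueError):
            sa.spike_snr([], trains, {"b": np.array([True])}, 10.0)

    def test_healthy_peak_exceeds_control_susceptible_does_not(
        self, healthy_recording, susceptible_recording
    ):
        def peak_vs_band(rec, seed):
            pm = sa.classify_partner_cells(
                rec.trains("BNST"), rec.trains("NAc"), rec.truth_states,
                n_surr=100, seed=seed,
            )
            labels = sa.classify_spikes(pm, rec.trains("BNST"), rec.trains("NAc"))
            ipis = sa.extract_ipis(rec.trains("BNST"), rec.truth_states)
            events = np.sort([ev.spike_time_s for ev in ipis])
            res = sa.spike_snr(events, rec.trains("BNST"), labels,
                               rec.duration_s, n_shift=100, seed=seed)
            mid = np.abs(res.t_s) <= 0.05
            return res.snr[mid].max(), res.control_band[1][mid].max()

        peak_h, band_h = peak_vs_band(healthy_recording, 2)
        peak_s, _ = peak_vs_band(susceptible_recording, 3)
        assert peak_h > band_h
        assert peak_s < 0.1 * peak_h  # peak abolished by hyperactivity


class TestFiringRates:
    def test_rate_arithmetic(self):
        states = sd.StateIntervals(((0.0, 1.0, "E"), (1.0, 3.0, "I")), 4.0)
        train = sd.SpikeTrain("u", "BNST", np.linspace(1.05, 2.95, 10))
        rates = sa.firing_rate_by_state([train], states)["u"]
        assert rates["I"] == pytest.approx(5.0)
        assert rates["E"] == 0.0

    def test_missing_state_yields_nan_not_zero(self):
        states = sd.StateIntervals(((0.0, 1.0, "E"),), 2.0)
        train = sd.SpikeTrain("u", "BNST", [0.5])
        rates = sa.firing_rate_by_state([train], states)["u"]
        assert np.isnan(rates["I"])

    def test_susceptible_elevates_i_not_e(
        self, healthy_recording, susceptible_recording
    ):
        rh = sa.firing_rate_by_state(
            healthy_recording.trains("BNST"), healthy_recording.truth_states
        )
        rs = sa.firing_rate_by_state(
            susceptible_recording.trains("BNST"), susceptible_recording.truth_states
        )
        mean_i_h = np.mean([r["I"] for r in rh.values()])
        mean_i_s = np.mean([r["I"] for r in rs.values()])
        mean_e_h = np.mean([r["E"] for r in rh.values()])
        mean_e_s = np.mean([r["E"] for r in rs.values()])
        assert mean_i_s > 3 * mean_i_h
        assert mean_e_s == pytest.approx(mean_e_h, rel=0.1)
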