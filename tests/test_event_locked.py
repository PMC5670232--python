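"""Event-triggered averaging, exclusion filters, cluster permutation tests."""

import numpy as np
import pandas as pd
import pytest

from recallshift.event_locked import (
    contrast_timecourse,
    extract_event_triggered,
    filter_separated_onsets,
    intrusion_timecourse,
    prompt_timecourse,
    recall_timecourse,
    roi_event_response,
)
from recallshift.hfb import HFBSignal
from recallshift.synthetic import simulate_log_envelope_db

from conftest import (
    RATE,
    add_recall_events,
    db_signal,
    inject_block_shift,
    inject_transients,
    transient_bump,
    two_run_block_events,
)


class TestSeparationFilter:
    def test_well_separated_retained_close_dropped(self):
        kept = filter_separated_onsets(np.array([10.0, 20.0, 23.0, 40.0]))
        assert list(kept) == [10.0, 20.0, 40.0]

    def test_separation_checked_against_all_events(self):
        # an event 3 s after an other-condition recall is still excluded
        kept = filter_separated_onsets(np.array([23.0]),
                                       all_onsets=np.array([20.0, 23.0]))
        assert kept.size == 0


class TestExtractEventTriggered:
    def test_constant_trace_stays_flat(self):
        hfb = db_signal(2, 100.0, seed=0)
        hfb.amplitude[:] = 0.7
        resp = extract_event_triggered(hfb, np.array([20.0, 40.0, 60.0]))
        assert np.allclose(resp.traces, 0.7)
        assert resp.n_events == 3
        assert resp.times[0] == pytest.approx(-5.0)
        assert resp.times[-1] == pytest.approx(7.0, abs=0.02)

    def test_transient_peak_recovered(self):
        """0.17 dB recall-locked plateau recovered to within 0.05 dB."""
        rng = np.random.default_rng(1)
        hfb = db_signal(10, 400.0, seed=2)
        onsets = np.arange(15.0, 390.0, 15.0)  # 25 events
        t = hfb.times()
        for i in range(10):
            for on in onsets:
                hfb.amplitude[i] += transient_bump(t, on, 0.17)
        resp = extract_event_triggered(hfb, onsets)
        grand = resp.traces.mean(axis=0)
        base = grand[(resp.times >= -5) & (resp.times < -3)].mean()
        peak = grand[(resp.times >= -0.4) & (resp.times < 0.9)].mean()
        assert peak - base == pytest.approx(0.17, abs=0.05)

    def test_no_surviving_events_rejected(self):
        hfb = db_signal(1, 30.0, seed=3)
        with pytest.raises(ValueError):
            extract_event_triggered(hfb, np.array([1.0]))  # no window support


class TestContrastTimecourse:
    def _smooth_noise(self, rng, n_el, n_t):
        x = rng.standard_normal((n_el, n_t + 40))
        k = np.ones(20) / 20.0
        return np.stack([np.convolve(row, k, mode="same") for row in x])[:, :n_t]

    def test_null_type_one_error_controlled(self):
        times = np.linspace(-5, 7, 241)
        rng = np.random.default_rng(4)
        hits = 0
        reps = 40
        for _ in range(reps):
            a = self._smooth_noise(rng, 12, times.size)
            b = self._smooth_noise(rng, 12, times.size)
            res = contrast_timecourse(a, b, times, paired=True, n_perm=200,
                                      seed=int(rng.integers(2**31)))
            hits += bool(res.significant(0.05))
        assert hits / reps <= 0.15  # loose bound at this rep count

    def test_injected_transient_cluster_onset(self):
        times = np.linspace(-5, 7, 601)
        rng = np.random.default_rng(5)
        effect = np.where((times >= -1.5) & (times < 2.0), 1.0, 0.0)
        a = self._smooth_noise(rng, 14, times.size) * 0.3 + effect
        b = self._smooth_noise(rng, 14, times.size) * 0.3
        res = contrast_timecourse(a, b, times, paired=True, n_perm=500, seed=0)
        sig = res.significant(0.05)
        assert sig
        onset = min(c.start_s for c in sig)
        assert onset == pytest.approx(-1.5, abs=0.3)

    def test_sign_symmetry_of_observed_mass(self):
        times = np.linspace(0, 1, 100)
        rng = np.random.default_rng(6)
        a = rng.standard_normal((8, 100))
        b = rng.standard_normal((8, 100))
        r1 = contrast_timecourse(a, b, times, paired=True, n_perm=100, seed=1)
        r2 = contrast_timecourse(b, a, times, paired=True, n_perm=100, seed=1)
        m1 = sorted(c.mass for c in r1.clusters)
        m2 = sorted(c.mass for c in r2.clusters)
        assert np.allclose(m1, m2)

    def test_parameter_validation(self):
        times = np.linspace(0, 1, 50)
        x = np.zeros((8, 50))
        with pytest.raises(ValueError):
            contrast_timecourse(x, x, times, n_perm=10)
        with pytest.raises(ValueError):
            contrast_timecourse(x[:3], x[:3], times, n_perm=200)


class TestRecallTimecourse:
    def test_differential_transient_detected(self):
        rng = np.random.default_rng(7)
        events = add_recall_events(two_run_block_events(), rng, n_per_block=8)
        hfb = db_signal(12, 600.0, seed=8)
        pref = {cid: ("face" if i % 2 == 0 else "place")
                for i, cid in enumerate(hfb.channel_ids)}
        inject_transients(hfb, events, {cid: 0.8 for cid in hfb.channel_ids},
                          preferred=pref)
        res, _ = recall_timecourse(hfb, events, pref, n_perm=300, seed=0)
        assert res.significant(0.05)

    def test_no_selective_electrodes_rejected(self):
        rng = np.random.default_rng(9)
        events = add_recall_events(two_run_block_events(), rng)
        hfb = db_signal(4, 600.0, seed=10)
        with pytest.raises(ValueError):
            recall_timecourse(hfb, events, {}, n_perm=300)


class TestIntrusionTimecourse:
    def _intrusion_setup(self, collapse, seed=11):
        rng = np.random.default_rng(seed)
        events = add_recall_events(two_run_block_events(), rng,
                                   n_per_block=9, intrusion_every=3)
        hfb = db_signal(14, 600.0, seed=seed + 1)
        pref = {cid: ("face" if i % 2 == 0 else "place")
                for i, cid in enumerate(hfb.channel_ids)}
        shifts = {cid: {pref[cid]: 1.0} for cid in hfb.channel_ids}
        inject_block_shift(hfb, events, shifts)
        if collapse:
            t = hfb.times()
            intr = events[(events["event_type"] == "recall")
                          & (events["is_intrusion"] == 1)]
            for cid in hfb.channel_ids:
                i = hfb.channel_ids.index(cid)
                for _, ev in intr.iterrows():
                    if ev["target_category"] != pref[cid]:
                        continue
                    on, off = ev["onset"], ev["onset"] + ev["duration"]
                    sel = (t >= on - 2.0) & (t < off)
                    hfb.amplitude[i, sel] -= 1.0  # shift collapses pre-intrusion
        return hfb, events, pref

    def test_collapse_limits_cluster_to_pre_intrusion(self):
        hfb, events, pref = self._intrusion_setup(collapse=True)
        res, _, _ = intrusion_timecourse(hfb, events, pref, n_perm=300, seed=0)
        sig = res.significant(0.05)
        assert sig
        # the steady-state preferred>non-preferred cluster ends ~2 s before
        # the intrusion onset, and none survives inside the collapse window
        assert any(c.end_s <= -1.5 for c in sig)
        assert not any(c.start_s < 2.0 and c.end_s > -1.0 for c in sig)

    def test_persistent_shift_cluster_through_onset(self):
        hfb, events, pref = self._intrusion_setup(collapse=False, seed=21)
        res, _, _ = intrusion_timecourse(hfb, events, pref, n_perm=300, seed=0)
        sig = res.significant(0.05)
        assert any(c.start_s < 0 < c.end_s for c in sig)

    def test_no_intrusions_rejected(self):
        rng = np.random.default_rng(12)
        events = add_recall_events(two_run_block_events(), rng, intrusion_every=0)
        hfb = db_signal(6, 600.0, seed=13)
        with pytest.raises(ValueError):
            intrusion_timecourse(hfb, events, {c: "face" for c in hfb.channel_ids},
                                 n_perm=300)


class TestPromptTimecourse:
    def _prompt_events(self):
        events = two_run_block_events()
        rows = []
        for _, blk in events[events["event_type"] == "recall_block"].iterrows():
            on = blk["onset"] + 60.0
            rows.append(dict(onset=on, duration=2.0, event_type="prompt",
                             item_id="", category="",
                             target_category=blk["target_category"],
                             is_intrusion=0, run=blk["run"]))
        return pd.concat([events, pd.DataFrame(rows)], ignore_index=True)

    def test_close_following_recall_excludes_prompt(self):
        events = self._prompt_events()
        rec = pd.DataFrame([dict(onset=events[events.event_type == "prompt"]
                                 .iloc[0]["onset"] + 4.0, duration=2.0,
                                 event_type="recall", item_id="face01",
                                 category="face", target_category="face",
                                 is_intrusion=0, run=0)])
        events2 = pd.concat([events, rec], ignore_index=True)
        hfb = db_signal(8, 600.0, seed=14)
        pref = {cid: ("face" if i % 2 == 0 else "place")
                for i, cid in enumerate(hfb.channel_ids)}
        _, traces, _ = prompt_timecourse(hfb, events2, pref, n_perm=300, seed=0)
        # the face-block prompt in run 0 was dropped: the preferred condition
        # for face electrodes uses only the remaining face prompt
        assert traces["preferred"].shape[0] == 8

    def test_post_prompt_recovery_detected_for_preferred(self):
        events = self._prompt_events()
        hfb = db_signal(12, 600.0, seed=15)
        pref = {cid: ("face" if i % 2 == 0 else "place")
                for i, cid in enumerate(hfb.channel_ids)}
        t = hfb.times()
        prompts = events[events["event_type"] == "prompt"]
        for i, cid in enumerate(hfb.channel_ids):
            for _, ev in prompts.iterrows():
                if ev["target_category"] != pref[cid]:
                    continue
                off = ev["onset"] + ev["duration"]
                sel = (t >= off) & (t < off + 4.0)
                hfb.amplitude[i, sel] += 1.2  # recovery after prompt offset
        res, _, times = prompt_timecourse(hfb, events, pref, n_perm=300, seed=0)
        sig = res.significant(0.05)
        assert sig
        assert any(c.start_s >= 1.5 for c in sig)  # post-offset (2 s prompts)

    def test_flat_signal_no_clusters(self):
        events = self._prompt_events()
        hfb = db_signal(8, 600.0, seed=16)
        hfb.amplitude[:] = 0.0
        pref = {cid: ("face" if i % 2 == 0 else "place")
                for i, cid in enumerate(hfb.channel_ids)}
        res, _, _ = prompt_timecourse(hfb, events, pref, n_perm=300, seed=0)
        assert not res.clusters

    def test_no_prompts_rejected(self):
        events = two_run_block_events()
        hfb = db_signal(6, 600.0, seed=17)
        with pytest.raises(ValueError):
            prompt_timecourse(hfb, events, {c: "face" for c in hfb.channel_ids},
                              n_perm=300)


class TestRoiEventResponse:
    def test_lagged_transient_measured(self):
        rng = np.random.default_rng(18)
        events = add_recall_events(two_run_block_events(), rng, n_per_block=8)
        hfb = db_signal(8, 600.0, seed=19)
        visual = hfb.channel_ids[:4]
        frontal = hfb.channel_ids[4:]
        inject_transients(hfb, events, {cid: 1.0 for cid in visual})
        inject_transients(hfb, events, {cid: 1.0 for cid in frontal}, lag=0.6)
        traces, bins, times = roi_event_response(
            hfb, events, {"visual": visual, "frontal": frontal})
        # response onset = first half-maximum crossing (the plateau top is
        # flat, so argmax would land anywhere inside it)
        onset_vis = times[np.flatnonzero(traces["visual"] > 0.5)[0]]
        onset_fr = times[np.flatnonzero(traces["frontal"] > 0.5)[0]]
        assert onset_fr - onset_vis >= 0.5 - 0.2
        assert (bins["transient_bin"] > bins["baseline_bin"]).all()

    def test_baseline_window_mean_is_zero_db(self):
        rng = np.random.default_rng(20)
        events = add_recall_events(two_run_block_events(), rng)
        hfb = db_signal(4, 600.0, seed=21)
        traces, bins, times = roi_event_response(
            hfb, events, {"roi": hfb.channel_ids})
        assert np.allclose(bins["baseline_bin"], 0.0, atol=1e-9)

    def test_empty_roi_rejected(self):
        rng = np.random.default_rng(22)
        events = add_recall_events(two_run_block_events(), rng)
        hfb = db_signal(2, 600.0, seed=23)
        with pytest.raises(ValueError):
            roi_event_response(hfb, events, {"roi": ["missing"]})
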