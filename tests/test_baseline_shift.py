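"""Median recall amplitude, percentile-gain statistic, dynamics models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recallshift.baseline_shift import (
    DynamicsModelSpec,
    classify_dynamics,
    csi_shift_correlation,
    median_recall_amplitude,
    percentile_gain_profile,
    recall_order_analysis,
    recall_order_effect,
    selectivity_db,
    simulate_dynamics_model,
    stage_gain,
)
from recallshift.synthetic import simulate_log_envelope_db

from conftest import (
    RATE,
    add_recall_events,
    db_signal,
    inject_block_shift,
    inject_transients,
    two_run_block_events,
)


def test_median_db_commutes_with_log():
    rng = np.random.default_rng(0)
    x = np.exp(rng.standard_normal(10001) * 0.4)
    assert np.median(10 * np.log10(x)) == pytest.approx(
        10 * np.log10(np.median(x)), abs=1e-12)


class TestMedianRecallAmplitude:
    def _cohort(self, shift_face, shift_place=0.0, n_el=20, seed=0):
        events = two_run_block_events()
        hfb = db_signal(n_el, 600.0, seed=seed)
        shifts = {cid: {"face": shift_face, "place": shift_place}
                  for cid in hfb.channel_ids}
        inject_block_shift(hfb, events, shifts)
        return hfb, events

    def test_injected_shift_recovered(self):
        hfb, events = self._cohort(0.5)
        med = median_recall_amplitude(hfb, events)
        assert med["face_minus_place_db"].mean() == pytest.approx(0.5, abs=0.1)

    def test_null_cohort_near_zero(self):
        hfb, events = self._cohort(0.0)
        med = median_recall_amplitude(hfb, events)
        assert abs(med["face_minus_place_db"].mean()) < 0.1

    def test_shift_survives_recall_exclusion(self):
        rng = np.random.default_rng(1)
        events = add_recall_events(two_run_block_events(), rng, n_per_block=8)
        hfb = db_signal(20, 600.0, seed=2)
        inject_block_shift(hfb, events, {cid: {"face": 0.4} for cid in hfb.channel_ids})
        med = median_recall_amplitude(hfb, events)
        med_ex = median_recall_amplitude(hfb, events, exclude_recalls=True)
        a = med["face_minus_place_db"].mean()
        b = med_ex["face_minus_place_db"].mean()
        assert abs(a - b) < 0.05
        assert b == pytest.approx(0.4, abs=0.1)

    def test_transient_only_signal_removed_by_exclusion(self):
        rng = np.random.default_rng(3)
        events = add_recall_events(two_run_block_events(), rng, n_per_block=10)
        hfb = db_signal(20, 600.0, seed=4)
        pref = {cid: "face" for cid in hfb.channel_ids}
        inject_transients(hfb, events, {cid: 1.5 for cid in hfb.channel_ids},
                          preferred=pref)
        med_ex = median_recall_amplitude(hfb, events, exclude_recalls=True)
        sel_ex = selectivity_db(med_ex, pref)
        med = median_recall_amplitude(hfb, events)
        sel = selectivity_db(med, pref)
        assert sel.mean() > 0.08  # transients leak into the plain median
        assert abs(sel_ex.mean()) < 0.05  # but are removed by the exclusion

    def test_empty_block_after_exclusion_rejected(self):
        events = two_run_block_events(block_s=4.0)
        rec = pd.DataFrame([dict(onset=2.0 + k * 4.0, duration=4.0,
                                 event_type="recall", item_id="face01",
                                 category="face", target_category="face",
                                 is_intrusion=0, run=0) for k in range(4)])
        events = pd.concat([events, rec], ignore_index=True)
        hfb = db_signal(2, 20.0, seed=5)
        with pytest.raises(ValueError):
            median_recall_amplitude(hfb, events, exclude_recalls=True)


class TestStageGain:
    def test_constant_shift_equal_stages(self):
        events = two_run_block_events()
        hfb = db_signal(15, 600.0, seed=6)
        pref = {cid: "face" for cid in hfb.channel_ids}
        inject_block_shift(hfb, events, {cid: {"face": 0.4} for cid in hfb.channel_ids})
        g = stage_gain(hfb, events, pref)
        means = [g[s].mean() for s in ("early", "middle", "late")]
        assert np.allclose(means, 0.4, atol=0.1)

    def test_shift_confined_to_early_stage(self):
        events = two_run_block_events()
        hfb = db_signal(15, 600.0, seed=7)
        pref = {cid: "face" for cid in hfb.channel_ids}
        t = hfb.times()
        blocks = events[events["event_type"] == "recall_block"]
        for _, blk in blocks.iterrows():
            if blk["target_category"] != "face":
                continue
            sel = (t >= blk["onset"]) & (t < blk["onset"] + 50.0)
            hfb.amplitude[:, sel] += 0.5
        g = stage_gain(hfb, events, pref)
        assert g["early"].mean() == pytest.approx(0.5, abs=0.12)
        assert abs(g["middle"].mean()) < 0.1
        assert abs(g["late"].mean()) < 0.1

    def test_truncated_block_rejected(self):
        events = two_run_block_events(block_s=100.0)
        hfb = db_signal(2, 400.0, seed=8)
        with pytest.raises(ValueError):
            stage_gain(hfb, events, {})


class TestCsiShiftCorrelation:
    def test_constructed_correlation_recovered(self):
        rng = np.random.default_rng(9)
        n_el = 30
        csi_true = rng.uniform(-1, 1, n_el)
        events = two_run_block_events()
        hfb = db_signal(n_el, 600.0, seed=10)
        shifts = {cid: {"face": max(0.6 * c, 0.0), "place": max(-0.6 * c, 0.0)}
                  for cid, c in zip(hfb.channel_ids, csi_true)}
        inject_block_shift(hfb, events, shifts)
        med = median_recall_amplitude(hfb, events)
        profiles = pd.DataFrame(dict(electrode_id=hfb.channel_ids, csi=csi_true))
        rho, p = csi_shift_correlation(profiles, med)
        assert rho >= 0.8
        assert p < 1e-4

    def test_independent_shift_uncorrelated(self):
        rng = np.random.default_rng(11)
        rhos = []
        for rep in range(10):
            n_el = 20
            profiles = pd.DataFrame(dict(
                electrode_id=[f"E{i + 1:02d}" for i in range(n_el)],
                csi=rng.uniform(-1, 1, n_el)))
            med = pd.DataFrame(dict(
                electrode_id=profiles["electrode_id"],
                face_minus_place_db=rng.standard_normal(n_el) * 0.2))
            rho, _ = csi_shift_correlation(profiles, med)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.2

    def test_too_few_electrodes_rejected(self):
        profiles = pd.DataFrame(dict(electrode_id=["a", "b"], csi=[0.1, 0.5]))
        med = pd.DataFrame(dict(electrode_id=["a", "b"],
                                face_minus_place_db=[0.0, 0.1]))
        with pytest.raises(ValueError):
            csi_shift_correlation(profiles, med)


class TestDynamicsModels:
    def test_full_coverage_shift_is_exact_offset(self):
        base = simulate_log_envelope_db(150.0, RATE, seed=0)
        spec = DynamicsModelSpec(kind="shift", gain_db=0.1, coverage=1.0)
        out = simulate_dynamics_model(base, spec, RATE, np.random.default_rng(0))
        assert np.array_equal(out, base + 0.1)

    def test_partial_coverage_touches_right_fraction(self):
        base = np.zeros(10_000)
        spec = DynamicsModelSpec(kind="shift", gain_db=0.1, coverage=0.8)
        out = simulate_dynamics_model(base, spec, RATE, np.random.default_rng(1))
        assert (out > 0).mean() == pytest.approx(0.8, abs=1e-9)

    def test_burst_mean_matches_occupancy_times_amplitude(self):
        # unit-area smoothing preserves the added mean: occupancy x burst dB
        base = np.zeros(int(600 * RATE))
        spec = DynamicsModelSpec(kind="burst", burst_db=2.0, occupancy=0.3,
                                 window_s=3.0)
        out = simulate_dynamics_model(base, spec, RATE, np.random.default_rng(2))
        assert out.mean() == pytest.approx(0.3 * 2.0, rel=0.02)
        assert out.max() == pytest.approx(2.0, rel=0.1)

    def test_zero_occupancy_is_identity(self):
        base = simulate_log_envelope_db(60.0, RATE, seed=3)
        spec = DynamicsModelSpec(kind="burst", burst_db=2.0, occupancy=1e-6)
        out = simulate_dynamics_model(base, spec, RATE, np.random.default_rng(3))
        assert np.allclose(out, base)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DynamicsModelSpec(kind="spike")
        with pytest.raises(ValueError):
            DynamicsModelSpec(kind="burst", occupancy=0.0)
        with pytest.raises(ValueError):
            DynamicsModelSpec(kind="shift", coverage=1.5)


class TestPercentileGain:
    @settings(max_examples=25, derandomize=True)
    @given(offset=st.floats(-2.0, 2.0), seed=st.integers(0, 100))
    def test_constant_offset_in_every_bin(self, offset, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(2000)
        prof = percentile_gain_profile(x + offset, x)
        assert np.allclose(prof.gains_db, offset, atol=1e-9)

    def test_identical_traces_zero_gain(self):
        x = np.random.default_rng(4).standard_normal(1000)
        assert np.allclose(percentile_gain_profile(x, x).gains_db, 0.0)

    def test_burst_gain_concentrates_in_top_bins(self):
        rng = np.random.default_rng(5)
        spec = DynamicsModelSpec(kind="burst", burst_db=2.0, occupancy=0.3)
        top, bottom = [], []
        for _ in range(10):
            base = simulate_log_envelope_db(150.0, RATE, rng=rng)
            mod = simulate_dynamics_model(base, spec, RATE, rng)
            prof = percentile_gain_profile(mod, base)
            top.append(prof.gains_db[-1])
            bottom.append(prof.gains_db[0])
        assert np.mean(top) > np.mean(bottom) + 0.5

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            percentile_gain_profile(np.zeros(50), np.zeros(50), n_bins=10)


class TestClassifyDynamics:
    def _cohort_label(self, kind, seed, n_el=30):
        rng = np.random.default_rng(seed)
        spec = (DynamicsModelSpec(kind="shift", gain_db=0.1, coverage=1.0)
                if kind == "shift"
                else DynamicsModelSpec(kind="burst", burst_db=2.0, occupancy=0.2))
        profs = []
        for _ in range(n_el):
            base = simulate_log_envelope_db(150.0, RATE, rng=rng)
            other = simulate_log_envelope_db(150.0, RATE, rng=rng)
            mod = simulate_dynamics_model(other, spec, RATE, rng=rng)
            profs.append(percentile_gain_profile(mod, base))
        return classify_dynamics(profs).label

    def test_shift_cohorts_labeled_shift(self):
        labels = [self._cohort_label("shift", s) for s in range(5)]
        assert labels.count("baseline_shift_like") >= 4

    def test_burst_cohorts_labeled_burst(self):
        labels = [self._cohort_label("burst", s) for s in range(5)]
        assert labels.count("burst_like") >= 4

    def test_pure_noise_rarely_significant(self):
        rng = np.random.default_rng(6)
        outcomes = []
        for _ in range(10):
            profs = []
            for _ in range(30):
                a = simulate_log_envelope_db(150.0, RATE, rng=rng)
                b = simulate_log_envelope_db(150.0, RATE, rng=rng)
                profs.append(percentile_gain_profile(a, b))
            res = classify_dynamics(profs)
            outcomes.append(res.label == "indeterminate" or res.overall_p >= 0.05)
        assert np.mean(outcomes) >= 0.8

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamics(np.zeros((5, 10)))


class TestRecallOrder:
    def _ratio_cohort(self, order_db, n_el=100, seed=12):
        """Rest-ratio traces with an extra gain when a category is targeted
        second within its run. A large low-noise cohort keeps the sampling
        error of the mean order effect well below the 0.02 dB tolerance."""
        from recallshift.hfb import HFBSignal

        events = two_run_block_events()
        rng = np.random.default_rng(seed)
        traces = []
        blocks = events[events["event_type"] == "recall_block"]
        n = int(600.0 * RATE)
        t = np.arange(n) / RATE
        for _ in range(n_el):
            db = simulate_log_envelope_db(600.0, RATE, sigma=0.1, rng=rng)
            for run in (0, 1):
                rb = blocks[blocks["run"] == run].sort_values("onset")
                second = rb.iloc[1]
                sel = (t >= second["onset"]) & (t < second["onset"] + second["duration"])
                db[sel] += order_db
            traces.append(10 ** (db / 10.0))
        return HFBSignal(np.stack(traces), RATE,
                         [f"E{i + 1:02d}" for i in range(n_el)],
                         state="rest_ratio"), events

    def test_order_effect_recovered(self):
        hfb, events = self._ratio_cohort(0.04)
        table = recall_order_analysis(hfb, events, {})
        assert recall_order_effect(table) == pytest.approx(0.04, abs=0.02)

    def test_null_order_effect(self):
        hfb, events = self._ratio_cohort(0.0, seed=13)
        table = recall_order_analysis(hfb, events, {})
        assert abs(recall_order_effect(table)) < 0.02

    def test_shuffled_order_labels_destroy_effect(self):
        hfb, events = self._ratio_cohort(0.2, seed=14)
        table = recall_order_analysis(hfb, events, {})
        rng = np.random.default_rng(15)
        table["order"] = rng.permutation(table["order"].to_numpy())
        assert abs(recall_order_effect(table)) < abs(0.2) / 3

    def test_single_run_rejected(self):
        from recallshift.hfb import HFBSignal

        events = two_run_block_events()
        events = events[events["run"] == 0]
        hfb = HFBSignal(np.ones((2, int(300 * RATE))), RATE, ["a", "b"],
                        state="rest_ratio")
        with pytest.raises(ValueError):
            recall_order_analysis(hfb, events, {})
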