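"""Recall-onset, intrusion, and prompt time-locked analyses.

Event-triggered HFB responses are computed on the rest-normalized dB trace,
smoothed with a 1000 ms triangular window (to absorb latency uncertainty of
the underlying neuronal events relative to speech onset), epoched from -5 to
+7 s around each event, and averaged within electrode per condition. Recall
events closer than 5 s to the previous recollection are excluded.

Condition contrasts run a time-point-by-time-point t-test across electrodes
with cluster-based multiple-comparisons correction: clusters are maximal
supra-threshold runs scored by the sum of |t| (cluster mass), compared to a
Monte-Carlo null built by shuffling condition labels over electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .hfb import HFBSignal, smooth_triangular


@dataclass
class EventTriggeredResponse:
    """Per-electrode mean event-locked traces for one condition."""

    times: np.ndarray
    traces: np.ndarray  # (n_electrodes, n_times)
    channel_ids: list[str]
    n_events: int
    n_excluded: int
    smoothing_ms: float
    baseline_window: tuple[float, float] | None = None


@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p_corrected: float


@dataclass
class ClusterTestResult:
    times: np.ndarray
    t_trace: np.ndarray
    clusters: list[Cluster]
    threshold_p: float
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < alpha]


# ---------------------------------------------------------------------------
# Event-triggered extraction
# ---------------------------------------------------------------------------


def filter_separated_onsets(onsets: np.ndarray, all_onsets: np.ndarray | None = None,
                            min_separation_s: float = 5.0) -> np.ndarray:
    """Keep onsets separated by at least min_separation_s from the previous
    recollection (checked against ``all_onsets`` when given, so events of
    other conditions also enforce the gap)."""
    onsets = np.sort(np.asarray(onsets, float))
    ref = np.sort(np.asarray(all_onsets, float)) if all_onsets is not None else onsets
    keep = []
    for on in onsets:
        prev = ref[ref < on]
        if prev.size == 0 or on - prev[-1] >= min_separation_s:
            keep.append(on)
    return np.asarray(keep)


def extract_event_triggered(
    hfb: HFBSignal,
    onsets: np.ndarray,
    window: tuple[float, float] = (-5.0, 7.0),
    smoothing_ms: float = 1000.0,
    min_separation_s: float = 5.0,
    all_onsets: np.ndarray | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> EventTriggeredResponse:
    """Smoothed event-triggered average per electrode.

    With ``baseline_window`` each epoch is first normalized by its own mean
    over that pre-event window (subtraction in dB, division in ratio state).
    """
    if hfb.state not in ("db", "rest_ratio"):
        raise ValueError("expects a rest-normalized trace")
    rate = hfb.rate
    n = hfb.n_samples
    kept = filter_separated_onsets(onsets, all_onsets, min_separation_s)
    n_excluded = len(onsets) - len(kept)
    i0 = int(round(window[0] * rate))
    i1 = int(round(window[1] * rate)) + 1
    idx = np.floor(kept * rate).astype(int)
    idx = idx[(idx + i0 >= 0) & (idx + i1 <= n)]
    if idx.size == 0:
        raise ValueError("no surviving events with full window support")

    smoothed = smooth_triangular(hfb.amplitude, smoothing_ms, rate)
    n_t = i1 - i0
    acc = np.zeros((hfb.amplitude.shape[0], n_t))
    for oi in idx:
        ep = smoothed[:, oi + i0 : oi + i1]
        if baseline_window is not None:
            b0 = int(round((baseline_window[0] - window[0]) * rate))
            b1 = int(round((baseline_window[1] - window[0]) * rate))
            base = ep[:, b0:b1].mean(axis=1, keepdims=True)
            ep = ep - base if hfb.state == "db" else ep / base
        acc += ep
    traces = acc / idx.size
    times = np.arange(i0, i1) / rate
    return EventTriggeredResponse(
        times=times, traces=traces, channel_ids=list(hfb.channel_ids),
        n_events=int(idx.size), n_excluded=int(n_excluded),
        smoothing_ms=smoothing_ms, baseline_window=baseline_window)


# ---------------------------------------------------------------------------
# Cluster-based permutation testing
# ---------------------------------------------------------------------------


def _clusters_from_stats(tvals: np.ndarray, crit: float) -> list[tuple[int, int, float]]:
    """Maximal runs of |t| > crit, scored by sum of |t| (cluster mass)."""
    supra = np.abs(tvals) > crit
    if not supra.any():
        return []
    x = np.concatenate([[False], supra, [False]])
    edges = np.flatnonzero(np.diff(x.astype(int)))
    out = []
    for s, e in zip(edges[::2], edges[1::2]):
        out.append((int(s), int(e), float(np.abs(tvals[s:e]).sum())))
    return out


def _max_cluster_mass(tmat: np.ndarray, crit: float) -> np.ndarray:
    """Maximum cluster mass per row of a (n_perm, n_times) t matrix."""
    out = np.zeros(tmat.shape[0])
    for i, row in enumerate(tmat):
        cl = _clusters_from_stats(row, crit)
        if cl:
            out[i] = max(m for _, _, m in cl)
    return out


def _paired_t(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    mu = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mu / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp * (1.0 / na + 1.0 / nb))
    return np.where(np.isfinite(t), t, 0.0)


def contrast_timecourse(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    times: np.ndarray,
    paired: bool = True,
    threshold_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-corrected condition contrast across electrodes.

    responses_a/b are (n_electrodes, n_times) per-electrode condition means.
    Paired contrasts permute by flipping condition labels within electrode
    (sign flips of the difference); unpaired contrasts reassign electrodes
    to groups. The corrected p of each observed cluster is the fraction of
    permutation maximum cluster masses at least as large.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    a = np.atleast_2d(np.asarray(responses_a, float))
    b = np.atleast_2d(np.asarray(responses_b, float))
    rng = np.random.default_rng(seed)

    if paired:
        if a.shape != b.shape:
            raise ValueError("paired contrast needs matching shapes")
        n = a.shape[0]
        if n < 5:
            raise ValueError("need at least 5 electrodes")
        d = a - b
        crit = sps.t.ppf(1.0 - threshold_p / 2.0, df=n - 1)
        t_obs = _paired_t(d)
        # sign-flip null; Var is invariant under flips, only the mean moves
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        mu = signs @ d / n
        ssq = (d**2).sum(axis=0)
        var = (ssq - n * mu**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mu / np.sqrt(var / n)
        t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
    else:
        na, nb = a.shape[0], b.shape[0]
        if na + nb < 5:
            raise ValueError("need at least 5 electrodes")
        crit = sps.t.ppf(1.0 - threshold_p / 2.0, df=na + nb - 2)
        t_obs = _two_sample_t(a, b)
        pooled = np.vstack([a, b])
        t_perm = np.empty((n_perm, a.shape[1]))
        order = np.arange(na + nb)
        for i in range(n_perm):
            perm = rng.permutation(order)
            t_perm[i] = _two_sample_t(pooled[perm[:na]], pooled[perm[na:]])

    null_max = _max_cluster_mass(t_perm, crit)
    clusters = []
    for s, e, mass in _clusters_from_stats(t_obs, crit):
        p = float((null_max >= mass).mean())
        clusters.append(Cluster(start_s=float(times[s]), end_s=float(times[e - 1]),
                                mass=mass, p_corrected=p))
    return ClusterTestResult(times=np.asarray(times, float), t_trace=t_obs,
                             clusters=clusters, threshold_p=threshold_p,
                             n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Task-specific analyses
# ---------------------------------------------------------------------------


def _recall_events(events: pd.DataFrame) -> pd.DataFrame:
    rec = events[events["event_type"] == "recall"].sort_values("onset")
    if rec.empty:
        raise ValueError("no recall events")
    return rec


def recall_timecourse(
    hfb: HFBSignal,
    events: pd.DataFrame,
    preferred: pd.Series | dict,
    n_perm: int = 10_000,
    seed: int = 0,
    window: tuple[float, float] = (-5.0, 7.0),
) -> tuple[ClusterTestResult, dict[str, EventTriggeredResponse]]:
    """Preferred vs non-preferred recall-onset contrast (paired, clustered).

    For each category-selective electrode, correct (non-intrusion) recall
    events of the electrode's preferred category form condition A and the
    other category condition B; the paired contrast tests the differential
    transient around speech onset.
    """
    pref = dict(preferred)
    rec = _recall_events(events)
    correct = rec[rec["is_intrusion"] == 0]
    all_onsets = rec["onset"].to_numpy(float)
    sel_ids = [cid for cid in hfb.channel_ids if pref.get(cid) in ("face", "place")]
    if not sel_ids:
        raise ValueError("no category-selective electrodes")

    traces_a, traces_b = [], []
    times = None
    resp_by_cat = {}
    for cat in ("face", "place"):
        onsets = correct[correct["category"] == cat]["onset"].to_numpy(float)
        resp_by_cat[cat] = extract_event_triggered(
            hfb, onsets, window=window, all_onsets=all_onsets)
        times = resp_by_cat[cat].times
    for cid in sel_ids:
        i = hfb.channel_ids.index(cid)
        p = pref[cid]
        q = "place" if p == "face" else "face"
        traces_a.append(resp_by_cat[p].traces[i])
        traces_b.append(resp_by_cat[q].traces[i])
    result = contrast_timecourse(np.array(traces_a), np.array(traces_b), times,
                                 paired=True, n_perm=n_perm, seed=seed)
    return result, resp_by_cat


def intrusion_timecourse(
    hfb: HFBSignal,
    events: pd.DataFrame,
    preferred: pd.Series | dict,
    n_perm: int = 10_000,
    seed: int = 0,
    window: tuple[float, float] = (-5.0, 7.0),
) -> tuple[ClusterTestResult, dict[str, np.ndarray], np.ndarray]:
    """Intrusion-locked contrast: preferred-targeted vs non-preferred-targeted.

    Intrusions occurring while an electrode's preferred category was the
    block target form one condition; intrusions during the other block form
    the second. Conditions need not co-occur within an electrode, so the
    contrast is a two-sample test across electrode-condition means.
    """
    pref = dict(preferred)
    rec = _recall_events(events)
    intr = rec[rec["is_intrusion"] == 1]
    if intr.empty:
        raise ValueError("no intrusion events")
    all_onsets = rec["onset"].to_numpy(float)

    cond_traces: dict[str, list[np.ndarray]] = {"preferred": [], "non_preferred": []}
    times = None
    by_target = {}
    for target in ("face", "place"):
        onsets = intr[intr["target_category"] == target]["onset"].to_numpy(float)
        if onsets.size == 0:
            continue
        by_target[target] = extract_event_triggered(
            hfb, onsets, window=window, all_onsets=all_onsets)
        times = by_target[target].times
    for cid in hfb.channel_ids:
        p = pref.get(cid)
        if p not in ("face", "place"):
            continue
        i = hfb.channel_ids.index(cid)
        if p in by_target:
            cond_traces["preferred"].append(by_target[p].traces[i])
        q = "place" if p == "face" else "face"
        if q in by_target:
            cond_traces["non_preferred"].append(by_target[q].traces[i])
    if not cond_traces["preferred"] or not cond_traces["non_preferred"]:
        raise ValueError("intrusions missing in one condition")
    a = np.array(cond_traces["preferred"])
    b = np.array(cond_traces["non_preferred"])
    result = contrast_timecourse(a, b, times, paired=False, n_perm=n_perm, seed=seed)
    return result, {"preferred": a, "non_preferred": b}, times


def prompt_timecourse(
    hfb: HFBSignal,
    events: pd.DataFrame,
    preferred: pd.Series | dict,
    min_gap_to_next_recall_s: float = 7.0,
    n_perm: int = 10_000,
    seed: int = 0,
    window: tuple[float, float] = (-5.0, 7.0),
    baseline_window: tuple[float, float] = (-5.0, -1.0),
) -> tuple[ClusterTestResult, dict[str, np.ndarray], np.ndarray]:
    """Prompt-locked contrast: preferred-category vs other-category prompts.

    Epochs are normalized by the pre-prompt baseline (-5 to -1 s); prompts
    followed by a recall event within ``min_gap_to_next_recall_s`` are
    excluded. Two-sample across electrode-condition means.
    """
    pref = dict(preferred)
    prompts = events[events["event_type"] == "prompt"].sort_values("onset")
    if prompts.empty:
        raise ValueError("no prompts")
    rec_onsets = np.sort(_recall_events(events)["onset"].to_numpy(float)) \
        if (events["event_type"] == "recall").any() else np.array([])

    eligible = []
    for _, ev in prompts.iterrows():
        nxt = rec_onsets[rec_onsets > ev["onset"]]
        if nxt.size == 0 or nxt[0] - ev["onset"] >= min_gap_to_next_recall_s:
            eligible.append(ev)
    if not eligible:
        raise ValueError("no eligible prompts")
    eligible = pd.DataFrame(eligible)

    by_cat = {}
    times = None
    for cat in ("face", "place"):
        onsets = eligible[eligible["target_category"] == cat]["onset"].to_numpy(float)
        if onsets.size == 0:
            continue
        by_cat[cat] = extract_event_triggered(
            hfb, onsets, window=window, min_separation_s=0.0,
            baseline_window=baseline_window)
        times = by_cat[cat].times
    a_list, b_list = [], []
    for cid in hfb.channel_ids:
        p = pref.get(cid)
        if p not in ("face", "place"):
            continue
        i = hfb.channel_ids.index(cid)
        q = "place" if p == "face" else "face"
        if p in by_cat:
            a_list.append(by_cat[p].traces[i])
        if q in by_cat:
            b_list.append(by_cat[q].traces[i])
    if not a_list or not b_list:
        raise ValueError("prompts missing in one condition")
    a, b = np.array(a_list), np.array(b_list)
    result = contrast_timecourse(a, b, times, paired=False, n_perm=n_perm, seed=seed)
    return result, {"preferred": a, "non_preferred": b}, times


def roi_event_response(
    hfb: HFBSignal,
    events: pd.DataFrame,
    roi_members: dict[str, list[str]],
    baseline_window: tuple[float, float] = (-5.0, -3.0),
    transient_window: tuple[float, float] = (-1.0, 1.0),
    window: tuple[float, float] = (-5.0, 7.0),
) -> tuple[dict[str, np.ndarray], pd.DataFrame, np.ndarray]:
    """Recall-locked responses in anatomical ROI (e.g. prefrontal, parietal).

    Each electrode's event-triggered trace is normalized by the pre-recall
    baseline (-5 to -3 s); per-ROI mean traces are returned alongside a
    per-electrode two-bin table (baseline vs recall-onset transient) that
    feeds the mixed-model contract.
    """
    rec = _recall_events(events)
    onsets = rec["onset"].to_numpy(float)
    resp = extract_event_triggered(
        hfb, onsets, window=window, all_onsets=onsets,
        baseline_window=baseline_window)
    times = resp.times
    b_sel = (times >= baseline_window[0]) & (times < baseline_window[1])
    t_sel = (times >= transient_window[0]) & (times < transient_window[1])

    roi_traces = {}
    rows = []
    for roi, members in roi_members.items():
        idx = [hfb.channel_ids.index(cid) for cid in members if cid in hfb.channel_ids]
        if not idx:
            raise ValueError(f"ROI {roi!r} has no electrodes in the recording")
        roi_traces[roi] = resp.traces[idx].mean(axis=0)
        for i in idx:
            rows.append(dict(
                electrode_id=hfb.channel_ids[i], roi=roi,
                baseline_bin=float(resp.traces[i, b_sel].mean()),
                transient_bin=float(resp.traces[i, t_sel].mean())))
    return roi_traces, pd.DataFrame(rows), times
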