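"""Synthetic ECoG generator emulating the free-recall task and signal model.

The generator produces seeded datasets (raw multichannel voltage + events
table + electrode table + ground truth) with the structure the analysis
pipeline assumes, so every downstream stage is testable by parameter
recovery:

* Task: per run, 200 s of eyes-closed rest; 14 pictures (7 famous faces,
  7 landmarks) x 4 repetitions, 1500 ms on / 750 ms inter-stimulus interval,
  pseudorandom cycles without immediate repeats; 40 s of backward-counting
  distraction; then two 150-s free-recall blocks, one per category, with the
  category order counter-balanced across the two runs (faces first in run 1).
* Recall events: an inhomogeneous Poisson process whose rate halves over a
  configurable decay time (more recollections early than late), durations
  uniform in 2-6 s, and a configurable intrusion probability (recalling an
  item from the non-targeted category).
* Signal: each channel is 1/f background noise plus a 60-160 Hz band-limited
  carrier whose instantaneous amplitude is exp(Gaussian AR(1) log-envelope)
  — i.e., log-normal HFB amplitude with ultra-slow autocorrelated
  fluctuations — modulated multiplicatively by per-item viewing responses,
  sustained category-specific baseline shifts during matching recall blocks,
  recall-onset-locked transients, optional sporadic bursts, a transient
  collapse of the shift before intrusion errors, and a dip/recovery around
  experimenter prompts.

All times are seconds, intervals half-open [start, end); sample index =
floor(t * rate), 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal as sig

from .preprocessing import Recording

FACE = "face"
PLACE = "place"
CATEGORIES = (FACE, PLACE)

LN10_OVER_10 = np.log(10.0) / 10.0  # dB -> natural-log amplitude factor


# ---------------------------------------------------------------------------
# Task schedule
# ---------------------------------------------------------------------------


@dataclass
class RunSchedule:
    index: int
    rest_interval: tuple[float, float]
    viewing_trials: list[tuple[float, str, str]]  # (onset, item_id, category)
    distraction_interval: tuple[float, float]
    recall_blocks: list[tuple[str, tuple[float, float]]]
    recall_events: list[tuple[float, float, str, str, bool]]
    prompts: list[tuple[float, float, str]]

    @property
    def end(self) -> float:
        return self.recall_blocks[-1][1][1]

    def items(self) -> list[str]:
        return sorted({item for _, item, _ in self.viewing_trials})


@dataclass
class TaskSchedule:
    sampling_rate: float
    runs: list[RunSchedule]

    @property
    def duration(self) -> float:
        return self.runs[-1].end

    def to_events(self) -> pd.DataFrame:
        """Flatten the schedule into a BIDS-like events table."""
        rows = []
        for run in self.runs:
            r = run.index
            rows.append(
                dict(onset=run.rest_interval[0], duration=run.rest_interval[1] - run.rest_interval[0],
                     event_type="rest", item_id="", category="", target_category="",
                     is_intrusion=0, run=r)
            )
            for onset, item, cat in run.viewing_trials:
                rows.append(
                    dict(onset=onset, duration=1.5, event_type="stimulus", item_id=item,
                         category=cat, target_category="", is_intrusion=0, run=r)
                )
            d0, d1 = run.distraction_interval
            rows.append(
                dict(onset=d0, duration=d1 - d0, event_type="distraction", item_id="",
                     category="", target_category="", is_intrusion=0, run=r)
            )
            for target, (b0, b1) in run.recall_blocks:
                rows.append(
                    dict(onset=b0, duration=b1 - b0, event_type="recall_block", item_id="",
                         category="", target_category=target, is_intrusion=0, run=r)
                )
            for onset, offset, item, cat, intr in run.recall_events:
                target = _block_target(run, onset)
                rows.append(
                    dict(onset=onset, duration=offset - onset, event_type="recall",
                         item_id=item, category=cat, target_category=target,
                         is_intrusion=int(intr), run=r)
                )
            for onset, offset, cat in run.prompts:
                rows.append(
                    dict(onset=onset, duration=offset - onset, event_type="prompt",
                         item_id="", category="", target_category=cat, is_intrusion=0, run=r)
                )
        df = pd.DataFrame(rows).sort_values(["onset", "event_type"]).reset_index(drop=True)
        return df


def _block_target(run: RunSchedule, t: float) -> str:
    for target, (b0, b1) in run.recall_blocks:
        if b0 <= t < b1:
            return target
    raise ValueError(f"time {t} falls outside every recall block")


def make_task_schedule(
    n_runs: int = 2,
    n_items_per_category: int = 7,
    seed: int = 0,
    intrusion_rate: float = 0.115,
    recall_rate_decay_s: float = 75.0,
    sampling_rate: float = 500.0,
    rest_s: float = 200.0,
    stim_s: float = 1.5,
    isi_s: float = 0.75,
    n_repetitions: int = 4,
    distraction_s: float = 40.0,
    recall_block_s: float = 150.0,
    recall_rate_hz: float = 0.10,
    min_recall_gap_s: float = 1.0,
    recall_duration_s: tuple[float, float] = (2.0, 6.0),
) -> TaskSchedule:
    """Build a seeded task schedule.

    Recall-event onsets are drawn from a thinned Poisson process whose rate
    halves every ``recall_rate_decay_s`` seconds within each block; a new
    item set (``n_items_per_category`` per category) is used in each run and
    the recalled-category order alternates across runs, starting with faces.
    """
    if n_items_per_category < 1:
        raise ValueError("need at least one item per category")
    if not (0.0 <= intrusion_rate < 1.0):
        raise ValueError("intrusion_rate must be in [0, 1)")
    for val, name in [(rest_s, "rest_s"), (stim_s, "stim_s"), (isi_s, "isi_s"),
                      (distraction_s, "distraction_s"), (recall_block_s, "recall_block_s"),
                      (recall_rate_hz, "recall_rate_hz"), (recall_rate_decay_s, "recall_rate_decay_s")]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")

    rng = np.random.default_rng(seed)
    runs = []
    t = 0.0
    for r in range(n_runs):
        items = {
            cat: [f"{cat}{r * n_items_per_category + i + 1:02d}" for i in range(n_items_per_category)]
            for cat in CATEGORIES
        }
        all_items = items[FACE] + items[PLACE]
        rest = (t, t + rest_s)
        t = rest[1]

        # pseudorandom cycles: every item once per cycle, no immediate repeats
        order: list[str] = []
        for _ in range(n_repetitions):
            for _attempt in range(100):
                cycle = list(rng.permutation(all_items))
                if not order or cycle[0] != order[-1]:
                    break
            order.extend(cycle)
        trials = []
        for item in order:
            cat = FACE if item.startswith(FACE) else PLACE
            trials.append((t, item, cat))
            t += stim_s + isi_s
        distraction = (t, t + distraction_s)
        t = distraction[1]

        cat_order = (FACE, PLACE) if r % 2 == 0 else (PLACE, FACE)
        blocks, events, prompts = [], [], []
        for target in cat_order:
            b0, b1 = t, t + recall_block_s
            blocks.append((target, (b0, b1)))
            ev = _draw_recall_events(
                rng, b0, b1, target, items, intrusion_rate,
                recall_rate_hz, recall_rate_decay_s, min_recall_gap_s, recall_duration_s,
            )
            events.extend(ev)
            prompts.extend(_place_prompts(b0, b1, ev, target))
            t = b1
        runs.append(
            RunSchedule(
                index=r, rest_interval=rest, viewing_trials=trials,
                distraction_interval=distraction, recall_blocks=blocks,
                recall_events=events, prompts=prompts,
            )
        )
    return TaskSchedule(sampling_rate=sampling_rate, runs=runs)


def _draw_recall_events(rng, b0, b1, target, items, intrusion_rate,
                        rate0, decay_s, min_gap, dur_range):
    """Inhomogeneous Poisson recall onsets (rate halving over decay_s)."""
    events = []
    t = b0
    last_offset = -np.inf
    while True:
        # thinning with envelope rate rate0
        t += rng.exponential(1.0 / rate0)
        if t >= b1:
            break
        lam = rate0 * 2.0 ** (-(t - b0) / decay_s)
        if rng.uniform() > lam / rate0:
            continue
        if t < last_offset + min_gap:
            continue
        dur = rng.uniform(*dur_range)
        offset = min(t + dur, b1)
        if offset - t < 0.5:
            continue
        is_intr = bool(rng.uniform() < intrusion_rate)
        cat = ({FACE: PLACE, PLACE: FACE}[target]) if is_intr else target
        item = str(rng.choice(items[cat]))
        events.append((t, offset, item, cat, is_intr))
        last_offset = offset
    return events


def _place_prompts(b0, b1, events, target, min_gap_s=14.0):
    """Drop a prompt into every long recollection-free gap of the block."""
    bounds = [b0] + [off for _, off, *_ in events] + [b1]
    onsets = [on for on, *_ in events] + [b1]
    prompts = []
    for gap_start, gap_end in zip(bounds, onsets):
        if gap_end - gap_start >= min_gap_s:
            onset = gap_start + 4.0
            prompts.append((onset, onset + 2.0, target))
    return prompts


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthElectrode:
    """Generative parameters of one synthetic electrode."""

    electrode_id: str
    group: str  # V1, V2, intermediate, face_selective, place_selective, other, roi_frontal, roi_parietal
    viewing_gain: dict[str, float] = field(default_factory=dict)  # item -> amplitude ratio
    baseline_shift_db: dict[str, float] = field(default_factory=dict)  # category -> dB
    transient_db: float = 0.0
    transient_lag_s: float = 0.0
    burst_spec: dict | None = None  # {amplitude_db, occupancy, window_s}
    envelope_sigma: float = 0.2
    envelope_tau_s: float = 1.0
    carrier_band: tuple[float, float] = (60.0, 160.0)
    noise_exponent: float = 2.0
    latency_s: float = 0.1
    intrusion_collapse: bool = True
    prompt_dip: bool = True
    recall_lowfreq_db: float = 0.0  # low-frequency (<10 Hz) LFP power change during overt recall
    slow_mod_hz: float = 0.0  # ultra-slow HFB amplitude modulation during recall blocks
    slow_mod_db: float = 0.0
    patient: str = "P01"
    hfb_rms_uv: float = 6.0
    noise_rms_uv: float = 25.0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.viewing_gain.values()):
            raise ValueError("viewing gains must be non-negative")
        if self.envelope_sigma <= 0:
            raise ValueError("envelope_sigma must be positive")
        if self.burst_spec is not None:
            occ = self.burst_spec.get("occupancy", 0.0)
            if not (0.0 <= occ <= 1.0):
                raise ValueError("burst occupancy must be in [0, 1]")

    def preferred_category(self) -> str | None:
        if not self.baseline_shift_db:
            return None
        return max(self.baseline_shift_db, key=lambda c: self.baseline_shift_db[c])


@dataclass
class SyntheticDataset:
    recording: Recording
    schedule: TaskSchedule
    electrode_table: pd.DataFrame
    ground_truth: list[GroundTruthElectrode]

    def events(self) -> pd.DataFrame:
        return self.schedule.to_events()


_GROUP_COORDS = {
    "V1": (-8.0, -92.0, 2.0),
    "V2": (12.0, -88.0, 8.0),
    "intermediate": (-30.0, -82.0, 14.0),
    "face_selective": (-38.0, -52.0, -18.0),  # lateral fusiform
    "place_selective": (-28.0, -46.0, -10.0),  # collateral sulcus
    "other": (-52.0, -30.0, 40.0),
    "roi_frontal": (-48.0, 33.0, -9.0),
    "roi_parietal": (-36.0, -57.0, 36.0),
}


def make_default_cohort(
    schedule: TaskSchedule,
    seed: int = 0,
    n_face: int = 4,
    n_place: int = 4,
    n_v1: int = 2,
    n_v2: int = 2,
    n_intermediate: int = 2,
    n_other: int = 1,
    n_roi_frontal: int = 1,
    n_roi_parietal: int = 1,
    baseline_shift_db: float = 0.3,
    transient_db: float = 0.17,
    n_patients: int = 4,
) -> list[GroundTruthElectrode]:
    """Ground-truth cohort emulating the effect structure of the study.

    Category-selective electrodes carry a sustained dB gain for their
    preferred category during matching recall blocks plus a 0.17 dB
    recall-onset transient; early visual electrodes respond fast (<180 ms)
    to all items with no recall effects; frontal/parietal electrodes carry
    a lagged recall transient only.
    """
    rng = np.random.default_rng(seed)
    items = sorted({item for run in schedule.runs for item in run.items()})
    face_items = [i for i in items if i.startswith(FACE)]
    place_items = [i for i in items if i.startswith(PLACE)]

    def item_gains(face_gain, place_gain, jitter=0.15):
        g = {}
        for it in face_items:
            g[it] = max(0.0, face_gain * (1.0 + jitter * rng.standard_normal()))
        for it in place_items:
            g[it] = max(0.0, place_gain * (1.0 + jitter * rng.standard_normal()))
        return g

    specs = []
    specs += [("face_selective", dict(
        viewing_gain=item_gains(2.5, 1.2), latency_s=0.16,
        baseline_shift_db={FACE: baseline_shift_db, PLACE: 0.0},
        transient_db=transient_db, recall_lowfreq_db=-0.95,
        slow_mod_hz=0.15, slow_mod_db=0.5)) for _ in range(n_face)]
    specs += [("place_selective", dict(
        viewing_gain=item_gains(1.2, 2.5), latency_s=0.16,
        baseline_shift_db={FACE: 0.0, PLACE: baseline_shift_db},
        transient_db=transient_db, recall_lowfreq_db=-0.95,
        slow_mod_hz=0.15, slow_mod_db=0.5)) for _ in range(n_place)]
    specs += [("V1", dict(viewing_gain=item_gains(2.2, 2.2, 0.08), latency_s=0.08,
                          recall_lowfreq_db=-0.95)) for _ in range(n_v1)]
    specs += [("V2", dict(viewing_gain=item_gains(2.0, 2.0, 0.08), latency_s=0.11,
                          recall_lowfreq_db=-0.95)) for _ in range(n_v2)]
    specs += [("intermediate", dict(viewing_gain=item_gains(1.8, 1.7), latency_s=0.14,
                                    recall_lowfreq_db=-0.95)) for _ in range(n_intermediate)]
    specs += [("other", dict(viewing_gain=item_gains(1.0, 1.0, 0.0))) for _ in range(n_other)]
    specs += [("roi_frontal", dict(viewing_gain=item_gains(1.0, 1.0, 0.0),
                                   transient_db=0.4, transient_lag_s=0.6))
              for _ in range(n_roi_frontal)]
    specs += [("roi_parietal", dict(viewing_gain=item_gains(1.0, 1.0, 0.0),
                                    transient_db=0.4, transient_lag_s=0.6))
              for _ in range(n_roi_parietal)]

    cohort = []
    for k, (group, kw) in enumerate(specs):
        cohort.append(
            GroundTruthElectrode(
                electrode_id=f"E{k + 1:02d}",
                group=group,
                patient=f"P{k % n_patients + 1:02d}",
                **kw,
            )
        )
    return cohort


def electrode_table_from_truth(ground_truth: Sequence[GroundTruthElectrode],
                               seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for gt in ground_truth:
        x, y, z = _GROUP_COORDS[gt.group]
        jit = rng.uniform(-4, 4, size=3)
        # anatomical label: ROI electrodes are located by coordinates, visual
        # groups carry an atlas label; selective electrodes sit in high-order
        # visual cortex ("ventral_temporal")
        label = {
            "V1": "V1", "V2": "V2", "intermediate": "intermediate",
            "face_selective": "ventral_temporal", "place_selective": "ventral_temporal",
            "other": "other", "roi_frontal": "frontal", "roi_parietal": "parietal",
        }[gt.group]
        rows.append(dict(name=gt.electrode_id, x=x + jit[0], y=y + jit[1], z=z + jit[2],
                         group=label, patient=gt.patient))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------


def simulate_log_envelope(n: int, rate: float, sigma: float, tau_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian AR(1) log-amplitude with s.d. sigma, e-folding tau."""
    a = np.exp(-1.0 / (tau_s * rate))
    w = rng.standard_normal(n)
    x0 = rng.standard_normal()  # stationary initial state
    x, _ = sig.lfilter([np.sqrt(1.0 - a * a)], [1.0, -a], w, zi=np.array([a * x0]))
    return sigma * x


def simulate_log_envelope_db(duration_s: float, rate: float,
                             sigma: float = 0.2, tau_s: float = 1.0,
                             rng: np.random.Generator | None = None,
                             seed: int | None = None) -> np.ndarray:
    """Rest-normalized HFB trace in dB for a stationary synthetic electrode.

    For a log-normal amplitude with log-s.d. sigma, the rest-normalized dB
    trace is Gaussian AR(1) with s.d. 10*sigma/ln(10).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    return simulate_log_envelope(n, rate, sigma, tau_s, rng) / LN10_OVER_10


def _pink_noise(n: int, exponent: float, rms: float, rng: np.random.Generator,
                rate: float, f_min: float = 0.1) -> np.ndarray:
    """Gaussian 1/f^exponent noise (power-spectral slope -exponent)."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = np.maximum(f[nz], f_min) ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
    return x * (rms / x.std())


def _carrier(n: int, rate: float, band: tuple[float, float],
             rng: np.random.Generator, n_components: int = 24) -> np.ndarray:
    """Random-phase sinusoid bank spanning the HFB carrier band (unit RMS)."""
    freqs = rng.uniform(band[0], band[1], n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    t = np.arange(n) / rate
    x = np.zeros(n)
    for f0, ph in zip(freqs, phases):
        x += np.sin(2 * np.pi * f0 * t + ph)
    return x / np.sqrt(n_components / 2.0)


def _ramp(t: np.ndarray, t0: float, t1: float, up: bool) -> np.ndarray:
    """Piecewise-linear 0->1 (up) or 1->0 (down) ramp over [t0, t1]."""
    r = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return r if up else 1.0 - r


def _transient_profile(t: np.ndarray, onset: float, lag: float) -> np.ndarray:
    """Smooth recall-locked bump: rises from onset-1.5 s, plateau, gone by +2 s."""
    t0 = onset + lag
    w = np.zeros_like(t)
    rise = (t >= t0 - 1.5) & (t < t0 - 0.5)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - (t0 - 1.5)) / 1.0))
    plateau = (t >= t0 - 0.5) & (t < t0 + 1.0)
    w[plateau] = 1.0
    fall = (t >= t0 + 1.0) & (t < t0 + 2.0)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (t0 + 1.0)) / 1.0))
    return w


def _viewing_response(t: np.ndarray, onset: float, offset: float,
                      latency: float) -> np.ndarray:
    """Gamma-like onset at the response latency, sustained to stimulus offset."""
    w = np.zeros_like(t)
    t0 = onset + latency
    rise = (t >= t0) & (t < t0 + 0.05)
    w[rise] = (t[rise] - t0) / 0.05
    hold = (t >= t0 + 0.05) & (t < offset)
    w[hold] = 1.0
    fall = (t >= offset) & (t < offset + 0.15)
    w[fall] = 1.0 - (t[fall] - offset) / 0.15
    return w


def _burst_train_db(n: int, rate: float, amplitude_db: float, occupancy: float,
                    window_s: float, rng: np.random.Generator) -> np.ndarray:
    """Sporadic dB bursts: rectangular pulses smoothed by a Gaussian window."""
    from .baseline_shift import _smoothed_burst_component

    return _smoothed_burst_component(n, rate, amplitude_db, occupancy, window_s, rng)


def simulate_recording(
    schedule: TaskSchedule,
    ground_truth: Sequence[GroundTruthElectrode],
    seed: int = 0,
    line_hz: float | None = 60.0,
    line_amp_uv: float = 2.0,
    tail_pad_s: float = 10.0,
) -> SyntheticDataset:
    """Render the cohort into a raw multichannel voltage recording."""
    if not ground_truth:
        raise ValueError("empty ground truth")
    rate = schedule.sampling_rate
    duration = schedule.duration + tail_pad_s
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(ground_truth) + 1)
    data = np.empty((len(ground_truth), n))

    for ch, (gt, cs) in enumerate(zip(ground_truth, child_seeds)):
        rng = np.random.default_rng(cs)
        log_env = simulate_log_envelope(n, rate, gt.envelope_sigma, gt.envelope_tau_s, rng)
        log_gain = np.zeros(n)

        for run in schedule.runs:
            for onset, item, _cat in run.viewing_trials:
                g = gt.viewing_gain.get(item, 1.0)
                if g != 1.0:
                    w = _viewing_response(t, onset, onset + 1.5, gt.latency_s)
                    log_gain += np.log1p((g - 1.0) * w)

            for target, (b0, b1) in run.recall_blocks:
                shift = gt.baseline_shift_db.get(target, 0.0)
                in_block = (t >= b0) & (t < b1)
                if shift != 0.0:
                    mod = np.ones(n)
                    if gt.intrusion_collapse:
                        for on, off, _item, _cat, intr in run.recall_events:
                            if intr and b0 <= on < b1:
                                mod *= np.where(
                                    (t >= on - 2.0) & (t < on - 0.5),
                                    _ramp(t, on - 2.0, on - 0.5, up=False), 1.0)
                                mod *= np.where((t >= on - 0.5) & (t < off), 0.0, 1.0)
                                mod *= np.where(
                                    (t >= off) & (t < off + 1.0),
                                    _ramp(t, off, off + 1.0, up=True), 1.0)
                    if gt.prompt_dip:
                        for on, off, _cat in run.prompts:
                            if b0 <= on < b1:
                                mod *= np.where(
                                    (t >= on - 3.0) & (t < on - 1.0),
                                    _ramp(t, on - 3.0, on - 1.0, up=False), 1.0)
                                mod *= np.where((t >= on - 1.0) & (t < off), 0.0, 1.0)
                                mod *= np.where(
                                    (t >= off) & (t < off + 1.0),
                                    _ramp(t, off, off + 1.0, up=True), 1.0)
                    log_gain += LN10_OVER_10 * shift * mod * in_block

                pref = gt.preferred_category()
                if gt.transient_db != 0.0:
                    for on, off, _item, cat, _intr in run.recall_events:
                        if not (b0 <= on < b1):
                            continue
                        if pref is None:
                            sign = 1.0  # non-selective electrodes respond to every recall
                        else:
                            sign = 1.0 if cat == pref else -1.0
                        w = _transient_profile(t, on, gt.transient_lag_s)
                        log_gain += LN10_OVER_10 * gt.transient_db * sign * w

                if gt.burst_spec is not None:
                    i0, i1 = int(b0 * rate), int(b1 * rate)
                    burst = _burst_train_db(
                        i1 - i0, rate,
                        gt.burst_spec["amplitude_db"],
                        gt.burst_spec["occupancy"],
                        gt.burst_spec.get("window_s", 3.0),
                        rng,
                    )
                    log_gain[i0:i1] += LN10_OVER_10 * burst

                if gt.slow_mod_db != 0.0 and gt.slow_mod_hz > 0.0:
                    ph = rng.uniform(0, 2 * np.pi)
                    log_gain += (LN10_OVER_10 * gt.slow_mod_db
                                 * np.sin(2 * np.pi * gt.slow_mod_hz * t + ph) * in_block)

        amplitude = gt.hfb_rms_uv * np.exp(log_env + log_gain)
        carrier = _carrier(n, rate, gt.carrier_band, rng)
        noise = _pink_noise(n, gt.noise_exponent, gt.noise_rms_uv, rng, rate)
        if gt.recall_lowfreq_db != 0.0:
            # scale the <10 Hz noise component inside overt-recall windows
            sos = sig.butter(4, 10.0, "lowpass", fs=rate, output="sos")
            low = sig.sosfiltfilt(sos, noise)
            w = np.zeros(n)
            for run in schedule.runs:
                for on, off, *_ in run.recall_events:
                    w[int(on * rate) : int(off * rate)] = 1.0
            factor = 10.0 ** (gt.recall_lowfreq_db / 20.0)
            noise = noise + (factor - 1.0) * low * w
        x = noise + amplitude * carrier
        if line_hz is not None and line_amp_uv > 0:
            x = x + line_amp_uv * np.sin(2 * np.pi * line_hz * t + rng.uniform(0, 2 * np.pi))
        data[ch] = x

    rec = Recording(
        data=data, rate=rate,
        channel_ids=[gt.electrode_id for gt in ground_truth],
    )
    table = electrode_table_from_truth(ground_truth, seed=int(child_seeds[-1].generate_state(1)[0] % 2**31))
    return SyntheticDataset(recording=rec, schedule=schedule,
                            electrode_table=table, ground_truth=list(ground_truth))


# ---------------------------------------------------------------------------
# Dataset I/O (TSV + JSON sidecar)
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path,
                  quantize: bool = False) -> dict[str, Path]:
    """Write recording (TSV + JSON sidecar), events, electrodes, ground truth.

    With ``quantize=True`` the voltage matrix is stored as 16-bit integers
    with a physical scale in the sidecar (EDF-style), bounding the round-trip
    error by half a quantization step.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = dataset.recording
    paths: dict[str, Path] = {}

    sidecar = {
        "rate_hz": rec.rate,
        "channel_ids": list(rec.channel_ids),
        "units": "uV",
        "t0": rec.t0,
        "quantized": bool(quantize),
    }
    rec_path = out / "recording.tsv"
    if quantize:
        vmax = float(np.abs(rec.data).max()) or 1.0
        scale = vmax / 32767.0
        q = np.round(rec.data / scale).astype(np.int16)
        sidecar["scale_uv_per_bit"] = scale
        pd.DataFrame(q.T, columns=rec.channel_ids).to_csv(rec_path, sep="\t", index=False)
    else:
        pd.DataFrame(rec.data.T, columns=rec.channel_ids).to_csv(
            rec_path, sep="\t", index=False, float_format="%.6f")
    paths["recording"] = rec_path
    sidecar_path = out / "recording.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    paths["sidecar"] = sidecar_path

    events_path = out / "events.tsv"
    dataset.events().to_csv(events_path, sep="\t", index=False, float_format="%.6f")
    paths["events"] = events_path

    el_path = out / "electrodes.tsv"
    dataset.electrode_table.to_csv(el_path, sep="\t", index=False, float_format="%.3f")
    paths["electrodes"] = el_path

    gt_path = out / "ground_truth.json"
    gt_payload = []
    for gt in dataset.ground_truth:
        d = asdict(gt)
        d["carrier_band"] = list(gt.carrier_band)
        gt_payload.append(d)
    gt_path.write_text(json.dumps(gt_payload, indent=1, sort_keys=True))
    paths["ground_truth"] = gt_path
    return paths


def read_recording(out_dir: str | Path) -> Recording:
    out = Path(out_dir)
    sidecar = json.loads((out / "recording.json").read_text())
    df = pd.read_csv(out / "recording.tsv", sep="\t")
    data = df.to_numpy(float).T
    if sidecar.get("quantized"):
        data = data * sidecar["scale_uv_per_bit"]
    return Recording(data=data, rate=sidecar["rate_hz"],
                     channel_ids=list(sidecar["channel_ids"]), t0=sidecar.get("t0", 0.0))


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"item_id": str, "category": str, "target_category": str})
    return df


def read_ground_truth(path: str | Path) -> list[GroundTruthElectrode]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        d["carrier_band"] = tuple(d["carrier_band"])
        out.append(GroundTruthElectrode(**d))
    return out
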