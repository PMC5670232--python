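"""Shared builders for envelope-level synthetic inputs.

Most analyses operate on the normalized HFB trace, so tests can bypass the
carrier-level simulation and construct dB-state HFBSignal objects directly
from the generator's log-normal AR(1) envelope model. Full raw-voltage
round trips are exercised separately in the synthetic/pipeline tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recallshift.hfb import HFBSignal
from recallshift.synthetic import simulate_log_envelope_db

RATE = 100.0  # envelope-level tests run at a reduced rate; analyses are rate-agnostic


def two_run_block_events(block_s: float = 150.0, start: float = 0.0,
                         gap_s: float = 0.0) -> pd.DataFrame:
    """Four recall blocks (two runs, category order counter-balanced)."""
    rows = []
    t = start
    for run, order in enumerate([("face", "place"), ("place", "face")]):
        for target in order:
            rows.append(dict(onset=t, duration=block_s, event_type="recall_block",
                             item_id="", category="", target_category=target,
                             is_intrusion=0, run=run))
            t += block_s + gap_s
    return pd.DataFrame(rows)


def add_recall_events(events: pd.DataFrame, rng: np.random.Generator,
                      n_per_block: int = 8, duration_s: float = 3.0,
                      intrusion_every: int = 0) -> pd.DataFrame:
    """Evenly spaced recall events inside each block (optional intrusions)."""
    rows = []
    blocks = events[events["event_type"] == "recall_block"]
    for _, blk in blocks.iterrows():
        b0, b1 = blk["onset"], blk["onset"] + blk["duration"]
        onsets = np.linspace(b0 + 6.0, b1 - duration_s - 6.0, n_per_block)
        onsets = onsets + rng.uniform(-0.5, 0.5, size=n_per_block)
        for k, on in enumerate(onsets):
            intr = intrusion_every > 0 and (k % intrusion_every == intrusion_every - 1)
            cat = blk["target_category"]
            if intr:
                cat = "place" if cat == "face" else "face"
            rows.append(dict(onset=on, duration=duration_s, event_type="recall",
                             item_id=f"{cat}01", category=cat,
                             target_category=blk["target_category"],
                             is_intrusion=int(intr), run=blk["run"]))
    out = pd.concat([events, pd.DataFrame(rows)], ignore_index=True)
    return out.sort_values("onset").reset_index(drop=True)


def transient_bump(t: np.ndarray, onset: float, peak_db: float,
                   lag: float = 0.0) -> np.ndarray:
    """Cosine-ramped plateau bump: rises from onset-1.5 s, flat 0.17-style
    plateau on [-0.5, +1.0], gone by +2.0 s (all relative to onset+lag)."""
    t0 = onset + lag
    w = np.zeros_like(t)
    rise = (t >= t0 - 1.5) & (t < t0 - 0.5)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - (t0 - 1.5))))
    plat = (t >= t0 - 0.5) & (t < t0 + 1.0)
    w[plat] = 1.0
    fall = (t >= t0 + 1.0) & (t < t0 + 2.0)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (t0 + 1.0))))
    return peak_db * w


def db_signal(n_el: int, duration_s: float, seed: int, rate: float = RATE,
              sigma: float = 0.2, tau_s: float = 1.0) -> HFBSignal:
    """Stationary rest-normalized dB cohort (no injected effects)."""
    rng = np.random.default_rng(seed)
    traces = np.stack([
        simulate_log_envelope_db(duration_s, rate, sigma=sigma, tau_s=tau_s, rng=rng)
        for _ in range(n_el)
    ])
    return HFBSignal(amplitude=traces, rate=rate,
                     channel_ids=[f"E{i + 1:02d}" for i in range(n_el)], state="db")


def inject_block_shift(hfb: HFBSignal, events: pd.DataFrame,
                       shift_by_electrode: dict[str, dict[str, float]]) -> None:
    """Add a constant dB gain during recall blocks of the mapped category."""
    t = hfb.times()
    blocks = events[events["event_type"] == "recall_block"]
    for cid, per_cat in shift_by_electrode.items():
        i = hfb.channel_ids.index(cid)
        for _, blk in blocks.iterrows():
            g = per_cat.get(blk["target_category"], 0.0)
            if g:
                sel = (t >= blk["onset"]) & (t < blk["onset"] + blk["duration"])
                hfb.amplitude[i, sel] += g


def inject_transients(hfb: HFBSignal, events: pd.DataFrame,
                      peak_by_electrode: dict[str, float],
                      preferred: dict[str, str] | None = None,
                      lag: float = 0.0) -> None:
    """Add recall-onset-locked bumps (sign flips for non-preferred events)."""
    t = hfb.times()
    rec = events[events["event_type"] == "recall"]
    for cid, peak in peak_by_electrode.items():
        i = hfb.channel_ids.index(cid)
        for _, ev in rec.iterrows():
            sign = 1.0
            if preferred is not None:
                sign = 1.0 if ev["category"] == preferred.get(cid) else -1.0
            hfb.amplitude[i] += transient_bump(t, ev["onset"], sign * peak, lag=lag)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full-physics dataset shared by the slower integration tests."""
    from recallshift.synthetic import (make_default_cohort, make_task_schedule,
                                       simulate_recording)

    schedule = make_task_schedule(n_runs=2, n_items_per_category=3, seed=11,
                                  rest_s=60.0, recall_block_s=60.0,
                                  recall_rate_hz=0.25)
    cohort = make_default_cohort(schedule, seed=12, n_face=2, n_place=2,
                                 n_v1=1, n_v2=1, n_intermediate=1, n_other=1,
                                 n_roi_frontal=1, n_roi_parietal=1)
    return simulate_recording(schedule, cohort, seed=13)
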