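"""High-frequency broadband (HFB, 60-160 Hz) amplitude extraction.

The HFB envelope is the field's standard proxy for local population firing.
It is computed in five steps: (1) zero-phase FIR band-pass filtering in five
contiguous 20 Hz bands between 60 and 160 Hz; (2) Hilbert envelope of each
band; (3) division of each band envelope by its own mean (whitening the 1/f
spectral decay so higher bands are not swamped by lower ones); (4) averaging
the normalized envelopes; (5) rescaling by the mean amplitude across bands,
bringing the trace back into volts.

Normalization states are tracked explicitly:
  volts          raw envelope amplitude (µV)
  rest_ratio     divided by the geometric mean over the rest period of a run
  prestim_ratio  viewing epochs divided by the run-average pre-stimulus mean
  db             10*log10 of a ratio state
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal as sig

from .preprocessing import ArtifactMask, Recording

DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (60.0, 80.0),
    (80.0, 100.0),
    (100.0, 120.0),
    (120.0, 140.0),
    (140.0, 160.0),
)


@dataclass
class BandSpec:
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    filter_order: int = 138
    window_type: str = "hamming"

    def __post_init__(self) -> None:
        for (l0, h0), (l1, _h1) in zip(self.bands, self.bands[1:]):
            if l0 >= h0 or h0 != l1:
                raise ValueError("bands must be contiguous and non-overlapping")


@dataclass
class HFBSignal:
    """Per-electrode broadband amplitude trace with normalization state."""

    amplitude: np.ndarray  # (n_channels, n_samples)
    rate: float
    channel_ids: list[str]
    state: str = "volts"
    rest_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim == 1:
            self.amplitude = self.amplitude[None, :]
        if self.state in ("volts", "rest_ratio") and np.any(self.amplitude < 0):
            raise ValueError(f"negative amplitude in state {self.state!r}")

    @property
    def n_samples(self) -> int:
        return self.amplitude.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class ViewingEpochs:
    """Stimulus-locked epochs (-500 to +1750 ms), pre-stimulus normalized.

    data is (n_electrodes, n_trials, n_times); trials holds one row per
    epoch (onset, item_id, category, run, artifact flag).
    """

    data: np.ndarray
    times: np.ndarray
    trials: pd.DataFrame
    rate: float
    channel_ids: list[str]
    state: str = "prestim_ratio"


def hfb_amplitude(
    recording: Recording,
    band_spec: BandSpec | None = None,
    mask: ArtifactMask | None = None,
) -> HFBSignal:
    """Five-step broadband amplitude extraction (returns state='volts').

    Band means in steps 3 and 5 are taken over the whole recording,
    excluding artifact-masked samples when a mask is given.
    """
    spec = band_spec or BandSpec()
    top = max(h for _, h in spec.bands)
    if recording.rate < 2.0 * top:
        raise ValueError("sampling rate below Nyquist for the top band")
    if recording.n_samples < 3 * (spec.filter_order + 1):
        raise ValueError("recording too short for the band-pass filter order")
    if not np.all(np.isfinite(recording.data)):
        raise ValueError("NaNs in input")

    good = np.ones(recording.n_samples, dtype=bool)
    if mask is not None:
        good = ~mask.excluded
    n_fft = int(2 ** np.ceil(np.log2(recording.n_samples)))
    band_envs = []
    band_means = []
    for lo, hi in spec.bands:
        taps = sig.firwin(
            spec.filter_order + 1,
            [lo, hi],
            fs=recording.rate,
            pass_zero=False,
            window=spec.window_type,
        )
        bp = sig.filtfilt(taps, [1.0], recording.data, axis=-1)
        env = np.abs(sig.hilbert(bp, N=n_fft, axis=-1)[..., : recording.n_samples])
        m = env[:, good].mean(axis=1, keepdims=True)
        band_envs.append(env / m)
        band_means.append(m)
    avg = np.mean(band_envs, axis=0)
    scale = np.mean(band_means, axis=0)  # mean amplitude across all bands
    return HFBSignal(
        amplitude=avg * scale,
        rate=recording.rate,
        channel_ids=list(recording.channel_ids),
        state="volts",
    )


def _interval_slice(interval: tuple[float, float], rate: float, n: int) -> slice:
    start, end = interval
    i0 = max(0, int(np.floor(start * rate)))
    i1 = min(n, int(np.floor(end * rate)))
    return slice(i0, i1)


def normalize_to_rest(
    hfb: HFBSignal,
    rest_intervals: Sequence[tuple[float, float]],
    mask: ArtifactMask | None = None,
    run_intervals: Sequence[tuple[float, float]] | None = None,
    min_rest_s: float = 30.0,
) -> HFBSignal:
    """Divide by the geometric mean amplitude over each run's rest period.

    ``rest_intervals`` gives one [start, end) rest window per run;
    ``run_intervals`` the span of data each run's normalizer applies to
    (defaults to a partition at the rest starts). Geometric-mean
    normalization equals median normalization for log-normal amplitudes.
    """
    if hfb.state != "volts":
        raise ValueError("normalize_to_rest expects state='volts'")
    n = hfb.n_samples
    if run_intervals is None:
        starts = [r[0] for r in rest_intervals]
        bounds = starts[1:] + [n / hfb.rate]
        run_intervals = [(s, e) for s, e in zip(starts, bounds)]
    if len(run_intervals) != len(rest_intervals):
        raise ValueError("one run interval per rest interval required")
    good = np.ones(n, dtype=bool) if mask is None else ~mask.excluded
    out = np.empty_like(hfb.amplitude)
    for rest, run in zip(rest_intervals, run_intervals):
        rsl = _interval_slice(rest, hfb.rate, n)
        sel = good[rsl]
        if sel.sum() / hfb.rate < min_rest_s:
            raise ValueError("fewer than the required unmasked rest seconds")
        seg = hfb.amplitude[:, rsl][:, sel]
        if np.any(seg <= 0):
            raise ValueError("non-positive amplitudes in rest period")
        gm = np.exp(np.log(seg).mean(axis=1, keepdims=True))
        usl = _interval_slice(run, hfb.rate, n)
        out[:, usl] = hfb.amplitude[:, usl] / gm
    return HFBSignal(
        amplitude=out,
        rate=hfb.rate,
        channel_ids=list(hfb.channel_ids),
        state="rest_ratio",
        rest_intervals=list(rest_intervals),
    )


def to_db(hfb: HFBSignal) -> HFBSignal:
    """dB transform of an amplitude ratio: x -> 10*log10(x)."""
    if hfb.state not in ("rest_ratio", "prestim_ratio"):
        raise ValueError("to_db expects a ratio state")
    if np.any(hfb.amplitude <= 0):
        raise ValueError("non-positive ratio")
    out = replace(hfb)
    out.amplitude = 10.0 * np.log10(hfb.amplitude)
    out.state = "db"
    return out


def epoch_viewing(
    hfb: HFBSignal,
    events: pd.DataFrame,
    mask: ArtifactMask | None = None,
    window: tuple[float, float] = (-0.5, 1.75),
    baseline: tuple[float, float] = (-0.4, -0.1),
) -> ViewingEpochs:
    """Epoch the HFB trace around stimulus onsets, pre-stimulus normalized.

    The divisor is one scalar per electrode per run: the mean amplitude in
    the baseline window, averaged across all of that run's trials. Trials
    overlapping the artifact mask are flagged, not dropped.
    """
    if hfb.state != "volts":
        raise ValueError("epoch_viewing expects state='volts'")
    stim = events[events["event_type"] == "stimulus"].sort_values("onset")
    if stim.empty:
        raise ValueError("no stimulus events")
    rate = hfb.rate
    n = hfb.n_samples
    i0 = int(round(window[0] * rate))
    i1 = int(round(window[1] * rate)) + 1  # endpoints inclusive
    n_t = i1 - i0
    b0 = int(round((baseline[0] - window[0]) * rate))
    b1 = int(round((baseline[1] - window[0]) * rate))

    onsets = stim["onset"].to_numpy(float)
    onset_idx = np.floor(onsets * rate).astype(int)
    if (onset_idx + i0 < 0).any() or (onset_idx + i1 > n).any():
        raise ValueError("epoch window outside recording")

    n_el = hfb.amplitude.shape[0]
    epochs = np.empty((n_el, len(onsets), n_t))
    art = np.zeros(len(onsets), dtype=bool)
    excluded = None if mask is None else mask.excluded
    for k, oi in enumerate(onset_idx):
        sl = slice(oi + i0, oi + i1)
        epochs[:, k, :] = hfb.amplitude[:, sl]
        if excluded is not None and excluded[sl].any():
            art[k] = True

    runs = stim["run"].to_numpy() if "run" in stim else np.zeros(len(onsets), int)
    for run in np.unique(runs):
        in_run = runs == run
        if not in_run.any():
            continue
        base = epochs[:, in_run, b0:b1].mean(axis=2).mean(axis=1)  # (n_el,)
        epochs[:, in_run, :] /= base[:, None, None]

    trials = stim.reset_index(drop=True).copy()
    trials["artifact"] = art
    times = (np.arange(i0, i1)) / rate
    return ViewingEpochs(
        data=epochs,
        times=times,
        trials=trials,
        rate=rate,
        channel_ids=list(hfb.channel_ids),
        state="prestim_ratio",
    )


def smooth_triangular(trace: np.ndarray, width_ms: float, rate: float) -> np.ndarray:
    """Smooth with a unit-area symmetric triangular kernel.

    Edges are renormalized over the kernel's valid support, so a constant
    trace is returned unchanged; output length equals input length.
    """
    trace = np.asarray(trace, dtype=float)
    n_k = int(round(width_ms / 1000.0 * rate))
    if n_k < 2:
        raise ValueError("kernel must span at least 2 samples")
    if n_k > trace.shape[-1]:
        raise ValueError("kernel wider than the trace")
    if n_k % 2 == 0:
        n_k += 1  # symmetric kernel
    kernel = sig.windows.triang(n_k)
    kernel /= kernel.sum()
    ones = np.ones(trace.shape[-1])
    norm = np.convolve(ones, kernel, mode="same")
    if trace.ndim == 1:
        return np.convolve(trace, kernel, mode="same") / norm
    out = np.empty_like(trace)
    for i in range(trace.shape[0]):
        out[i] = np.convolve(trace[i], kernel, mode="same") / norm
    return out
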