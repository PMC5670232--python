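"""Raw ECoG cleaning: line-noise removal, re-referencing, artifact handling.

The cleaning chain mirrors standard clinical-ECoG practice: zero-phase FIR
notch filters at the mains frequency and its harmonics, common-average
re-referencing (excluding corrupted channels), rejection of channels with
extreme voltage tails, and masking of transient multi-channel artifacts.
Masked samples stay in the time base (they are excluded from statistics,
never cut out), so event alignment is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.signal as sig


@dataclass
class Recording:
    """Multichannel voltage trace.

    data is (n_channels, n_samples) in microvolts; rate in Hz; t0 the time
    (s) of the first sample.
    """

    data: np.ndarray
    rate: float
    channel_ids: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate


@dataclass
class ArtifactMask:
    """Per-sample exclusion mask plus rejected channels.

    ``excluded[i]`` is True where sample i falls inside an exclusion window
    (window_ms centred on a detected outlier event).
    """

    bad_channels: list[str]
    excluded: np.ndarray
    window_ms: float

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)

    def intervals(self, rate: float) -> list[tuple[float, float]]:
        """Contiguous excluded spans as (start_s, end_s), half-open."""
        if not self.excluded.any():
            return []
        x = np.concatenate([[False], self.excluded, [False]])
        edges = np.flatnonzero(np.diff(x.astype(int)))
        starts, ends = edges[::2], edges[1::2]
        return [(s / rate, e / rate) for s, e in zip(starts, ends)]


def notch_line_noise(
    recording: Recording, line_hz: float = 60.0, max_hz: float | None = None
) -> Recording:
    """Remove mains interference and harmonics with zero-phase FIR band-stops.

    Hamming-windowed FIR band-stop filters (half-width 2.5 Hz) are applied
    forward-backward at line_hz and every harmonic below min(max_hz, Nyquist).
    """
    nyq = recording.rate / 2.0
    if line_hz >= nyq:
        raise ValueError("line frequency must be below Nyquist")
    top = nyq if max_hz is None else min(max_hz, nyq)
    half_width = 2.5
    numtaps = int(recording.rate) | 1  # ~1 s kernel, odd length
    data = recording.data
    f = line_hz
    while f < top:
        lo, hi = f - half_width, min(f + half_width, nyq - 1e-6)
        taps = sig.firwin(numtaps, [lo, hi], fs=recording.rate, window="hamming")
        data = sig.filtfilt(taps, [1.0], data, axis=-1)
        f += line_hz
    return Recording(data, recording.rate, list(recording.channel_ids), recording.t0)


def common_average_reference(
    recording: Recording, exclude_ids: Sequence[str] = ()
) -> Recording:
    """Subtract the across-channel mean (excluded channels pass through).

    The reference is the per-sample mean over non-excluded channels; excluded
    (corrupted) channels are left untouched and do not enter the average.
    """
    exclude = set(exclude_ids)
    keep = np.array([cid not in exclude for cid in recording.channel_ids])
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-excluded channels")
    ref = recording.data[keep].mean(axis=0)
    data = recording.data.copy()
    data[keep] -= ref
    return Recording(data, recording.rate, list(recording.channel_ids), recording.t0)


def detect_bad_channels(recording: Recording, thresh_uv: float = 500.0) -> list[str]:
    """Flag channels whose extreme-voltage tail is implausibly large.

    A channel is rejected when the mean of |voltage| over its own samples
    above the 99th percentile of |voltage| exceeds thresh_uv (microvolts).
    """
    if recording.n_samples < 100:
        raise ValueError("need at least 100 samples for a 99th percentile")
    bad = []
    for cid, x in zip(recording.channel_ids, np.abs(recording.data)):
        q99 = np.percentile(x, 99)
        tail = x[x > q99]
        if tail.size and tail.mean() > thresh_uv:
            bad.append(cid)
    return bad


def detect_transient_artifacts(
    recording: Recording,
    sd_thresh: float = 5.0,
    grad_thresh_uv_per_ms: float = 30.0,
    frac_channels: float = 0.10,
    window_ms: float = 200.0,
) -> ArtifactMask:
    """Mask transient multi-channel voltage artifacts.

    A sample is an outlier event when at least ``frac_channels`` of channels
    either deviate more than ``sd_thresh`` standard deviations from their own
    mean, or show a voltage gradient above ``grad_thresh_uv_per_ms``. A
    window of ``window_ms`` centred on each outlier sample is excluded.
    """
    if window_ms < 1000.0 / recording.rate:
        raise ValueError("window_ms shorter than one sample period")
    x = recording.data
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    amp_out = np.abs(x - mu) > sd_thresh * sd
    # gradient in µV/ms; boundary sample uses the forward difference
    grad = np.empty_like(x)
    grad[:, :-1] = np.diff(x, axis=1)
    grad[:, -1] = grad[:, -2]
    grad = np.abs(grad) * recording.rate / 1000.0
    grad_out = grad > grad_thresh_uv_per_ms
    outlier = (amp_out | grad_out).mean(axis=0) >= frac_channels

    excluded = np.zeros(recording.n_samples, dtype=bool)
    half = int(round(window_ms / 2.0 * recording.rate / 1000.0))
    idx = np.flatnonzero(outlier)
    for i in idx:
        excluded[max(0, i - half) : min(recording.n_samples, i + half + 1)] = True
    return ArtifactMask(bad_channels=[], excluded=excluded, window_ms=window_ms)


def preprocess(
    recording: Recording,
    line_hz: float = 60.0,
    max_harmonic_hz: float | None = None,
    corrupted_ids: Sequence[str] = (),
) -> tuple[Recording, ArtifactMask]:
    """Full cleaning chain: notch, re-reference, bad channels, transients."""
    rec = notch_line_noise(recording, line_hz, max_harmonic_hz)
    rec = common_average_reference(rec, exclude_ids=corrupted_ids)
    bad = detect_bad_channels(rec)
    keep = [cid for cid in rec.channel_ids if cid not in set(bad) | set(corrupted_ids)]
    keep_idx = [rec.channel_ids.index(cid) for cid in keep]
    clean = Recording(rec.data[keep_idx], rec.rate, keep, rec.t0)
    mask = detect_transient_artifacts(clean)
    mask.bad_channels = list(bad)
    return clean, mask
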