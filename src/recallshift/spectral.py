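"""Multitaper spectral analysis of raw LFP and ultra-slow HFB fluctuations.

Power spectra are estimated with the multitaper method: each demeaned,
zero-padded segment is windowed with K orthogonal Slepian (DPSS) tapers,

    s_x(f) = (1/K) sum_k | FFT( w_k(t) * x_n(t) ) |^2,

then averaged over tapers and segments. The time-bandwidth product is
NW = (K+1)/2 (the standard K = 2NW - 1 relation), giving a half-bandwidth
W = NW / T for a segment of T seconds.

Two configurations are used:
* raw LFP, 1-50 Hz: 5-s non-overlapping segments, K=7 tapers, pad to 2^12;
* ultra-slow HFB fluctuations (< ~2 Hz): the rest-normalized HFB amplitude
  in 25-s segments, K=4 tapers, pad to 2^14 — half-bandwidth 0.1 Hz.

Condition spectra are compared as dB gains relative to rest with a
per-frequency signed-rank test across electrodes, BH-FDR corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal as sig

from .hfb import HFBSignal
from .preprocessing import Recording
from .stats import bh_fdr, wilcoxon_signed_rank


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray  # (..., n_freqs), averaged over segments and tapers
    segment_s: float
    k_tapers: int
    nw: float
    pad: int
    n_segments: int
    condition: str = ""

    @property
    def half_bandwidth_hz(self) -> float:
        return self.nw / self.segment_s


def multitaper_half_bandwidth(segment_s: float, k_tapers: int) -> float:
    """Half-bandwidth W = NW / T with NW = (K+1)/2."""
    return ((k_tapers + 1) / 2.0) / segment_s


def multitaper_psd(
    segments: np.ndarray,
    rate: float,
    k_tapers: int,
    nw: float | None = None,
    pad: int | None = None,
    condition: str = "",
) -> PSDEstimate:
    """Average multitaper PSD over segments (one-sided, density scaling).

    ``segments`` is (n_segments, n_samples); each segment is demeaned,
    tapered with the K Slepian tapers of time-bandwidth NW (default
    (K+1)/2), zero-padded to ``pad`` (default next power of 2), and the
    taper periodograms are averaged over tapers then segments.
    """
    segs = np.atleast_2d(np.asarray(segments, float))
    n_seg, n = segs.shape
    if nw is None:
        nw = (k_tapers + 1) / 2.0
    if k_tapers > 2 * nw - 1 + 1e-9:
        raise ValueError("K exceeds the 2*NW - 1 concentration limit")
    if pad is None:
        pad = int(2 ** np.ceil(np.log2(n)))
    if pad < n:
        raise ValueError("pad shorter than the segment")
    tapers = sig.windows.dpss(n, nw, Kmax=k_tapers)  # (K, n), unit energy
    segs = segs - segs.mean(axis=1, keepdims=True)
    # (n_seg, K, pad) spectra
    tapered = segs[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, n=pad, axis=-1)
    psd = (np.abs(spec) ** 2) / rate
    # one-sided: double everything except DC (and Nyquist when present)
    psd[..., 1:] *= 2.0
    if pad % 2 == 0:
        psd[..., -1] /= 2.0
    power = psd.mean(axis=1).mean(axis=0)
    freqs = np.fft.rfftfreq(pad, d=1.0 / rate)
    return PSDEstimate(freqs=freqs, power=power, segment_s=n / rate,
                       k_tapers=k_tapers, nw=nw, pad=pad,
                       n_segments=n_seg, condition=condition)


# ---------------------------------------------------------------------------
# Segment bookkeeping
# ---------------------------------------------------------------------------


def _cut_nonoverlapping(interval: tuple[float, float], seg_s: float,
                        rate: float, n: int, good: np.ndarray) -> list[slice]:
    """Non-overlapping seg_s slices inside [start, end), skipping masked ones."""
    start, end = interval
    w = int(round(seg_s * rate))
    out = []
    i = int(np.floor(start * rate))
    stop = min(n, int(np.floor(end * rate)))
    while i + w <= stop:
        if good[i : i + w].all():
            out.append(slice(i, i + w))
        i += w
    return out


def condition_segments(
    events: pd.DataFrame,
    rate: float,
    n_samples: int,
    seg_s: float = 5.0,
    mask=None,
    guard_before_next_recall_s: float = 2.0,
) -> dict[str, list[slice]]:
    """Sample slices per condition: rest, viewing, recall events, IRI.

    Recall-event segments are seg_s windows centred on recall onsets.
    Inter-recall-interval (IRI) segments are non-overlapping seg_s cuts
    from each recall offset until ``guard_before_next_recall_s`` seconds
    before the next recall onset (bounded by the block end).
    """
    good = np.ones(n_samples, dtype=bool) if mask is None else ~mask.excluded[:n_samples]
    segs: dict[str, list[slice]] = {"rest": [], "viewing": [], "recall": [], "iri": []}

    for _, ev in events[events["event_type"] == "rest"].iterrows():
        segs["rest"] += _cut_nonoverlapping(
            (ev["onset"], ev["onset"] + ev["duration"]), seg_s, rate, n_samples, good)

    stim = events[events["event_type"] == "stimulus"]
    for run in stim["run"].unique() if "run" in stim else [0]:
        s = stim[stim["run"] == run] if "run" in stim else stim
        if s.empty:
            continue
        t0 = s["onset"].min()
        t1 = (s["onset"] + s["duration"]).max()
        segs["viewing"] += _cut_nonoverlapping((t0, t1), seg_s, rate, n_samples, good)

    rec = events[events["event_type"] == "recall"].sort_values("onset")
    blocks = events[events["event_type"] == "recall_block"]
    half = seg_s / 2.0
    w = int(round(seg_s * rate))
    for _, ev in rec.iterrows():
        c = int(np.floor(ev["onset"] * rate))
        i0 = c - w // 2
        if i0 >= 0 and i0 + w <= n_samples and good[i0 : i0 + w].all():
            segs["recall"].append(slice(i0, i0 + w))
    for _, blk in blocks.iterrows():
        b0, b1 = blk["onset"], blk["onset"] + blk["duration"]
        in_blk = rec[(rec["onset"] >= b0) & (rec["onset"] < b1)].sort_values("onset")
        offs = (in_blk["onset"] + in_blk["duration"]).to_numpy(float)
        ons = in_blk["onset"].to_numpy(float)
        for k, off in enumerate(offs):
            nxt = ons[k + 1] - guard_before_next_recall_s if k + 1 < len(ons) else b1
            segs["iri"] += _cut_nonoverlapping((off, min(nxt, b1)), seg_s, rate,
                                               n_samples, good)
    return segs


# ---------------------------------------------------------------------------
# Condition spectra with rest-relative gains
# ---------------------------------------------------------------------------


def _per_electrode_psd(data: np.ndarray, slices: list[slice], rate: float,
                       k_tapers: int, pad: int, condition: str) -> PSDEstimate:
    if not slices:
        raise ValueError(f"condition {condition!r} has no eligible segments")
    n_el = data.shape[0]
    stack = None
    for i in range(n_el):
        segs = np.stack([data[i, sl] for sl in slices])
        est = multitaper_psd(segs, rate, k_tapers, pad=pad, condition=condition)
        if stack is None:
            stack = np.empty((n_el, est.freqs.size))
            freqs = est.freqs
        stack[i] = est.power
    return PSDEstimate(freqs=freqs, power=stack, segment_s=est.segment_s,
                       k_tapers=k_tapers, nw=est.nw, pad=pad,
                       n_segments=len(slices), condition=condition)


def gain_vs_reference(est: PSDEstimate, ref: PSDEstimate,
                      fmin: float, fmax: float, alpha: float = 0.05) -> pd.DataFrame:
    """Per-frequency dB gain vs a reference condition, signed-rank + BH-FDR.

    Power is per-electrode (rows); the gain at each frequency is tested
    across electrodes with a Wilcoxon signed-rank test and FDR-corrected
    over the reported frequency range.
    """
    sel = (est.freqs >= fmin) & (est.freqs <= fmax)
    freqs = est.freqs[sel]
    gain = 10.0 * np.log10(est.power[:, sel] / ref.power[:, sel])
    pvals = np.ones(freqs.size)
    for k in range(freqs.size):
        col = gain[:, k]
        try:
            pvals[k] = wilcoxon_signed_rank(col).p
        except ValueError:
            pvals[k] = 1.0
    reject, qvals = bh_fdr(pvals, alpha=alpha)
    return pd.DataFrame(dict(
        freq_hz=freqs, mean_gain_db=gain.mean(axis=0),
        p=pvals, q=qvals, significant=reject))


def lfp_condition_spectra(
    recording: Recording,
    events: pd.DataFrame,
    mask=None,
    seg_s: float = 5.0,
    k_tapers: int = 7,
    pad: int = 2**12,
    fmin: float = 1.0,
    fmax: float = 50.0,
) -> dict:
    """Raw-LFP multitaper spectra (1-50 Hz) per condition with rest gains."""
    segs = condition_segments(events, recording.rate, recording.n_samples,
                              seg_s=seg_s, mask=mask)
    estimates = {}
    for cond, slices in segs.items():
        estimates[cond] = _per_electrode_psd(
            recording.data, slices, recording.rate, k_tapers, pad, cond)
    gains = {}
    for cond in ("viewing", "recall", "iri"):
        gains[cond] = gain_vs_reference(estimates[cond], estimates["rest"], fmin, fmax)
    gains["recall_vs_iri"] = gain_vs_reference(estimates["recall"], estimates["iri"],
                                               fmin, fmax)
    return {"estimates": estimates, "gains": gains}


def hfb_fluctuation_spectra(
    hfb: HFBSignal,
    events: pd.DataFrame,
    mask=None,
    seg_s: float = 25.0,
    k_tapers: int = 4,
    pad: int = 2**14,
    fmax: float = 2.0,
) -> dict:
    """Ultra-slow (< ~2 Hz) spectra of the normalized HFB amplitude.

    Conditions: rest, viewing, and free recall (whole blocks), cut into
    non-overlapping 25-s epochs; epochs touching the artifact mask are
    dropped whole. Gains are reported relative to rest.
    """
    if hfb.state != "rest_ratio":
        raise ValueError("expects the rest-normalized amplitude-ratio trace")
    n = hfb.n_samples
    good = np.ones(n, dtype=bool) if mask is None else ~mask.excluded[:n]
    segs: dict[str, list[slice]] = {"rest": [], "viewing": [], "recall": []}
    for _, ev in events[events["event_type"] == "rest"].iterrows():
        segs["rest"] += _cut_nonoverlapping(
            (ev["onset"], ev["onset"] + ev["duration"]), seg_s, hfb.rate, n, good)
    stim = events[events["event_type"] == "stimulus"]
    for run in stim["run"].unique() if "run" in stim else [0]:
        s = stim[stim["run"] == run] if "run" in stim else stim
        if s.empty:
            continue
        segs["viewing"] += _cut_nonoverlapping(
            (s["onset"].min(), (s["onset"] + s["duration"]).max()), seg_s, hfb.rate, n, good)
    for _, blk in events[events["event_type"] == "recall_block"].iterrows():
        segs["recall"] += _cut_nonoverlapping(
            (blk["onset"], blk["onset"] + blk["duration"]), seg_s, hfb.rate, n, good)

    estimates = {}
    for cond, slices in segs.items():
        estimates[cond] = _per_electrode_psd(
            hfb.amplitude, slices, hfb.rate, k_tapers, pad, cond)
    gains = {}
    for cond in ("viewing", "recall"):
        gains[cond] = gain_vs_reference(estimates[cond], estimates["rest"],
                                        estimates[cond].freqs[1], fmax)
    return {"estimates": estimates, "gains": gains}
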