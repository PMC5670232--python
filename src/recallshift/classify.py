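"""Visual responsiveness, latency, category selectivity, and electrode groups.

Electrodes are classified from their stimulus-locked HFB responses:

* responsiveness — per-trial response mean (100-500 ms post-stimulus) vs the
  per-trial pre-stimulus baseline (-400 to -100 ms), paired two-tailed t-test,
  p-values pooled across all electrodes and BH-FDR controlled at alpha=0.01;
* latency — the first post-stimulus time point whose per-sample paired t-test
  stays below p=0.05 for at least 50 ms;
* category selectivity — two-sample t-test on per-trial dB responses to faces
  vs places, BH-FDR across responsive electrodes (alpha=0.01); selective
  electrodes outside V1/V2 become face- or place-selective;
* CSI — (R_faces - R_places) / (R_faces + R_places) with category means
  normalized by the electrode's maximal single-item response; +1 = pure face
  preference, -1 = pure place preference;
* groups — V1/V2 (anatomical label AND latency <= 180 ms), face/place
  selective, intermediate retinotopic, or other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .hfb import ViewingEpochs
from .stats import bh_fdr
from .synthetic import FACE, PLACE

RESPONSE_WINDOW = (0.1, 0.5)
BASELINE_WINDOW = (-0.4, -0.1)
EARLY_VISUAL_MAX_LATENCY_MS = 180.0


def _window_mean(epochs: ViewingEpochs, window: tuple[float, float]) -> np.ndarray:
    """Per-electrode, per-trial mean over a time window: (n_el, n_trials)."""
    sel = (epochs.times >= window[0]) & (epochs.times < window[1])
    return epochs.data[:, :, sel].mean(axis=2)


def _clean_trials(epochs: ViewingEpochs) -> np.ndarray:
    if "artifact" in epochs.trials:
        return ~epochs.trials["artifact"].to_numpy(bool)
    return np.ones(len(epochs.trials), dtype=bool)


def test_responsiveness(epochs: ViewingEpochs, alpha: float = 0.01) -> pd.DataFrame:
    """Paired t-test of post-stimulus response vs pre-stimulus baseline.

    p-values are pooled across every electrode passed in (the intended call
    pools electrodes across patients) and BH-FDR controlled.
    """
    ok = _clean_trials(epochs)
    if ok.sum() < 10:
        raise ValueError("need at least 10 artifact-free trials")
    resp = _window_mean(epochs, RESPONSE_WINDOW)[:, ok]
    base = _window_mean(epochs, BASELINE_WINDOW)[:, ok]
    tvals, pvals = sps.ttest_rel(resp, base, axis=1)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    tvals = np.where(np.isfinite(tvals), tvals, 0.0)
    reject, qvals = bh_fdr(pvals, alpha=alpha)
    return pd.DataFrame(
        dict(electrode_id=epochs.channel_ids, t=tvals, p=pvals, q=qvals, responsive=reject)
    )


def response_latency(
    epochs: ViewingEpochs,
    electrode: int | str,
    alpha: float = 0.05,
    min_duration_ms: float = 50.0,
) -> float:
    """Earliest sustained significant post-stimulus time point, in ms.

    Each post-stimulus sample is compared against the per-trial scalar
    baseline mean with a paired t-test; the latency is the start of the
    first run of p < alpha lasting at least min_duration_ms. NaN when no
    such run exists.
    """
    idx = (
        epochs.channel_ids.index(electrode) if isinstance(electrode, str) else electrode
    )
    ok = _clean_trials(epochs)
    base = _window_mean(epochs, BASELINE_WINDOW)[idx, ok]
    data = epochs.data[idx, ok, :]
    post = epochs.times >= 0.0
    diffs = data[:, post] - base[:, None]
    n = diffs.shape[0]
    mu = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = mu / (sd / np.sqrt(n))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=n - 1)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    sig = pvals < alpha
    need = int(round(min_duration_ms / 1000.0 * epochs.rate))
    run = 0
    post_times = epochs.times[post]
    for k, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= need:
            return float(post_times[k - need + 1] * 1000.0)
    return float("nan")


def test_category_selectivity(
    epochs: ViewingEpochs,
    responsive: pd.Series | np.ndarray,
    anatomical_labels: dict[str, str] | pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sample t-test of per-trial dB responses, faces vs places.

    Tested on visually responsive electrodes; BH-FDR across that set; a
    significant electrode located anatomically outside V1/V2 is labeled
    face- or place-selective by the sign of the difference.
    """
    labels = dict(anatomical_labels)
    responsive = np.asarray(responsive, dtype=bool)
    ok = _clean_trials(epochs)
    cats = epochs.trials["category"].to_numpy()
    is_face = ok & (cats == FACE)
    is_place = ok & (cats == PLACE)
    if not is_face.any() or not is_place.any():
        raise ValueError("both categories required")
    resp = _window_mean(epochs, RESPONSE_WINDOW)
    resp_db = 10.0 * np.log10(np.maximum(resp, 1e-12))

    rows = []
    test_idx = [i for i, r in enumerate(responsive) if r]
    pvals, tvals = [], []
    for i in test_idx:
        t, p = sps.ttest_ind(resp_db[i, is_face], resp_db[i, is_place], equal_var=True)
        pvals.append(p if np.isfinite(p) else 1.0)
        tvals.append(t if np.isfinite(t) else 0.0)
    if test_idx:
        reject, qvals = bh_fdr(pvals, alpha=alpha)
    else:
        reject, qvals = np.array([], bool), np.array([])

    by_idx = {i: k for k, i in enumerate(test_idx)}
    for i, cid in enumerate(epochs.channel_ids):
        if i in by_idx:
            k = by_idx[i]
            early = labels.get(cid) in ("V1", "V2")
            sig = bool(reject[k]) and not early
            label = ""
            if sig:
                label = FACE if tvals[k] > 0 else PLACE
            rows.append(dict(electrode_id=cid, t=tvals[k], p=pvals[k], q=qvals[k],
                             selective=sig, selective_category=label))
        else:
            rows.append(dict(electrode_id=cid, t=np.nan, p=np.nan, q=np.nan,
                             selective=False, selective_category=""))
    return pd.DataFrame(rows)


def compute_csi(mean_resp_faces: float, mean_resp_places: float) -> float:
    """Category selectivity index: (Rf - Rp) / (Rf + Rp), in [-1, 1]."""
    if mean_resp_faces < 0 or mean_resp_places < 0:
        raise ValueError("category response means must be non-negative")
    denom = mean_resp_faces + mean_resp_places
    if denom == 0:
        raise ValueError("both category means are zero; CSI undefined")
    return (mean_resp_faces - mean_resp_places) / denom


def category_response_means(epochs: ViewingEpochs) -> pd.DataFrame:
    """Per-electrode category means normalized by the maximal item response.

    The normalizer is the electrode's largest per-item mean response in the
    100-500 ms window (it cancels in the CSI ratio but keeps the means on a
    comparable unitless scale).
    """
    ok = _clean_trials(epochs)
    resp = _window_mean(epochs, RESPONSE_WINDOW)
    items = epochs.trials["item_id"].to_numpy()
    cats = epochs.trials["category"].to_numpy()
    rows = []
    for i, cid in enumerate(epochs.channel_ids):
        item_means = {
            it: resp[i, ok & (items == it)].mean() for it in np.unique(items[ok])
        }
        max_resp = max(item_means.values())
        if max_resp <= 0:
            max_resp = 1.0
        rf = resp[i, ok & (cats == FACE)].mean() / max_resp
        rp = resp[i, ok & (cats == PLACE)].mean() / max_resp
        rows.append(dict(electrode_id=cid, mean_resp_faces=rf, mean_resp_places=rp))
    return pd.DataFrame(rows)


def rank_items(epochs: ViewingEpochs, electrode: int | str, k: int = 10) -> dict:
    """Items ordered by mean viewing response (dB), with top/bottom-k sets.

    Ties break deterministically by item_id. With 28 items and k=10 the
    8 middle 'borderline' exemplars belong to neither set.
    """
    idx = (
        epochs.channel_ids.index(electrode) if isinstance(electrode, str) else electrode
    )
    ok = _clean_trials(epochs)
    resp = _window_mean(epochs, RESPONSE_WINDOW)[idx]
    items = epochs.trials["item_id"].to_numpy()
    uniq = sorted(np.unique(items[ok]))
    if k > len(uniq) // 2:
        raise ValueError("k exceeds half the item count")
    means = {it: 10.0 * np.log10(max(resp[ok & (items == it)].mean(), 1e-12)) for it in uniq}
    # stable sort: descending response, ascending item_id on ties
    ranking = sorted(uniq, key=lambda it: (-means[it], it))
    return dict(ranking=ranking, top=ranking[:k], bottom=ranking[-k:], means=means)


def assign_groups(profiles: pd.DataFrame,
                  anatomical_labels: dict[str, str] | pd.Series) -> pd.Series:
    """Partition responsive electrodes into the five analysis groups.

    V1/V2: anatomical label and latency <= 180 ms. Face/place-selective:
    significant category preference outside V1/V2. Intermediate: responsive,
    retinotopic-intermediate label, not selective. Everything else
    responsive: 'other'. Non-responsive electrodes get no group.
    """
    labels = dict(anatomical_labels)
    groups = []
    for _, row in profiles.iterrows():
        cid = row["electrode_id"]
        if cid not in labels:
            raise ValueError(f"missing anatomical label for {cid}")
        if not row["responsive"]:
            groups.append("")
            continue
        anat = labels[cid]
        lat = row["latency_ms"]
        if anat in ("V1", "V2") and np.isfinite(lat) and lat <= EARLY_VISUAL_MAX_LATENCY_MS:
            groups.append(anat)
        elif row["selective"]:
            groups.append(f"{row['selective_category']}_selective")
        elif anat == "intermediate":
            groups.append("intermediate")
        else:
            groups.append("other")
    return pd.Series(groups, index=profiles.index, name="group")


def build_selectivity_profiles(
    epochs: ViewingEpochs,
    anatomical_labels: dict[str, str] | pd.Series,
    alpha_responsive: float = 0.01,
    alpha_selective: float = 0.01,
    k_items: int = 10,
) -> pd.DataFrame:
    """Full per-electrode selectivity profile table.

    Columns: responsiveness (flag, q), latency_ms, category means, csi,
    selectivity (flag, q, category), group, preferred category, and the
    top/bottom item sets (comma-joined).
    """
    resp = test_responsiveness(epochs, alpha=alpha_responsive)
    sel = test_category_selectivity(
        epochs, resp["responsive"], anatomical_labels, alpha=alpha_selective
    )
    means = category_response_means(epochs)
    prof = resp.merge(sel, on="electrode_id", suffixes=("_resp", "_sel"))
    prof = prof.merge(means, on="electrode_id")

    lat = []
    for i, r in enumerate(prof["responsive"]):
        lat.append(response_latency(epochs, i) if r else float("nan"))
    prof["latency_ms"] = lat
    prof["csi"] = [
        compute_csi(rf, rp) if rf + rp > 0 else np.nan
        for rf, rp in zip(prof["mean_resp_faces"], prof["mean_resp_places"])
    ]
    prof["group"] = assign_groups(prof, anatomical_labels)
    prof["preferred_category"] = prof["group"].map(
        {"face_selective": FACE, "place_selective": PLACE}
    ).fillna("")

    can_rank = len(set(epochs.trials["item_id"])) >= 2 * k_items
    tops, bottoms = [], []
    for i in range(len(prof)):
        if can_rank:
            r = rank_items(epochs, i, k=k_items)
            tops.append(",".join(r["top"]))
            bottoms.append(",".join(r["bottom"]))
        else:
            tops.append("")
            bottoms.append("")
    prof["top_items"] = tops
    prof["bottom_items"] = bottoms
    return prof
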