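"""End-to-end orchestration: simulate -> preprocess -> HFB -> classify ->
baseline-shift, event-locked and spectral analyses, with a machine-readable
summary.

A run is fully determined by its configuration and seed: the global seed is
fanned out to the schedule, cohort, recording and analysis stages through a
named seed derivation, so stages can be re-run independently and two runs
with the same configuration produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline_shift as bs
from . import classify as cl
from . import event_locked as ev
from . import spectral as sp
from .hfb import BandSpec, hfb_amplitude, normalize_to_rest, to_db, epoch_viewing
from .preprocessing import (
    common_average_reference,
    detect_bad_channels,
    detect_transient_artifacts,
    notch_line_noise,
)
from .stats import MixedModelSpec, mixed_anova
from .synthetic import (
    make_default_cohort,
    make_task_schedule,
    simulate_recording,
    write_dataset,
)

log = logging.getLogger("recallshift")


@dataclass
class PipelineConfig:
    """Everything that determines a run. Thresholds default to the analysis
    conventions documented in each module."""

    seed: int = 0
    out_dir: str = "recallshift_out"
    # synthetic cohort
    n_runs: int = 2
    n_items_per_category: int = 7
    n_face: int = 5
    n_place: int = 5
    n_v1: int = 2
    n_v2: int = 2
    n_intermediate: int = 2
    n_other: int = 1
    n_roi_frontal: int = 1
    n_roi_parietal: int = 1
    baseline_shift_db: float = 0.3
    transient_db: float = 0.17
    intrusion_rate: float = 0.115
    recall_rate_hz: float = 0.10
    rest_s: float = 200.0
    recall_block_s: float = 150.0
    # preprocessing / extraction
    line_hz: float = 60.0
    alpha_responsive: float = 0.01
    alpha_selective: float = 0.01
    # analysis toggles and sizes
    n_perm: int = 1000
    run_event_locked: bool = True
    run_spectra: bool = True
    run_mixed_model: bool = True
    write_signals: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _stage_seed(base: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (stable across processes)."""
    import zlib

    h = np.random.SeedSequence([base, zlib.crc32(stage.encode())]).generate_state(1)[0]
    return int(h % 2**31)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _cluster_report(result: ev.ClusterTestResult) -> dict:
    return {
        "n_permutations": result.n_permutations,
        "threshold_p": result.threshold_p,
        "clusters": [
            {"start_s": c.start_s, "end_s": c.end_s, "mass": round(c.mass, 6),
             "p_corrected": c.p_corrected}
            for c in result.clusters
        ],
        "significant": [
            {"start_s": c.start_s, "end_s": c.end_s, "p_corrected": c.p_corrected}
            for c in result.significant()
        ],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write intermediates + summary.json.

    Returns the summary dictionary. Stage failures raise with a
    stage-tagged message; optional analyses that are impossible on the
    realized dataset (e.g. no intrusions drawn) are skipped with a logged
    reason recorded in the summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(asdict(config)), "skipped": {}}

    # --- simulate -----------------------------------------------------------
    log.info("stage simulate")
    schedule = make_task_schedule(
        n_runs=config.n_runs, n_items_per_category=config.n_items_per_category,
        seed=_stage_seed(config.seed, "schedule"),
        intrusion_rate=config.intrusion_rate,
        recall_rate_hz=config.recall_rate_hz,
        rest_s=config.rest_s, recall_block_s=config.recall_block_s)
    cohort = make_default_cohort(
        schedule, seed=_stage_seed(config.seed, "cohort"),
        n_face=config.n_face, n_place=config.n_place, n_v1=config.n_v1,
        n_v2=config.n_v2, n_intermediate=config.n_intermediate,
        n_other=config.n_other, n_roi_frontal=config.n_roi_frontal,
        n_roi_parietal=config.n_roi_parietal,
        baseline_shift_db=config.baseline_shift_db,
        transient_db=config.transient_db)
    dataset = simulate_recording(schedule, cohort,
                                 seed=_stage_seed(config.seed, "recording"),
                                 line_hz=config.line_hz)
    events = dataset.events()
    events.to_csv(out / "events.tsv", sep="\t", index=False, float_format="%.6f")
    dataset.electrode_table.to_csv(out / "electrodes.tsv", sep="\t", index=False,
                                   float_format="%.3f")
    if config.write_signals:
        write_dataset(dataset, out / "dataset")
    truth = {gt.electrode_id: gt for gt in dataset.ground_truth}
    summary["n_electrodes"] = len(cohort)
    summary["n_recall_events"] = int((events["event_type"] == "recall").sum())
    summary["n_intrusions"] = int(events["is_intrusion"].sum())
    summary["n_prompts"] = int((events["event_type"] == "prompt").sum())

    # --- preprocess ---------------------------------------------------------
    log.info("stage preprocess")
    rec = notch_line_noise(dataset.recording, line_hz=config.line_hz)
    rec = common_average_reference(rec)
    bad = detect_bad_channels(rec)
    mask = detect_transient_artifacts(rec)
    mask.bad_channels = bad
    summary["bad_channels"] = bad
    summary["masked_fraction"] = float(mask.excluded.mean())
    pd.DataFrame(mask.intervals(rec.rate), columns=["start_s", "end_s"]).to_csv(
        out / "artifact_mask.tsv", sep="\t", index=False, float_format="%.6f")

    # --- HFB ----------------------------------------------------------------
    log.info("stage hfb")
    hfb_v = hfb_amplitude(rec, BandSpec(), mask=mask)
    rest_intervals = [run.rest_interval for run in schedule.runs]
    run_intervals = [(run.rest_interval[0], run.end) for run in schedule.runs]
    # pad the last run interval to the end of the recording
    run_intervals[-1] = (run_intervals[-1][0], rec.duration)
    hfb_ratio = normalize_to_rest(hfb_v, rest_intervals, mask=mask,
                                  run_intervals=run_intervals)
    hfb_db = to_db(hfb_ratio)
    if config.write_signals:
        df = pd.DataFrame(hfb_db.amplitude.T, columns=hfb_db.channel_ids)
        df.insert(0, "time_s", hfb_db.times())
        df.to_csv(out / "hfb_db.tsv", sep="\t", index=False, float_format="%.5f")

    # --- classification -----------------------------------------------------
    log.info("stage classify")
    epochs = epoch_viewing(hfb_v, events, mask=mask)
    anat = dict(zip(dataset.electrode_table["name"], dataset.electrode_table["group"]))
    profiles = cl.build_selectivity_profiles(
        epochs, anat, alpha_responsive=config.alpha_responsive,
        alpha_selective=config.alpha_selective)
    profiles.to_csv(out / "profiles.tsv", sep="\t", index=False, float_format="%.6f")
    summary["n_responsive"] = int(profiles["responsive"].sum())
    summary["groups"] = profiles.groupby("group", observed=True)["electrode_id"].count().to_dict()
    truth_groups = {cid: truth[cid].group for cid in profiles["electrode_id"]}
    assigned = dict(zip(profiles["electrode_id"], profiles["group"]))
    vis_ids = [cid for cid, g in truth_groups.items()
               if g in ("V1", "V2", "intermediate", "face_selective", "place_selective")]
    summary["group_recovery_rate"] = float(
        np.mean([assigned[cid] == truth_groups[cid] for cid in vis_ids]))

    preferred = dict(zip(profiles["electrode_id"], profiles["preferred_category"]))

    # --- baseline shift -----------------------------------------------------
    log.info("stage baseline_shift")
    medians = bs.median_recall_amplitude(hfb_db, events, mask=mask)
    medians_excl = bs.median_recall_amplitude(hfb_db, events, mask=mask,
                                              exclude_recalls=True)
    sel = bs.selectivity_db(medians, preferred)
    sel_excl = bs.selectivity_db(medians_excl, preferred)
    shift_table = medians.merge(
        medians_excl, on="electrode_id", suffixes=("", "_excl"))
    shift_table["selectivity_db"] = shift_table["electrode_id"].map(sel)
    shift_table["selectivity_db_excl"] = shift_table["electrode_id"].map(sel_excl)
    stage = bs.stage_gain(hfb_db, events, preferred, mask=mask)
    if len(stage):
        shift_table = shift_table.merge(stage, on="electrode_id", how="left")
    shift_table.to_csv(out / "baseline_shift.tsv", sep="\t", index=False,
                       float_format="%.6f")
    summary["selectivity_db_mean"] = float(sel.mean()) if len(sel) else None
    summary["selectivity_db_excl_mean"] = float(sel_excl.mean()) if len(sel_excl) else None
    summary["stage_gains_mean"] = {
        k: float(stage[k].mean()) for k in bs.STAGE_NAMES} if len(stage) else None

    try:
        rho, p = bs.csi_shift_correlation(profiles, medians)
        summary["csi_shift_spearman"] = {"rho": rho, "p": p}
    except ValueError as e:
        summary["skipped"]["csi_shift_correlation"] = str(e)

    # percentile-gain dynamics on preferred vs non-preferred block traces
    try:
        gain_profiles = []
        blocks = bs.recall_blocks(events)
        good = ~mask.excluded[: hfb_db.n_samples]
        for cid, p_cat in preferred.items():
            if p_cat not in ("face", "place"):
                continue
            i = hfb_db.channel_ids.index(cid)
            pref_samples, nonpref_samples = [], []
            for _, blk in blocks.iterrows():
                i0 = int(blk["start"] * hfb_db.rate)
                i1 = int(blk["end"] * hfb_db.rate)
                seg = hfb_db.amplitude[i, i0:i1][good[i0:i1]]
                (pref_samples if blk["target_category"] == p_cat
                 else nonpref_samples).append(seg)
            gain_profiles.append(bs.percentile_gain_profile(
                np.concatenate(pref_samples), np.concatenate(nonpref_samples)))
        dyn = bs.classify_dynamics(gain_profiles)
        summary["dynamics"] = {
            "label": dyn.label, "overall_p": dyn.overall_p, "kw_p": dyn.kw_p,
            "mean_gain_db": dyn.mean_gain_db,
            "bin_gains_db": _jsonable(dyn.bin_gains_db)}
        (out / "dynamics.json").write_text(
            json.dumps(_jsonable(summary["dynamics"]), indent=1, sort_keys=True))
    except ValueError as e:
        summary["skipped"]["dynamics"] = str(e)

    order_table = bs.recall_order_analysis(hfb_ratio, events, preferred, mask=mask)
    order_table.to_csv(out / "recall_order.tsv", sep="\t", index=False,
                       float_format="%.6f")
    summary["recall_order_effect_db"] = bs.recall_order_effect(order_table)

    # --- mixed model --------------------------------------------------------
    if config.run_mixed_model:
        log.info("stage mixed_model")
        try:
            long = medians.melt(id_vars="electrode_id",
                                value_vars=["median_face_db", "median_place_db"],
                                var_name="category", value_name="median_db")
            long["category"] = long["category"].str.replace("median_", "").str.replace("_db", "")
            long["group"] = long["electrode_id"].map(preferred)
            long = long[long["group"].isin(["face", "place"])]
            pat = dict(zip(dataset.electrode_table["name"],
                           dataset.electrode_table["patient"]))
            long["patient"] = long["electrode_id"].map(pat)
            long = long.rename(columns={"electrode_id": "electrode", "median_db": "y"})
            effects = mixed_anova(
                long, MixedModelSpec(response="y", fixed=("group", "category")),
                method="aggregate")
            summary["mixed_model"] = [
                {"effect": e.effect, "F": e.f, "df1": e.df1, "df2": e.df2, "p": e.p}
                for e in effects]
        except Exception as e:  # noqa: BLE001 - surfaced, not fatal
            summary["skipped"]["mixed_model"] = f"{type(e).__name__}: {e}"

    # --- event-locked -------------------------------------------------------
    if config.run_event_locked:
        log.info("stage event_locked")
        seed = _stage_seed(config.seed, "event_locked")
        try:
            res, _ = ev.recall_timecourse(hfb_db, events, preferred,
                                          n_perm=config.n_perm, seed=seed)
            summary["recall_clusters"] = _cluster_report(res)
        except ValueError as e:
            summary["skipped"]["recall_timecourse"] = str(e)
        try:
            res, _, _ = ev.intrusion_timecourse(hfb_db, events, preferred,
                                                n_perm=config.n_perm, seed=seed)
            summary["intrusion_clusters"] = _cluster_report(res)
        except ValueError as e:
            summary["skipped"]["intrusion_timecourse"] = str(e)
        try:
            res, _, _ = ev.prompt_timecourse(hfb_db, events, preferred,
                                             n_perm=config.n_perm, seed=seed)
            summary["prompt_clusters"] = _cluster_report(res)
        except ValueError as e:
            summary["skipped"]["prompt_timecourse"] = str(e)
        try:
            roi_members: dict[str, list[str]] = {}
            for _, row in dataset.electrode_table.iterrows():
                if row["group"] in ("frontal", "parietal"):
                    roi_members.setdefault(row["group"], []).append(row["name"])
            if roi_members:
                _, bins, _ = ev.roi_event_response(hfb_db, events, roi_members)
                bins.to_csv(out / "roi_bins.tsv", sep="\t", index=False,
                            float_format="%.6f")
                summary["roi_transient_minus_baseline_db"] = float(
                    (bins["transient_bin"] - bins["baseline_bin"]).mean())
            else:
                summary["skipped"]["roi_event_response"] = "no ROI electrodes"
        except ValueError as e:
            summary["skipped"]["roi_event_response"] = str(e)

    # --- spectra ------------------------------------------------------------
    if config.run_spectra:
        log.info("stage spectra")
        try:
            lfp = sp.lfp_condition_spectra(rec, events, mask=mask)
            for cond, g in lfp["gains"].items():
                g.to_csv(out / f"lfp_gain_{cond}.tsv", sep="\t", index=False,
                         float_format="%.6f")
            summary["lfp_recall_vs_iri_mean_gain_db"] = float(
                lfp["gains"]["recall_vs_iri"]
                .query("freq_hz >= 1 and freq_hz <= 9")["mean_gain_db"].mean())
        except ValueError as e:
            summary["skipped"]["lfp_spectra"] = str(e)
        try:
            slow = sp.hfb_fluctuation_spectra(hfb_ratio, events, mask=mask)
            for cond, g in slow["gains"].items():
                g.to_csv(out / f"hfb_slow_gain_{cond}.tsv", sep="\t", index=False,
                         float_format="%.6f")
            rg = slow["gains"]["recall"]
            sig_f = rg[rg["significant"]]["freq_hz"]
            summary["hfb_slow_significant_hz"] = (
                [float(sig_f.min()), float(sig_f.max())] if len(sig_f) else None)
        except ValueError as e:
            summary["skipped"]["hfb_fluctuation_spectra"] = str(e)

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=1, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
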