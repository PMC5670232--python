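# recallshift

Analysis pipeline for sustained **baseline shifts** in human intracranial
ECoG during episodic free recall, driven end-to-end by a synthetic-ECoG
generator so that every stage is verifiable by parameter recovery.

## The scientific problem

When people freely recall items from a target category ("recall the faces
you saw"), category-selective visual cortex raises its high-frequency
broadband (HFB, 60–160 Hz) amplitude *tonically* for as long as the category
is being targeted — a small (fractions of a dB), sustained baseline shift —
on top of which brief transients accompany individual recollections. The
analytical challenge is to distinguish a genuine tonic shift from the
accumulation of many transient recall-locked bursts over a long (150 s)
recall block, using only the statistics of the amplitude trace.

The package implements the full chain for multichannel ECoG sampled at
500 Hz:

1. **Preprocessing** — zero-phase FIR notch filters at the mains frequency
   and harmonics; common-average re-referencing; rejection of channels whose
   extreme-voltage tail (mean |V| above the channel's 99th percentile)
   exceeds 500 µV; masking of 200 ms windows around samples where ≥10% of
   electrodes exceed 5 SD or a 30 µV/ms gradient.
2. **HFB extraction** — five 20 Hz band-pass filters (60–160 Hz, order-138
   Hamming FIR, zero phase), Hilbert envelopes, per-band mean normalization
   (flattening the 1/f spectral decay), averaging, and rescaling to volts.
   Recall analyses divide by the geometric mean over each run's 200-s rest
   period and work in dB (10·log10 of the amplitude ratio, which normalizes
   the log-normal HFB amplitude distribution).
3. **Electrode classification** — visual responsiveness (paired t of the
   100–500 ms response vs the −400..−100 ms pre-stimulus baseline, BH-FDR
   α = 0.01 pooled over all electrodes), response latency (first p < 0.05
   sustained ≥ 50 ms), category selectivity (two-sample t on dB responses,
   BH-FDR α = 0.01), and the category selectivity index

   CSI = (R̄_faces − R̄_places) / (R̄_faces + R̄_places) ∈ [−1, 1],

   with electrode groups V1 / V2 (anatomical label and latency ≤ 180 ms),
   face-/place-selective, intermediate, other.
4. **Baseline-shift analysis** — the median normalized HFB amplitude per
   150-s recall block (averaged over runs), its preferred-minus-non-preferred
   selectivity, early/middle/late stage gains, the CSI-vs-shift Spearman
   correlation, a recall-exclusion control (removing 2 s before onset to
   offset of every overt recollection), and the burst-vs-shift
   discrimination: injecting either sporadic 2 dB bursts (smoothed by a 3-s
   Gaussian window) or a constant 0.1 dB gain into a log-normal trace and
   comparing amplitude gains across the deciles of the amplitude
   distribution. A constant shift raises every decile equally
   (Kruskal–Wallis across bins non-significant, signed-rank on the overall
   gain significant); bursts load the top deciles.
5. **Event-locked analysis** — recall-onset, intrusion-error, and
   experimenter-prompt triggered averages (1000 ms triangular smoothing,
   −5..+7 s windows, 5-s separation filter) with cluster-based permutation
   correction (cluster mass = sum of |t|, labels shuffled over electrodes).
6. **Spectral analysis** — multitaper PSDs (Slepian tapers): raw LFP in
   1–50 Hz (5-s segments, K = 7) across rest / viewing / recall events /
   inter-recall intervals, and ultra-slow (<2 Hz) fluctuations of the
   normalized HFB amplitude (25-s segments, K = 4, half-bandwidth 0.1 Hz),
   with rest-relative dB gains tested per frequency (signed-rank, BH-FDR).
7. **Statistics** — BH-FDR, Wilcoxon signed-rank (exact enumeration for
   small n), Kruskal–Wallis, Spearman, and the group-level mixed model
   Y ~ group × category + (1 | patient/electrode).

Because the original patient recordings are not publicly deposited, the
package ships a first-class **synthetic generator** that emulates the task
(200-s rest; 14 pictures × 4 repetitions at 1500 ms on / 750 ms ISI; 40-s
distraction; two 150-s recall blocks per run, category order
counter-balanced over two runs) and the signal model (1/f background noise
plus a 60–160 Hz carrier whose amplitude is log-normal with AR(1) log-
envelope, modulated by viewing responses, sustained recall-block gains,
recall-locked transients, pre-intrusion collapses and prompt dips).

## Worked example

```sh
recallshift run --seed 7 --out out/
```

runs the full pipeline on the default synthetic cohort (19 electrodes:
5 face-selective, 5 place-selective, 2 V1, 2 V2, 2 intermediate, 1 other,
2 frontal/parietal; injected 0.3 dB baseline shifts and 0.17 dB recall
transients) and prints

```json
{
 "out_dir": "out/",
 "n_responsive": 19,
 "dynamics_label": "baseline_shift_like",
 "selectivity_db_mean": 0.20646738862540173
}
```

`out/summary.json` holds the full machine-readable report. In this run the
group assignment recovered the ground-truth group of every visually
responsive electrode (`group_recovery_rate: 1.0`); the median recall
amplitude was 0.206 dB higher for each group's preferred category (below
the injected 0.3 dB because the generator also collapses the shift around
intrusions and prompts, as observed in the real data); viewing CSI and
recall selectivity correlated at Spearman ρ = 0.85; the percentile-gain
analysis labeled the cohort `baseline_shift_like` (overall signed-rank
p = 0.004, Kruskal–Wallis across deciles p = 0.98); and the mixed-model
group × category interaction was significant (F = 15.7, p = 0.001).
Per-stage tables (`profiles.tsv`, `baseline_shift.tsv`, `recall_order.tsv`,
cluster and spectra reports) are written next to it.

The library surface mirrors these stages; see `recallshift/__init__.py`
for the public API and `docs/methods.md` for the modeling choices.

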