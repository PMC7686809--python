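# msmod

Resting-state EEG microstate analysis with a moderation-statistics
layer, plus a ground-truth simulator that makes the whole chain
verifiable without access to raw study data.

## What problem this addresses

Scalp EEG at rest passes through a small set of quasi-stable
topographies ("microstates", classically four: MS1–MS4) lasting tens of
milliseconds. Their temporal parameters — mean **duration**,
**occurrence** rate, time **contribution**, and the directed
**transition probabilities** between states — index large-scale brain
network dynamics, and individual differences in them have been related
to traits such as creativity. Whether such a relationship holds can
itself depend on a third variable: for example, self-esteem may
*moderate* the link between microstate dynamics and trait creativity,
so the association is positive for low-self-esteem individuals and
negative for high. `msmod` implements both halves of that research
program for psychophysiologists and methodologists:

1. **Microstate pipeline** — band-pass (2–20 Hz), average reference,
   2-s epoching with ±80 μV rejection; scalp maps at GFP peaks
   clustered by polarity-invariant atomize–agglomerate hierarchical
   clustering (AAHC); model order chosen by the predictive
   cross-validation criterion CV = σ̂²·((N−1)/(N−1−K))²; every sample
   backfit to the template of highest |spatial correlation|
   (GMD² = 2(1−C)); the 24 temporal parameters computed per subject.
2. **Moderation layer** — for outcome Y, predictor X (a microstate
   parameter), moderator W and covariates sex/age:
   `Y = b0 + b1·Xc + b2·Wc + b3·Xc·Wc + b4·sex + b5·age + e`,
   with the interaction judged by ΔR² and F(1, n−6), simple slopes at
   W = mean ± 1 sd, analytic Johnson–Neyman regions of significance,
   and Benjamini–Hochberg FDR across the 24-test family.
3. **Simulator** — semi-Markov switching between smooth topographies
   under a rectified alpha envelope plus white sensor noise, and
   behavioral cohorts with planted, analytically known moderation
   effects.

See `docs/methods.md` for the full model description and design
choices.

## Worked example

```python
import numpy as np
from msmod import (SimulationConfig, simulate_subject_eeg, bandpass_filter,
                   average_reference, epoch_and_reject, extract_peak_maps,
                   aahc_cluster, order_templates_canonically, backfit_labels,
                   temporal_statistics)

cfg = SimulationConfig(n_channels=64, sampling_rate=250, record_duration=60, seed=1)
rec, truth = simulate_subject_eeg(cfg)                 # 60 s, SNR 3
rec = average_reference(bandpass_filter(rec, 2.0, 20.0))
epochs = epoch_and_reject(rec, epoch_ms=2000, threshold_uv=80)
print(f"kept {epochs.n_epochs} epochs")

peaks = extract_peak_maps(epochs, max_peaks=5000, seed=1)
sets = aahc_cluster(peaks, k_range=range(1, 9))
ts, _ = order_templates_canonically(sets[4])
print(f"k=4: GEV={sets[4].gev:.3f}, CV={sets[4].cv_value:.2f}")
print("recovery |C| per planted map:",
      np.round(np.abs(ts.maps @ truth.templates.T).max(axis=0), 3))

stats = temporal_statistics(backfit_labels(epochs, ts))
print("contribution:", np.round(stats.contribution, 3))
```

prints

```
kept 30 epochs
k=4: GEV=0.891, CV=27.07
recovery |C| per planted map: [0.999 0.998 0.999 0.998]
contribution: [0.269 0.231 0.241 0.26 ]
```

GEV 0.891 means the four templates explain 89% of the GFP²-weighted
topographic variance of this subject; each recovered map correlates
≥ 0.998 with the planted one; the four states cover 23–27% of the
recording each. (Mean durations from unsmoothed sample-by-sample
labeling are short at this noise level — pass
`backfit_labels(..., min_duration_ms=30)` to merge noise-fragmented
runs; see the methods note.)

The moderation layer consumes a per-subject statistics table plus a
behavioral table (`wcts_total`, subscales, `rses`, `sex`, `age`):

```python
from msmod import run_moderation_battery
report, results = run_moderation_battery(stats_table, behavior)
# report: 24 rows with delta_r2, F, p_uncorrected, p_fdr;
# results["duration_ms2"].slopes / .jn for significant parameters
```

Everything is also scriptable from the shell:

```sh
msmod run-all --seed 1 --out run1          # simulate -> ... -> moderate
msmod simulate --seed 1 --out subj_raw.fif
msmod moderate --stats stats.csv --behavior beh.csv --out report.csv
```

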