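# Methods

## Overview

`msmod` implements a complete resting-state EEG microstate analysis with
a moderated-regression layer on top. The scientific question the
pipeline serves: do the temporal dynamics of the four classical
microstate classes (MS1–MS4) predict a trait score (here, trait
creativity measured by a 50-item scale), and is that relationship
conditional on a moderator (self-esteem on the 10–40 Rosenberg scale)?
Because raw data for such studies are rarely deposited, the package
ships a generator that produces microstate-structured EEG and behavioral
cohorts with known ground truth, so every stage can be validated
end-to-end.

## Microstate segmentation

**GFP and peak maps.** The global field power is the spatial standard
deviation of the scalp map at each sample,
GFP(t) = sqrt(1/N · Σᵢ (vᵢ(t) − v̄(t))²). Only maps at strict local
maxima of the GFP series enter clustering (plateaus count once at their
first sample; endpoints never count): these are the moments of maximal
topographic signal-to-noise. Peak detection runs per epoch, so no peak
straddles an epoch boundary. A seeded uniform subsample caps the number
of peak maps per subject (default 5,000) to bound the quadratic cost of
clustering; a 6-minute recording yields roughly 2·f_alpha peaks per
second, ~7,000 at 10 Hz.

**Similarity.** Map similarity is the Pearson correlation C of the
mean-removed maps; the global map dissimilarity on GFP-normalized maps
satisfies GMD² = 2(1 − C) exactly, so the two are interchangeable.
Polarity is disregarded throughout clustering and backfitting (|C|),
because the generators of a topography reverse sign within every
oscillatory cycle.

**AAHC.** Atomize–agglomerate hierarchical clustering starts from one
cluster per peak map. At each step the cluster contributing least
GFP²-weighted explained variance — Σ_members (GFP·|C| to own template)² —
is dissolved, and each orphan map is reassigned to the surviving cluster
with which it correlates best. Cluster templates are the dominant
eigenvector of the members' outer-product sum (the polarity-invariant
centroid), with the deterministic sign convention that the
largest-magnitude channel is positive. All ties break to the lowest
index, making the procedure deterministic given input order. A template
set is recorded at every requested k on the way down.

**Model-order selection.** The predictive cross-validation criterion
CV = σ̂² · ((N−1)/(N−1−K))², with σ̂² the mean per-sample residual
variance after removing each map's projection onto its best-fitting
template, is minimized over k (lowest k wins ties). On generator output
the criterion recovers the true K reliably (20/20 seeds in the
validation suite).

**Two-level clustering.** The default is subject-level AAHC followed by
AAHC over the pooled subject templates ("group" level); clustering the
pooled peak maps directly is available by flag. Per-subject explained
variance (GEV = Σ(GFP·C)²/ΣGFP², computed over all samples with the
final labels) is reported as mean ± sd across subjects.

**Canonical naming.** When k = 4 the group maps are named MS1–MS4 by
solving the 4×4 assignment maximizing total |C| to built-in archetype
maps on a schematic disk layout: two diagonal gradients, an occipital
left-right-symmetric map and a fronto-central focal map. The assignment
is exact (Hungarian algorithm, verified against all 24 permutations).

## Backfitting and temporal statistics

Every sample of every kept epoch is labeled with the template of highest
|C| (ties to the lowest index; flat samples get label 0 with correlation
0). No temporal smoothing and no minimum-duration rejection are applied
by default — the labeling is purely spatial — and epochs are labeled
independently.

From the labeling: duration_k is the mean run length in ms, occurrence_k
the number of runs per analyzed second, contribution_k the fraction of
samples labeled k. Runs truncated at epoch edges are counted; this
choice preserves the identity contribution = occurrence × duration/1000
exactly on every input (tested property-based), at the cost of a small
downward bias of durations in 2-s epochs. Transition probabilities count
directed run-to-run changes within epochs only and are normalized per
row over observed departures (rows with no departures are zero and
flagged via the raw count matrix, which is also reported). For k = 4
this yields the 24 parameters consumed by the moderation stage: 4
durations, 4 occurrences, 4 contributions, 12 directed transitions.

## Moderated regression

For each microstate parameter X, with creativity total Y, self-esteem
total W and covariates sex (0/1) and age:

Y = b₀ + b₁X_c + b₂W_c + b₃X_c·W_c + b₄·sex + b₅·age + ε,

where X and W are mean-centered before forming the product. The
interaction is tested by ΔR² between this model and the one without the
product term, F(1, n−6) = ΔR²(n−6)/(1−R²_full). Standardized β values
come from refitting with z-scored Y, X, W (covariates untouched) — a
documented convention, since "β" is often reported without definition.

Screening drops subjects whose creativity or self-esteem total deviates
more than 3 sd from the full-sample mean (single pass, means and sds
from the unscreened table). The 24 interaction p-values are corrected by
the Benjamini–Hochberg step-up with family size 24; parameters passing
FDR < 0.05 get simple slopes at W = mean ± 1 sd and a Johnson–Neyman
analysis. The J–N boundaries solve |b₁ + b₃w| = t_crit·SE(w) as a
quadratic in w using the coefficient covariance; roots are reported only
inside the observed moderator range, in raw W units (the boundaries are
invariant to centering), with the percent of observed W at or beyond
each boundary (inclusive). A near-zero quadratic coefficient degenerates
to the linear solution; no real root means the effect is significant
everywhere or nowhere, decided by the slope test at the range midpoint.

## The synthetic generator

**EEG.** K spatially smooth, zero-mean, unit-norm topographies (pairwise
|C| ≤ 0.7; the first four perturb the canonical archetypes) succeed each
other as a semi-Markov chain: gamma dwell times (shape 2 by default, so
durations are unimodal with mode > 0, mean 80 ms) and an embedded
transition matrix given by row-normalizing nonnegative weights with zero
diagonal. Within a run the map is the active template scaled by a
rectified alpha oscillation (10 Hz, so GFP peaks arrive at ~20/s) with
onset-zero phase, shaped by a per-run Tukey window (α = 0.4) and floored
at 2% amplitude; polarity is redrawn per run. The boundary gating is
deliberate: real microstate transitions occur near GFP minima, and
abrupt full-amplitude map switches would smear into two-template mixture
maps under the 2–20 Hz zero-phase filter (measured: one-template
residual 23 μV² versus 3.1 μV² on the full planted basis, with a
filtered-noise floor of 3.3 μV²). The template signal is scaled so its
RMS is `snr` times the white-sensor-noise sd (default 3 × 5 μV);
`snr=inf` disables noise. Defaults describe a 64-channel, 500 Hz,
6-minute eyes-open session.

**Behavior.** Every parameter of a semi-Markov chain has a closed form:
with stationary run distribution π of the embedded chain and mean dwells
m_k, duration_k = m_k, occurrence_k = 1000·π_k/Σπ_jm_j,
contribution_k = π_km_k/Σπ_jm_j, transition_ij = P_ij. Subjects share
templates but get per-subject lognormal perturbations of dwell means
(σ = 0.15) and transition weights (σ = 0.20), giving every parameter a
continuous distribution across subjects; the analytic value is the
ground-truth X for the behavioral model. The creativity total is
b₀ + Σ(b₁X_c + b₂W_c + b₃X_c·W_c) + sex/age terms + N(0, 10), truncated
to 50–150 by resampling (no point mass at the bounds); self-esteem is
N(28.37, 2.81²) truncated to 10–40 the same way, sex is Bernoulli(0.72)
and age N(18.3, 0.84²). The default planted effect
(`duration_ms2`, b₁ = 0, b₂ = 1.0, b₃ = −0.06) produces a self-esteem ×
creativity correlation near 0.27, interaction ΔR² near 0.04 and simple
slopes near ±0.2 at mean ∓ 1 sd — the magnitudes typical of this
literature. The scale-noise sd of 10 points is a free choice; nothing in
the underlying design pins the creativity-total distribution.

**What the generator does not emulate.** No volume-conducted dipole
topographies (maps are smooth Gaussian-process draws on a schematic
layout), no ocular/muscle artifacts (the ±80 μV rejection is exercised
by noise excursions only, and no ICA step exists), no 1/f background or
non-alpha rhythms, and state dynamics are first-order semi-Markov.
Passing tests therefore validate the algorithms and their contracts, not
performance on measured EEG.

## Numerical choices and degenerate inputs

- Filter: 4th-order Butterworth band-pass applied forward–backward
  (`sosfiltfilt`), band 2–20 Hz; the realization is configurable.
- Epoching: contiguous, non-overlapping, starting at sample 0; trailing
  partial epoch discarded. Rejection uses absolute per-sample amplitude
  (not peak-to-peak), applied programmatically.
- Template sign: largest-|value| channel positive; tie-breaks
  everywhere: lowest index.
- Flat maps: similarity is an error where a defined value is required;
  backfitting assigns label 0 with correlation 0 so every sample stays
  labeled.
- CV criterion requires K < N−1; larger K raises an error (and is
  skipped when recording template sets during agglomeration).
- The J–N quadratic's leading coefficient is treated as zero below
  1e-12 relative to the problem scale.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  cohorts derive per-subject streams from a SeedSequence, so results are
  bit-reproducible.

## Design choices where the design was open

- **Fixed k = 4 in the pipeline default.** After band-pass filtering,
  peak maps are genuine mixtures of the planted templates (see above),
  which flattens the CV curve — a known weakness of predictive residual
  criteria on filtered switching signals. The pipeline therefore fixes
  the conventional four classes by default (`k_fixed: 4`), as applied
  microstate studies overwhelmingly do, while CV selection remains one
  config switch away and is validated on unfiltered generator output.
- **Truncated runs counted** in all three temporal statistics
  (preserves the c = o·d identity; discarding them would lose ~10% of
  2-s epochs).
- **Row-normalized transitions** (conditional on leaving state i)
  rather than normalization by total transitions; the count matrix is
  exported for anyone preferring the alternative.
- **Two-level clustering default** (subject then group), which is what
  produces an across-subject spread of explained variance.
- **FDR family = all 24 tests** of one battery.
- **Covariates in standardized refits stay raw**; only Y, X, W are
  z-scored.

## Problem sizes in the validation suite

The shipped tests and the acceptance script use scaled-down recordings
chosen to exercise every code path at comfortable statistical margins:
20–60 s at 250 Hz with 32–64 channels for segmentation checks (a 60-s,
64-channel subject yields ~1,300 peak maps, ample for AAHC at k ≤ 8),
10-s, 8-channel configs when only the analytic parameters matter, 20
seeds for model-order selection, 2,000–5,000 Monte-Carlo cohorts of
n = 335 for calibration of the interaction test, and a 12–20-subject
end-to-end pipeline run. Full-scale 6-minute, 64-channel, 500 Hz
cohorts run through the identical code paths via the default configs.

## Known limitations

- The CV criterion's behavior on band-passed data (above) means
  automatic model-order selection should be trusted only on data whose
  topography is near-piecewise-constant at GFP peaks.
- Durations are biased low by epoch-edge truncation (~4% at 80 ms dwell
  in 2-s epochs); all comparisons within the package use the same
  convention, so the moderation layer is unaffected.
- Backfitting is purely spatial; no smoothing means noisy samples can
  fragment runs at low SNR, inflating occurrence and deflating duration
  jointly (their product, the contribution, is more robust).
- The J–N sample percentages use inclusive boundaries; with heavily
  tied integer moderator scores the reported percentages depend on that
  choice.
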