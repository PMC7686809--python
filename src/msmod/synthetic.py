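"""Microstate-structured EEG and behavioral-cohort simulation.

The generator produces the two kinds of data the analysis consumes:

1. Multichannel resting-state EEG in which a small set of quasi-stable,
   polarity-alternating topographies succeed each other as a semi-Markov
   chain (gamma dwell times, embedded transition matrix), amplitude-
   modulated by a rectified alpha oscillation so that GFP peaks occur at
   roughly twice the alpha frequency, plus spatially white sensor noise.

2. A behavioral cohort (creativity total and subscales, self-esteem,
   sex, age) in which chosen microstate parameters predict the
   creativity score with a self-esteem-moderated interaction.

Because the dynamics are a semi-Markov chain, every microstate parameter
(duration, occurrence, contribution, transition probability) has a
closed-form generator-side value; :func:`analytic_parameters` exposes
these as the ground truth X used when planting behavioral effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortConfig, SimulationConfig
from .layout import canonical_archetypes, normalize_map, smooth_random_maps
from .preprocessing import Recording

__all__ = [
    "GroundTruth",
    "CohortGroundTruth",
    "generate_templates",
    "simulate_state_runs",
    "simulate_subject_eeg",
    "analytic_parameters",
    "parameter_names",
    "simulate_cohort",
]

_MAX_PAIRWISE_C = 0.7


@dataclass
class GroundTruth:
    """Generator-side truth for one simulated recording."""

    templates: np.ndarray                      # (K, n_channels) zero-mean unit-norm
    state_runs: list[tuple[int, int, int]]     # (state, onset, offset) half-open
    planted_coefficients: dict = field(default_factory=dict)

    def states_per_sample(self) -> np.ndarray:
        n = self.state_runs[-1][2]
        out = np.empty(n, dtype=int)
        for state, a, b in self.state_runs:
            out[a:b] = state
        return out


@dataclass
class CohortGroundTruth:
    templates: np.ndarray
    subject_parameters: pd.DataFrame           # analytic microstate parameters per subject
    planted_coefficients: list[tuple[str, float, float, float]]
    state_runs: list[list[tuple[int, int, int]]] | None = None


def parameter_names(n_states: int = 4) -> list[str]:
    """The canonical ordering of microstate parameters: durations,
    occurrences, contributions, then directed transitions."""
    ms = [f"ms{i + 1}" for i in range(n_states)]
    names = [f"duration_{m}" for m in ms]
    names += [f"occurrence_{m}" for m in ms]
    names += [f"contribution_{m}" for m in ms]
    names += [
        f"transition_{a}_{b}" for a in ms for b in ms if a != b
    ]
    return names


def generate_templates(n_channels: int, n_states: int, seed: int) -> np.ndarray:
    """Draw ``n_states`` smooth, zero-mean, unit-norm topographies.

    The first four mimic the canonical microstate orientations (two
    diagonal gradients, an occipital symmetric map, a fronto-central
    focal map) with a seeded smooth perturbation; further maps are smooth
    Gaussian-process draws. Pairwise |spatial correlation| is kept at or
    below 0.7 by rejection.
    """
    if n_states < 1 or n_channels < 2:
        raise ValueError("need n_states >= 1 and n_channels >= 2")
    if n_states > n_channels - 1:
        raise ValueError(
            "cannot build more than n_channels - 1 linearly independent "
            "zero-mean maps"
        )
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    base = canonical_archetypes(n_channels) if n_channels >= 4 else None

    def admissible(candidate: np.ndarray) -> bool:
        return all(abs(candidate @ m) <= _MAX_PAIRWISE_C for m in maps)

    k = 0
    attempts = 0
    while len(maps) < n_states:
        if base is not None and k < min(4, n_states):
            perturb = smooth_random_maps(1, n_channels, rng)[0]
            cand = normalize_map(base[k] + 0.15 * perturb)
        else:
            cand = smooth_random_maps(1, n_channels, rng, length_scale=0.45)[0]
        attempts += 1
        if admissible(cand):
            maps.append(cand)
            k += 1
        elif attempts > 200 * n_states:
            raise RuntimeError("could not place sufficiently dissimilar maps")
    return np.array(maps)


def _draw_run_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    ms = rng.gamma(cfg.dwell_shape, cfg.mean_dwell / cfg.dwell_shape)
    return max(1, int(round(ms * cfg.sampling_rate / 1000.0)))


def simulate_state_runs(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Draw the semi-Markov run list tiling ``cfg.n_samples`` samples.

    Dwell times are gamma (shape ``dwell_shape``, mean ``mean_dwell`` ms)
    rounded to whole samples; the next state is drawn from the row of
    ``transition_weights``, so consecutive runs always differ.
    """
    n = cfg.n_samples
    if cfg.n_states == 1:
        return [(0, 0, n)]
    w = cfg.weights
    probs = w / w.sum(axis=1, keepdims=True)
    state = int(rng.integers(cfg.n_states))
    runs: list[tuple[int, int, int]] = []
    t = 0
    while t < n:
        length = _draw_run_length(rng, cfg)
        end = min(t + length, n)
        runs.append((state, t, end))
        t = end
        state = int(rng.choice(cfg.n_states, p=probs[state]))
    return runs


_AMP_FLOOR = 0.02  # keeps every sample's map well-defined (nonzero GFP)


def _synthesize_signal(
    cfg: SimulationConfig,
    runs: list[tuple[int, int, int]],
    templates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Channel-level synthesis from a run list.

    Within each run the scalp map is the active template scaled by a
    rectified alpha oscillation with onset-zero phase, shaped by a
    per-run Tukey window so the amplitude is small at run boundaries
    (real microstate transitions occur near GFP minima, and abrupt map
    switches at full amplitude would smear into two-template mixtures
    under band-pass filtering). Polarity is redrawn per run, exercising
    polarity-invariant clustering downstream. The template signal is
    scaled to ``snr`` times the noise RMS (``noise_sd`` μV of white
    Gaussian sensor noise); ``snr=inf`` turns the noise off.
    """
    from scipy.signal.windows import tukey

    n = cfg.n_samples
    fs = cfg.sampling_rate
    amp = np.empty(n)
    sign = np.empty(n)
    states = np.empty(n, dtype=int)
    for state, a, b in runs:
        t_rel = np.arange(b - a) / fs
        osc = np.abs(np.sin(2.0 * np.pi * cfg.alpha_freq * t_rel))
        amp[a:b] = np.maximum(osc * tukey(b - a, 0.4), _AMP_FLOOR)
        sign[a:b] = -1.0 if rng.random() < 0.5 else 1.0
        states[a:b] = state
    signal = (amp * sign)[None, :] * templates[states].T  # (channels, samples)

    finite_snr = np.isfinite(cfg.snr)
    target_rms = cfg.noise_sd * (cfg.snr if finite_snr else 1.0)
    rms = np.sqrt(np.mean(signal**2))
    if rms > 0:
        signal *= target_rms / rms
    if finite_snr:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    return signal


def simulate_subject_eeg(
    cfg: SimulationConfig, templates: np.ndarray | None = None
) -> tuple[Recording, GroundTruth]:
    """Synthesize one recording of ``cfg.record_duration`` seconds.

    The state sequence is a semi-Markov chain (see
    :func:`simulate_state_runs`); the channel signal is built by
    :func:`_synthesize_signal`. Bit-reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if templates is None:
        templates = generate_templates(cfg.n_channels, cfg.n_states, cfg.seed)
    templates = np.asarray(templates, dtype=float)
    runs = simulate_state_runs(cfg, rng)
    signal = _synthesize_signal(cfg, runs, templates, rng)
    labels = [f"CH{i + 1:02d}" for i in range(cfg.n_channels)]
    rec = Recording(signal, labels, cfg.sampling_rate, reference="average")
    return rec, GroundTruth(templates=templates, state_runs=runs)


def analytic_parameters(cfg: SimulationConfig, mean_dwell_ms: np.ndarray | None = None) -> dict[str, float]:
    """Closed-form microstate parameters implied by a simulation config.

    For a semi-Markov chain with embedded transition matrix P (the
    row-normalized weights) and per-state mean dwell m_k, the long-run
    fraction of runs in state k is the stationary vector pi of P, and

    - duration_k     = m_k  (ms)
    - occurrence_k   = 1000 * pi_k / sum_j(pi_j m_j)  (runs / second)
    - contribution_k = pi_k m_k / sum_j(pi_j m_j)
    - transition_ij  = P_ij
    """
    k = cfg.n_states
    m = np.full(k, cfg.mean_dwell) if mean_dwell_ms is None else np.asarray(mean_dwell_ms, float)
    if k == 1:
        pi = np.array([1.0])
        p = np.zeros((1, 1))
    else:
        w = cfg.weights
        p = w / w.sum(axis=1, keepdims=True)
        evals, evecs = np.linalg.eig(p.T)
        i = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.real(evecs[:, i])
        pi = np.abs(pi) / np.abs(pi).sum()
    denom = float(pi @ m)
    out: dict[str, float] = {}
    ms = [f"ms{i + 1}" for i in range(k)]
    for i in range(k):
        out[f"duration_{ms[i]}"] = float(m[i])
        out[f"occurrence_{ms[i]}"] = 1000.0 * float(pi[i]) / denom
        out[f"contribution_{ms[i]}"] = float(pi[i] * m[i]) / denom
    for i in range(k):
        for j in range(k):
            if i != j:
                out[f"transition_{ms[i]}_{ms[j]}"] = float(p[i, j])
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Draw by resampling (not clipping) so the bounds carry no point mass."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def _perturb_config(
    cfg: SimulationConfig, cohort: CohortConfig, rng: np.random.Generator, seed: int
) -> tuple[SimulationConfig, np.ndarray]:
    """Per-subject variation: scale per-state dwell means and transition
    weights by lognormal factors, giving every microstate parameter a
    continuous distribution across subjects."""
    k = cfg.n_states
    dwell_mult = rng.lognormal(0.0, cohort.dwell_spread, size=k)
    w = cfg.weights * rng.lognormal(0.0, cohort.weight_spread, size=(k, k))
    np.fill_diagonal(w, 0.0)
    sub_cfg = SimulationConfig(
        n_channels=cfg.n_channels,
        n_states=k,
        sampling_rate=cfg.sampling_rate,
        record_duration=cfg.record_duration,
        mean_dwell=cfg.mean_dwell,
        dwell_shape=cfg.dwell_shape,
        transition_weights=w.tolist(),
        alpha_freq=cfg.alpha_freq,
        snr=cfg.snr,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    return sub_cfg, cfg.mean_dwell * dwell_mult


def _simulate_with_state_dwells(
    cfg: SimulationConfig, dwells_ms: np.ndarray, templates: np.ndarray
) -> tuple[Recording, GroundTruth]:
    """Like :func:`simulate_subject_eeg` but with per-state dwell means."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    if cfg.n_states == 1:
        runs = [(0, 0, n)]
    else:
        w = cfg.weights
        probs = w / w.sum(axis=1, keepdims=True)
        state = int(rng.integers(cfg.n_states))
        runs = []
        t = 0
        while t < n:
            ms = rng.gamma(cfg.dwell_shape, dwells_ms[state] / cfg.dwell_shape)
            length = max(1, int(round(ms * cfg.sampling_rate / 1000.0)))
            end = min(t + length, n)
            runs.append((state, t, end))
            t = end
            state = int(rng.choice(cfg.n_states, p=probs[state]))
    signal = _synthesize_signal(cfg, runs, templates, rng)
    labels = [f"CH{i + 1:02d}" for i in range(cfg.n_channels)]
    rec = Recording(signal, labels, cfg.sampling_rate, reference="average")
    return rec, GroundTruth(templates=templates, state_runs=runs)


def simulate_cohort(
    sim_cfg: SimulationConfig,
    cohort_cfg: CohortConfig,
    with_eeg: bool = True,
) -> tuple[pd.DataFrame, list[Recording] | None, CohortGroundTruth]:
    """Simulate a cohort: per-subject microstate dynamics plus behavior.

    Every subject shares the template maps but gets individually
    perturbed dwell means and transition weights. The creativity total is

        WCTS = b0 + sum_e (b1*Xc + b2*Wc + b3*Xc*Wc) + b_sex*sex
               + b_age*(age - mean) + N(0, noise_sd)

    with X the subject's generator-side microstate parameter (analytic,
    see :func:`analytic_parameters`), W the self-esteem total, both
    centered at the cohort mean. Scores are truncated to their legal
    ranges (creativity 50-150, self-esteem 10-40) by resampling.
    ``with_eeg=False`` skips the channel-level synthesis, which the
    Monte-Carlo calibration studies rely on for speed.
    """
    valid = set(parameter_names(sim_cfg.n_states))
    for name, *_ in cohort_cfg.effect_map:
        if name not in valid:
            raise ValueError(f"unknown microstate parameter in effect_map: {name!r}")

    master = np.random.SeedSequence([cohort_cfg.seed, sim_cfg.seed])
    children = master.spawn(cohort_cfg.n_subjects + 1)
    beh_rng = np.random.default_rng(children[-1])

    templates = generate_templates(sim_cfg.n_channels, sim_cfg.n_states, sim_cfg.seed)

    rows = []
    recordings: list[Recording] | None = [] if with_eeg else None
    run_lists: list[list[tuple[int, int, int]]] | None = [] if with_eeg else None
    for i in range(cohort_cfg.n_subjects):
        srng = np.random.default_rng(children[i])
        sub_seed = int(srng.integers(2**31 - 1))
        sub_cfg, dwells = _perturb_config(sim_cfg, cohort_cfg, srng, sub_seed)
        params = analytic_parameters(sub_cfg, mean_dwell_ms=dwells)
        rows.append(params)
        if with_eeg:
            rec, gt = _simulate_with_state_dwells(sub_cfg, dwells, templates)
            recordings.append(rec)
            run_lists.append(gt.state_runs)

    params_df = pd.DataFrame(rows)
    params_df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(len(rows))])

    n = cohort_cfg.n_subjects
    rses = _truncated_normal(beh_rng, cohort_cfg.rses_mean, cohort_cfg.rses_sd, 10, 40, n)
    sex = (beh_rng.random(n) < cohort_cfg.male_prob).astype(int)  # 1 = male
    age = _truncated_normal(
        beh_rng,
        cohort_cfg.age_mean,
        cohort_cfg.age_sd,
        cohort_cfg.age_mean - 4 * cohort_cfg.age_sd,
        cohort_cfg.age_mean + 4 * cohort_cfg.age_sd,
        n,
    )
    wc = rses - rses.mean()
    mu = np.full(n, cohort_cfg.wcts_intercept, dtype=float)
    for name, b1, b2, b3 in cohort_cfg.effect_map:
        x = params_df[name].to_numpy()
        xc = x - x.mean()
        mu += b1 * xc + b2 * wc + b3 * xc * wc
    mu += cohort_cfg.sex_effect * sex + cohort_cfg.age_effect * (age - cohort_cfg.age_mean)
    wcts = mu + beh_rng.normal(0.0, cohort_cfg.noise_sd, n)
    for _ in range(1000):
        bad = (wcts < 50) | (wcts > 150)
        if not bad.any():
            break
        wcts[bad] = mu[bad] + beh_rng.normal(0.0, cohort_cfg.noise_sd, int(bad.sum()))
    wcts = np.clip(wcts, 50, 150)

    # subscale totals: item-count shares of the 50-item scale plus noise,
    # kept inside each subscale's legal range
    shares = {"curiosity": 13 / 50, "imagination": 13 / 50, "challenge": 12 / 50, "risk_taking": 12 / 50}
    ranges = {"curiosity": (13, 39), "imagination": (13, 39), "challenge": (12, 36), "risk_taking": (12, 36)}
    sub_scores = {}
    for key, share in shares.items():
        lo, hi = ranges[key]
        s = share * wcts + beh_rng.normal(0.0, 1.5, n)
        sub_scores[key] = np.clip(s, lo, hi)

    behavior = pd.DataFrame(
        {
            "subject_id": params_df["subject_id"],
            "wcts_total": wcts,
            "risk_taking": sub_scores["risk_taking"],
            "curiosity": sub_scores["curiosity"],
            "imagination": sub_scores["imagination"],
            "challenge": sub_scores["challenge"],
            "rses": rses,
            "sex": sex,
            "age": age,
        }
    )
    truth = CohortGroundTruth(
        templates=templates,
        subject_parameters=params_df,
        planted_coefficients=list(cohort_cfg.effect_map),
        state_runs=run_lists,
    )
    return behavior, recordings, truth
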