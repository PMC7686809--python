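"""Microstate template derivation: GFP peaks, polarity-invariant AAHC,
cross-validation model selection and global explained variance.

The segmentation follows the classical recipe: only scalp maps at local
maxima of the global field power (GFP) enter clustering, because those
are the moments of highest topographic signal-to-noise; clustering is
atomize-agglomerate hierarchical clustering (AAHC) with map polarity
disregarded; the number of template maps is chosen by the predictive
cross-validation criterion, which trades residual variance against the
number of clusters.

Conventions used throughout:

- maps are vectors over channels; similarity is the Pearson correlation
  C of the mean-removed maps, and the global map dissimilarity satisfies
  GMD^2 = 2(1 - C) on GFP-normalized maps
- template maps are zero-mean, unit-norm, with the deterministic
  polarity that the largest-|value| channel is positive
- all tie-breaks go to the lowest index, making every routine
  deterministic given its input order
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GFPSeries",
    "TemplateSet",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_similarity",
    "extract_peak_maps",
    "aahc_cluster",
    "cv_criterion",
    "select_optimal_k",
    "compute_gev",
    "group_cluster",
]


@dataclass
class GFPSeries:
    values: np.ndarray
    peak_indices: np.ndarray


@dataclass
class TemplateSet:
    """K template maps plus fit diagnostics."""

    maps: np.ndarray                      # (k, n_channels), zero-mean unit-norm
    k: int
    gev: float | None = None
    cv_value: float | None = None
    source: str = "subject"
    names: list[str] | None = None
    gev_per_subject: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != self.k:
            raise ValueError("maps must be (k, n_channels)")


def compute_gfp(maps: np.ndarray) -> np.ndarray:
    """GFP(t) = spatial standard deviation of the scalp map at t.

    ``maps`` is ``(n_channels, n_samples)`` (or a single map vector).
    Computed about the instantaneous spatial mean, so it is invariant to
    any reference shift.
    """
    maps = np.asarray(maps, dtype=float)
    single = maps.ndim == 1
    if single:
        maps = maps[:, None]
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    out = maps.std(axis=0)
    return float(out[0]) if single else out


def find_gfp_peaks(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of the GFP series.

    A plateau of equal values counts once, at its first sample; the
    first and last samples are never peaks.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("series too short for peak detection")
    # a plateau start is a peak iff the last strict change before it was
    # upward and the next strict change after the plateau is downward
    peaks = []
    i = 1
    while i < v.size - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < v.size and v[j + 1] == v[j]:
                j += 1
            if j < v.size - 1 and v[j + 1] < v[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def _demean(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return u - u.mean()


def spatial_similarity(
    u: np.ndarray, v: np.ndarray, polarity_invariant: bool = True
) -> tuple[float, float]:
    """Spatial correlation C and global map dissimilarity GMD.

    Both maps are mean-removed and GFP-normalized first. With
    ``polarity_invariant`` the sign minimizing GMD (maximizing C) is
    taken, so C >= 0. The identity GMD^2 = 2(1 - C) holds exactly.
    """
    u, v = _demean(u), _demean(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("similarity undefined for a flat map (GFP = 0)")
    c = float(u @ v / (nu * nv))
    if polarity_invariant:
        c = abs(c)
    gmd = float(np.sqrt(max(0.0, 2.0 * (1.0 - c))))
    return c, gmd


def extract_peak_maps(
    epochs, max_peaks: int | None = 5000, seed: int = 0
) -> np.ndarray:
    """Collect mean-removed scalp maps at GFP peaks of every kept epoch.

    Peak detection runs per epoch so no peak spans an epoch boundary.
    If more than ``max_peaks`` accumulate, a seeded uniform subsample
    bounds the quadratic cost of AAHC.
    """
    collected = []
    for ep in epochs.data:
        gfp = compute_gfp(ep)
        idx = find_gfp_peaks(gfp)
        if idx.size:
            collected.append(ep[:, idx].T)
    if not collected:
        raise ValueError("no GFP peaks found")
    maps = np.concatenate(collected, axis=0)
    maps = maps - maps.mean(axis=1, keepdims=True)
    if max_peaks is not None and maps.shape[0] > max_peaks:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(maps.shape[0], size=max_peaks, replace=False))
        maps = maps[pick]
    return maps


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return v if v[i] >= 0 else -v


def _dominant_eigvec(s: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(s)
    v = evecs[:, -1]
    return _fix_sign(v / np.linalg.norm(v))


class _AAHCState:
    """Bookkeeping for one AAHC run over mean-removed peak maps."""

    def __init__(self, maps: np.ndarray):
        self.maps = maps                                   # (m, N)
        self.gfp = maps.std(axis=1)
        self.norms = np.linalg.norm(maps, axis=1)
        unit = maps / np.where(self.norms[:, None] == 0, 1.0, self.norms[:, None])
        self.unit = unit
        m = maps.shape[0]
        self.members: dict[int, list[int]] = {i: [i] for i in range(m)}
        self.templates: dict[int, np.ndarray] = {
            i: _fix_sign(unit[i].copy()) for i in range(m)
        }
        # GEV contribution of each cluster (unnormalized numerator)
        self.contrib: dict[int, float] = {
            i: float((self.gfp[i] * abs(unit[i] @ self.templates[i])) ** 2)
            for i in range(m)
        }

    def _update_cluster(self, c: int) -> None:
        idx = self.members[c]
        x = self.maps[idx]
        if len(idx) == 1:
            t = _fix_sign(self.unit[idx[0]].copy())
        else:
            t = _dominant_eigvec(x.T @ x)
        self.templates[c] = t
        corr = np.abs(self.unit[idx] @ t)
        self.contrib[c] = float(np.sum((self.gfp[idx] * corr) ** 2))

    def dissolve_worst(self) -> None:
        worst = min(self.contrib, key=lambda c: (self.contrib[c], c))
        orphans = self.members.pop(worst)
        del self.templates[worst]
        del self.contrib[worst]
        keys = sorted(self.members)
        tmat = np.stack([self.templates[c] for c in keys])
        corr = np.abs(self.unit[orphans] @ tmat.T)          # (n_orphans, k)
        best = np.argmax(corr, axis=1)                      # first max wins
        touched = set()
        for o, b in zip(orphans, best):
            c = keys[int(b)]
            self.members[c].append(o)
            touched.add(c)
        for c in touched:
            self._update_cluster(c)

    def template_set(self, source: str) -> TemplateSet:
        keys = sorted(self.members)
        maps = np.stack([self.templates[c] for c in keys])
        return TemplateSet(maps=maps, k=len(keys), source=source)


def aahc_cluster(
    peak_maps: np.ndarray, k_range, source: str = "subject"
) -> dict[int, TemplateSet]:
    """Atomize-agglomerate hierarchical clustering, polarity disregarded.

    Every input map starts as its own cluster; at each step the cluster
    explaining the least GFP-weighted variance is dissolved and its maps
    reassigned to the surviving cluster of highest |C|. Cluster templates
    are the dominant eigenvector of the members' outer-product sum — the
    polarity-invariant centroid. A :class:`TemplateSet` is recorded at
    every k in ``k_range`` on the way down.
    """
    maps = np.asarray(peak_maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    m = maps.shape[0]
    k_range = sorted(set(int(k) for k in k_range), reverse=True)
    if any(k < 1 or k > m for k in k_range):
        raise ValueError(f"k_range must lie within [1, {m}]")
    state = _AAHCState(maps)
    out: dict[int, TemplateSet] = {}
    k = m
    if k in k_range:
        out[k] = state.template_set(source)
    while k > min(k_range):
        state.dissolve_worst()
        k -= 1
        if k in k_range:
            out[k] = state.template_set(source)
    for ts in out.values():
        ts.gev = compute_gev(maps, maps.std(axis=1), ts)
        if ts.k < maps.shape[1] - 1:
            ts.cv_value = cv_criterion(maps, ts)
    return dict(sorted(out.items()))


def _best_fit(maps: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-invariant best template per map: labels and |C| values.

    ``maps`` are mean-removed ``(m, N)``; ``templates`` ``(k, N)``
    zero-mean unit-norm. Correlation reduces to the normalized dot
    product.
    """
    norms = np.linalg.norm(maps, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    corr = np.abs((maps / safe[:, None]) @ templates.T)
    corr[norms == 0] = 0.0
    labels = np.argmax(corr, axis=1)
    return labels, corr[np.arange(maps.shape[0]), labels]


def compute_gev(
    maps: np.ndarray,
    gfp: np.ndarray,
    template_set: TemplateSet,
    labels: np.ndarray | None = None,
) -> float:
    """Global explained variance of a labeling.

    GEV = sum_t (GFP_t * C(v_t, T_label(t)))^2 / sum_t GFP_t^2 — the
    GFP^2-weighted fraction of topographic variance the assigned
    templates explain.
    """
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.asarray(gfp, dtype=float)
    denom = float(np.sum(gfp**2))
    if denom == 0:
        raise ValueError("all-flat input: GEV undefined")
    if labels is None:
        labels, best = _best_fit(maps, template_set.maps)
    else:
        norms = np.linalg.norm(maps, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        best = np.abs(
            np.einsum("ij,ij->i", maps / safe[:, None], template_set.maps[labels])
        )
        best[norms == 0] = 0.0
    return float(np.sum((gfp * best) ** 2) / denom)


def cv_criterion(peak_maps: np.ndarray, template_set: TemplateSet) -> float:
    """Predictive cross-validation criterion for model-order selection.

    CV = sigma_hat^2 * ((N - 1) / (N - 1 - K))^2, where sigma_hat^2 is
    the mean per-sample residual variance after removing each map's
    projection onto its best-fitting template. Lower is better: the
    squared penalty factor counters the monotone decrease of residual
    variance with K.
    """
    maps = np.asarray(peak_maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    n_ch = maps.shape[1]
    k = template_set.k
    if k >= n_ch - 1:
        raise ValueError("CV criterion undefined for K >= n_channels - 1")
    labels, _ = _best_fit(maps, template_set.maps)
    proj = np.einsum("ij,ij->i", maps, template_set.maps[labels])
    resid = np.einsum("ij,ij->i", maps, maps) - proj**2
    sigma2 = float(np.mean(resid) / (n_ch - 1))
    return sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2


def select_optimal_k(sets: dict[int, TemplateSet]) -> int:
    """The k minimizing the CV criterion (lowest k wins ties)."""
    usable = {k: ts.cv_value for k, ts in sets.items() if ts.cv_value is not None}
    if not usable:
        raise ValueError("no CV values available")
    return min(usable, key=lambda k: (usable[k], k))


def group_cluster(subject_sets: list[TemplateSet], k: int) -> TemplateSet:
    """Second-level clustering: AAHC over the pooled subject templates.

    With a single subject (or identical sets) this reduces to the input
    maps themselves. Per-subject explained variance should afterwards be
    recomputed by backfitting the group maps to each subject's data.
    """
    pooled = np.concatenate([ts.maps for ts in subject_sets], axis=0)
    if pooled.shape[0] < k:
        raise ValueError("fewer pooled maps than requested clusters")
    if pooled.shape[0] == k:
        maps = np.array([_fix_sign(m / np.linalg.norm(m)) for m in pooled])
        return TemplateSet(maps=maps, k=k, source="group")
    out = aahc_cluster(pooled, [k], source="group")
    return out[k]
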