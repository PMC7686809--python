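"""Idealized sensor layout and canonical microstate archetype maps.

Microstate template maps live on the scalp, but for simulation and for
canonical MS1-MS4 naming only the relative 2-D sensor geometry matters.
This module provides a deterministic quasi-uniform layout of ``n`` sensors
on the unit disk (a schematic top view of the head, +y = anterior,
+x = right) and the four archetypal topographies used throughout the
microstate literature:

- MS1 (type A): left-posterior to right-anterior diagonal gradient
- MS2 (type B): right-posterior to left-anterior diagonal gradient
- MS3 (type C): anterior-posterior oriented, left-right symmetric,
  with an occipital extremum
- MS4 (type D): fronto-central focal map

Maps are returned zero-mean across sensors and unit-norm, the convention
used by the segmentation code.
"""

from __future__ import annotations

import numpy as np

__all__ = ["disk_layout", "canonical_archetypes", "normalize_map", "smooth_random_maps"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def disk_layout(n_channels: int) -> np.ndarray:
    """Return ``(n_channels, 2)`` sensor positions on the unit disk.

    Uses a sunflower (Fibonacci) spiral, which is deterministic and
    quasi-uniform for any sensor count.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    k = np.arange(n_channels)
    r = np.sqrt((k + 0.5) / n_channels)
    theta = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Remove the spatial mean and scale to unit norm."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("flat map cannot be normalized")
    return v / nrm


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # deterministic polarity: the largest-|value| channel is positive
    i = int(np.argmax(np.abs(v)))
    return v if v[i] >= 0 else -v


def canonical_archetypes(n_channels: int) -> np.ndarray:
    """Return the four canonical archetype maps, shape ``(4, n_channels)``.

    Each map is zero-mean and unit-norm on the :func:`disk_layout`
    geometry. Pairwise |spatial correlation| stays well below 0.7 so the
    archetypes are usable both as simulation seeds and as references for
    canonical MS1-MS4 assignment.
    """
    pos = disk_layout(n_channels)
    x, y = pos[:, 0], pos[:, 1]
    maps = np.vstack(
        [
            x + y,  # MS1: left-posterior -> right-anterior
            y - x,  # MS2: right-posterior -> left-anterior
            np.exp(-(x**2 + (y + 0.55) ** 2) / 0.35),  # MS3: occipital, symmetric
            np.exp(-(x**2 + (y - 0.40) ** 2) / 0.22),  # MS4: fronto-central focal
        ]
    )
    return np.array([_fix_sign(normalize_map(m)) for m in maps])


def smooth_random_maps(
    n_maps: int, n_channels: int, rng: np.random.Generator, length_scale: float = 0.6
) -> np.ndarray:
    """Draw spatially smooth random maps from a Gaussian process on the layout.

    A squared-exponential kernel over sensor positions gives maps with the
    broad spatial structure typical of scalp potentials; each returned map
    is zero-mean and unit-norm.
    """
    pos = disk_layout(n_channels)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2 * length_scale**2)) + 1e-9 * np.eye(n_channels)
    chol = np.linalg.cholesky(cov)
    raw = rng.standard_normal((n_maps, n_channels)) @ chol.T
    return np.array([_fix_sign(normalize_map(m)) for m in raw])
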