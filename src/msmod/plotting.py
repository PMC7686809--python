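"""Quick-look topographic plots of template maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layout import disk_layout
from .segmentation import TemplateSet

__all__ = ["plot_templates"]


def plot_templates(
    ts: TemplateSet,
    path: str | Path | None = None,
    positions: np.ndarray | None = None,
):
    """Draw each template as an interpolated scalp map on the unit disk.

    ``positions`` defaults to the package's schematic sensor layout;
    pass real 2-D montage coordinates for measured data. Returns the
    figure; saves to ``path`` when given.
    """
    import matplotlib.pyplot as plt

    if positions is None:
        positions = disk_layout(ts.maps.shape[1])
    names = ts.names or [f"state{i}" for i in range(ts.k)]
    fig, axes = plt.subplots(1, ts.k, figsize=(2.2 * ts.k, 2.4), squeeze=False)
    lim = np.abs(ts.maps).max()
    for ax, m, name in zip(axes[0], ts.maps, names):
        ax.tricontourf(
            positions[:, 0], positions[:, 1], m, levels=24,
            cmap="RdBu_r", vmin=-lim, vmax=lim,
        )
        ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1.0))
        ax.plot(positions[:, 0], positions[:, 1], "k.", ms=1.5)
        ax.set_title(name, fontsize=10)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
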