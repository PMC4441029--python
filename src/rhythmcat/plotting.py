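"""Performance-space maps and activation figures.

The triangular performance space is the 2-simplex of IOI triples; grid
rhythms project to barycentric coordinates and are drawn as colored
points (category maps) or a continuous colormap (SNR maps).  Plain
matplotlib; no interactive backends required.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .categorize import Categorization, EXCLUDED, _barycentric_xy
from .oscillators import AmplitudeTimeSeries
from .stimuli import RhythmSequence


def _simplex_axes(ax):
    corners = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(corners[:, 0], corners[:, 1], color="0.3", lw=1)
    ax.set_aspect("equal")
    ax.axis("off")


def plot_category_map(categorization: Categorization,
                      rhythms: Sequence[RhythmSequence], ax=None):
    """Ternary scatter of the category map, one color per label."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    _simplex_axes(ax)
    units = np.array([r.grid_units for r in rhythms], dtype=float)
    xy = _barycentric_xy(units)
    labels = [categorization.label_of(r.id) for r in rhythms]
    uniq = sorted({l for l in labels if l != EXCLUDED})
    cmap = plt.get_cmap("tab20")
    for j, lab in enumerate(uniq):
        sel = [i for i, l in enumerate(labels) if l == lab]
        ax.scatter(xy[sel, 0], xy[sel, 1], s=60, color=cmap(j % 20),
                   label=lab.display, edgecolor="k", linewidth=0.3)
    excl = [i for i, l in enumerate(labels) if l == EXCLUDED]
    if excl:
        ax.scatter(xy[excl, 0], xy[excl, 1], s=60, facecolor="none",
                   edgecolor="0.5", label="excluded")
    ax.legend(loc="upper left", bbox_to_anchor=(1, 1), fontsize=7)
    return ax


def plot_snr_map(snr_table, ax=None, log_scale: bool = True):
    """Ternary scatter of SNR over the performance space."""
    import matplotlib.pyplot as plt
    from matplotlib import colors
    ax = ax or plt.gca()
    _simplex_axes(ax)
    units = snr_table[["k1", "k2", "k3"]].to_numpy(dtype=float)
    xy = _barycentric_xy(units)
    vals = snr_table["snr"].to_numpy(dtype=float)
    norm = colors.LogNorm(vals.min(), vals.max()) if log_scale else None
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=vals, s=60, cmap="RdYlBu", norm=norm,
                    edgecolor="k", linewidth=0.3)
    ax.figure.colorbar(sc, ax=ax, label="SNR")
    return ax


def plot_activation_over_time(ts: AmplitudeTimeSeries, ax=None,
                              downsample: int = 10):
    """Heatmap of oscillator amplitude over time (frequency on y, log)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    t = ts.times()[::downsample]
    m = ax.pcolormesh(t, ts.frequencies, ts.amplitudes[:, ::downsample],
                      shading="nearest", cmap="magma")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intrinsic frequency (Hz)")
    ax.figure.colorbar(m, ax=ax, label="|z|")
    return ax
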