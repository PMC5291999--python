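"""Optional plots: deformity counts, prevalence and group mean curves.

matplotlib is imported lazily so the rest of the package stays importable
without it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .kinematics import InterSegmentAngleSeries


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_deformity_counts(counts: Mapping[int, int], ax=None):
    """Bar chart of the number of feet with 0..5 structural deformities."""
    ax = _get_axes(ax)
    keys = sorted(counts)
    ax.bar(keys, [counts[k] for k in keys], color="tab:blue")
    ax.set_xlabel("number of deformities")
    ax.set_ylabel("feet")
    return ax


def plot_prevalence(prevalence: Mapping[str, float], ax=None):
    """Bar chart of per-type deformity prevalence (fractions)."""
    ax = _get_axes(ax)
    names = list(prevalence)
    ax.bar(range(len(names)), [100.0 * prevalence[n] for n in names],
           color="tab:orange")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("prevalence (%)")
    return ax


def plot_group_curves(series_by_group: Mapping[str, Sequence[InterSegmentAngleSeries]],
                      joint: str, plane: str, ax=None):
    """Mean angle curves per group over the normalised time base."""
    import numpy as np
    ax = _get_axes(ax)
    for label, series_list in series_by_group.items():
        curves = np.array([s.curve(joint, plane) for s in series_list])
        pct = np.linspace(0, 100, curves.shape[1])
        mean = curves.mean(axis=0)
        sd = curves.std(axis=0, ddof=1) if curves.shape[0] > 1 else 0 * mean
        line, = ax.plot(pct, mean, label=f"{label} (n={curves.shape[0]})")
        ax.fill_between(pct, mean - sd, mean + sd, alpha=0.2,
                        color=line.get_color())
    ax.set_xlabel("% of window")
    ax.set_ylabel(f"{joint} {plane} angle (deg)")
    ax.legend()
    return ax
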