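"""Grouped-bar figure of observed vs predicted cover across the tillage boundary."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scenarios import ComparisonReport

_PANELS = (
    ("obs", "Observed"),
    ("psf", "PSF model"),
    ("null", "Null model"),
)


def plot_comparison(report: ComparisonReport):
    """Three panels (observed, PSF model, null model) of native vs non-native
    percent cover per distance class.  Returns the matplotlib Figure."""
    table = report.table
    distances = table.index.tolist()
    x = range(len(distances))
    width = 0.38
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, (prefix, title) in zip(axes, _PANELS):
        ax.bar([i - width / 2 for i in x], table[f"{prefix}_native"], width,
               label="native", color="#2a7e43")
        ax.bar([i + width / 2 for i in x], table[f"{prefix}_nonnative"], width,
               label="non-native", color="#b5651d")
        ax.set_xticks(list(x))
        ax.set_xticklabels([f"{d:+d} m" for d in distances])
        ax.set_title(title)
        ax.set_xlabel("distance from tillage boundary")
    axes[0].set_ylabel("percent ground cover")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    return fig
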