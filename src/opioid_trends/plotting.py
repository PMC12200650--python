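"""Trend plot: observed annual rates, fitted segments and the pre-break
counterfactual projection."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .config import SegmentedModelSpec
from .its import SegmentedFitResult, fitted_rates, project_counterfactual

_RATE_COLS = {"incident": "rate_incident", "ltot": "rate_ltot",
              "discontinuers": "rate_discontinuers"}
_LABELS = {"incident": "Incident opioid users",
           "ltot": "L-TOT users",
           "discontinuers": "L-TOT discontinuers"}


def plot_trends(table, fits: dict[str, SegmentedFitResult],
                spec: SegmentedModelSpec | None = None, path=None):
    """Three-panel trend figure; returns the matplotlib Figure."""
    spec = spec or SegmentedModelSpec()
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharex=True)
    post_years = [y for y in table["year"] if y > spec.break_year]
    for ax, (name, fit) in zip(axes, fits.items()):
        ax.plot(table["year"], table[_RATE_COLS[name]], "o", color="k",
                label="observed", ms=4)
        fr = fitted_rates(fit, spec)
        pre = fr.index <= spec.break_year
        ax.plot(fr.index[pre], fr.to_numpy()[pre], "-", color="tab:blue",
                label="fitted (pre)")
        ax.plot(fr.index[~pre], fr.to_numpy()[~pre], "-", color="tab:red",
                label="fitted (post)")
        proj = project_counterfactual(fit, post_years, spec)
        ax.plot(proj.index, proj.to_numpy(), "--", color="tab:blue",
                label="pre-trend projection")
        ax.axvline(spec.break_year, color="grey", lw=0.8, ls=":")
        ax.set_title(_LABELS[name])
        ax.set_xlabel("year")
        ax.set_ylabel("rate (%)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
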