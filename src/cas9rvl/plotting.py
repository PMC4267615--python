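"""Optional rendering helpers (requires the ``plots`` extra / matplotlib).

These are conveniences on top of the TSV outputs, not part of the tested
analysis contract.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _mpl():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the 'plots' extra)") from exc
    return plt


def plot_single_variant_heatmap(heat: pd.Series, spec, path) -> None:
    """Blue-white-red heat map of ratio-to-WT; WT cells asterisked."""
    plt = _mpl()
    from .library import BASES

    positions = sorted({p for p, _ in heat.index})
    grid = np.full((len(BASES), len(positions)), np.nan)
    for (pos, base), value in heat.items():
        grid[BASES.index(base), positions.index(pos)] = value
    fig, ax = plt.subplots(figsize=(0.35 * len(positions) + 2, 3))
    im = ax.imshow(grid, cmap="bwr_r", vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(range(len(positions)), positions, fontsize=7)
    ax.set_yticks(range(len(BASES)), BASES)
    ax.set_xlabel("position")
    for j, pos in enumerate(positions):
        if pos in spec.doped_positions:
            ax.text(j, BASES.index(spec.base_at(pos)), "*", ha="center", va="center")
    fig.colorbar(im, ax=ax, label="median retention / WT median")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timecourses(courses: Sequence, path) -> None:
    """Median retention vs time with SD error bars, one line per category."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    for tc in courses:
        ax.errorbar(
            tc.table["timepoint"], tc.table["median"], yerr=tc.table["sd"],
            marker="o", capsize=3, label=tc.label,
        )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("median retention (log2)")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
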