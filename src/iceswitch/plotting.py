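"""Minimal figure helpers for the population readouts.

Kept deliberately small: a count histogram with the exact-zero class drawn
as its own distinct bar, and the dose-response curve with Monte-Carlo error
bars.  Both write image files and never open interactive windows.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import DoseResponseCurve, SubpopulationSummary

__all__ = ["plot_state_histogram", "plot_dose_response"]


def plot_state_histogram(summary: SubpopulationSummary, path, title: str = "",
                         species: str = "BisDC") -> None:
    """Histogram of per-cell output with the zero state as a separate bar."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    edges, counts = summary.bin_edges, summary.bin_counts
    widths = edges[1:] - edges[:-1]
    ax.bar(edges[:-1][1:], counts[1:], width=widths[1:], align="edge",
           color="#c2418f", label="positive state")
    ax.bar(edges[0], counts[0], width=widths[0], align="edge",
           color="black", label=f"zero state ({summary.zero_fraction:.0%})")
    ax.set_xlabel(f"{species} molecules per cell")
    ax.set_ylabel("cells")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dose_response(curve: DoseResponseCurve, path, title: str = "") -> None:
    """Positive fraction vs input level (log2 x-axis) with +/- 2 s.e. bars."""
    df = curve.df
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.errorbar(df["level"], df["positive_fraction"],
                yerr=2 * df["positive_fraction_se"],
                marker="o", color="#c2418f", capsize=3)
    ax.set_xscale("log", base=2)
    ax.set_ylim(0, 1)
    ax.set_xlabel("input level (mean initial molecules)")
    ax.set_ylabel("fraction of positive cells")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
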