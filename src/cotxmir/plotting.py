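"""Plot helpers for metagene profiles and joint locus reports.

Thin matplotlib wrappers; all figures use the Agg-safe API (no display
needed) and return the Figure for further styling or saving.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_profile", "plot_locus_report"]


def plot_profile(profiles: dict, n_flank: int = 0, ax=None, title: str = ""):
    """Aggregated metagene profiles, one line per group.

    ``profiles`` is the output of :func:`cotxmir.metagene.aggregate_profile`
    (``{group: (vector, n)}``); empty groups are skipped.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3.2))
    else:
        fig = ax.figure
    for group, (vec, n) in sorted(profiles.items()):
        if vec is None:
            continue
        ax.plot(np.arange(len(vec)), vec, label=f"{group} (n={n})", lw=1.2)
    if n_flank:
        for x in (n_flank, ):
            ax.axvline(x, color="0.7", ls="--", lw=0.8)
    ax.set_xlabel("bin (5'→3', transcript orientation)")
    ax.set_ylabel("mean signal")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    return fig


def plot_locus_report(report: pd.DataFrame, ax=None):
    """Joint NET-seq 3'-end / strand-specific DRIP profile for one locus."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 4.2))
    else:
        fig, axes = ax.figure, ax
    top, bottom = axes
    x = report["t_pos"]
    top.fill_between(x, report["net_3p_ends"], step="mid", color="0.3")
    top.set_ylabel("3'-end reads")
    bottom.plot(x, report["drip_sense"], color="tab:red", lw=1.0, label="sense R-loop")
    bottom.plot(x, report["drip_antisense"], color="tab:blue", lw=1.0, label="antisense R-loop")
    bottom.set_ylabel("DRIP signal")
    bottom.set_xlabel("transcript position (nt from TSS)")
    for _, row in report[report["cut_index"] >= 0].iterrows():
        top.axvline(row["t_pos"], color="tab:cyan", ls=":", lw=0.9)
    title = report.attrs.get("locus_id", "")
    if report.attrs.get("co_processing_evidence"):
        title += "  [co-transcriptional processing evidence]"
    top.set_title(title, fontsize=9)
    bottom.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    return fig
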