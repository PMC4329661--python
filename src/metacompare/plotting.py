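"""Optional matplotlib figures: scatter, rarefaction, recruitment panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def scatter_plot(points, labels=("sample A", "sample B"), path=None, highlight=None):
    """Pseudocounted log-abundance scatter for two samples.

    ``highlight`` optionally maps taxon -> group label used for coloring
    (e.g. archaeal vs bacterial families).
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    highlight = highlight or {}
    groups: dict = {}
    for p in points:
        groups.setdefault(highlight.get(p.taxon, "other"), []).append(p)
    for label, pts in sorted(groups.items()):
        ax.scatter([p.x for p in pts], [p.y for p in pts], s=12, alpha=0.7, label=label)
    lim = max(
        [0.1]
        + [max(p.x, p.y) for p in points]
    ) * 1.05
    ax.plot([0, lim], [0, lim], lw=0.8, color="grey")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel(f"log10 normalized count + 1 ({labels[0]})")
    ax.set_ylabel(f"log10 normalized count + 1 ({labels[1]})")
    if len(groups) > 1:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def rarefaction_plot(curves, path=None):
    """Mean richness vs depth with ±1 SD bands; one line per curve."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for label, curve in curves.items():
        d = np.asarray(curve.depths)
        m = np.asarray(curve.mean_richness)
        s = np.asarray(curve.sd_richness)
        ax.plot(d, m, label=label)
        ax.fill_between(d, m - s, m + s, alpha=0.2)
    ax.set_xlabel("subsample depth (reads)")
    ax.set_ylabel("mean richness")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def recruitment_panels(points, hist, genome_label="reference", path=None):
    """Two-panel recruitment figure: identity vs position (I) and the
    1%-binned identity distribution (II)."""
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.5), gridspec_kw={"width_ratios": [2.2, 1]}
    )
    ax1.scatter([p.position for p in points], [p.identity for p in points], s=2, alpha=0.4)
    ax1.set_ylim(55, 100.5)
    ax1.set_xlabel(f"position on {genome_label} (bp)")
    ax1.set_ylabel("identity (%)")
    ax1.set_title("(I) fragment recruitment")
    mids = np.asarray(hist.edges[:-1]) + 0.5
    ax2.bar(mids, hist.counts, width=1.0)
    ax2.set_xlabel("identity (%)")
    ax2.set_ylabel("normalized hits")
    ax2.set_title("(II) hit distribution")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
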