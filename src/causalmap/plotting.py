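"""Plot helpers for the mapping-by-sequencing stage."""

from __future__ import annotations

from typing import Optional, Sequence


def plot_snp_index(records: Sequence, interval=None, min_index: float = 0.9, ax=None):
    """Scatter SNP/Indel index against position, one panel per chromosome.

    Draws the index threshold and, when given, shades the candidate
    interval. Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    chroms = sorted({r.variant.chrom for r in records})
    if ax is None:
        fig, axes = plt.subplots(1, max(len(chroms), 1), figsize=(5 * len(chroms), 3.2), squeeze=False)
        axes = axes[0]
    else:
        fig, axes = ax.figure, [ax]
    for a, chrom in zip(axes, chroms):
        xs = [r.variant.pos / 1e6 for r in records if r.variant.chrom == chrom and r.defined]
        ys = [r.index for r in records if r.variant.chrom == chrom and r.defined]
        a.scatter(xs, ys, s=12, alpha=0.7)
        a.axhline(min_index, color="firebrick", ls="--", lw=1)
        if interval is not None and interval.chrom == chrom:
            a.axvspan(interval.left / 1e6, interval.right / 1e6, color="gold", alpha=0.25)
        a.set_xlabel(f"{chrom} position (Mbp)")
        a.set_ylabel("SNP/Indel index")
        a.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    return fig
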