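"""Manhattan-style plot of posterior inclusion probabilities."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def manhattan_ppi(posterior_frame, threshold=None, ax=None, out=None):
    """Plot PPI against genome position, chromosome-coloured, with an
    optional horizontal genome-wise threshold line.

    ``posterior_frame`` is the per-SNP table from
    ``BayesCPiResults.to_frame()`` (snp_id, chrom, pos, effect_mean, ppi).
    Returns the matplotlib Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(posterior_frame.groupby("chrom", sort=True)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, grp["ppi"], s=6,
                   color="#1f77b4" if i % 2 == 0 else "#ff7f0e")
        ticks.append(offset + grp["pos"].to_numpy().mean())
        labels.append(str(chrom))
        offset += grp["pos"].max() + 1
    if threshold is not None:
        ax.axhline(threshold, color="red", ls="--", lw=1,
                   label=f"genome-wise threshold = {threshold:.3f}")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("posterior inclusion probability")
    ax.set_ylim(0, 1.02)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax
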