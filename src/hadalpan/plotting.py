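"""Plot helpers: the ENC-GC3 scatter with the expected curve, and the
Z-normalised depth-profile heatmap."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .codon import expected_enc

__all__ = ["plot_enc_gc3", "plot_profile_heatmap"]


def plot_enc_gc3(
    gc3_values: Sequence[float],
    enc_values: Sequence[float],
    out_path,
    highlight: Optional[Sequence[bool]] = None,
):
    """Scatter of per-gene ENC against GC3 with the random-usage curve;
    ``highlight`` marks a subset (e.g. focal-unique genes) in red."""
    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0.0, 1.0, 200)
    ax.plot(s, [expected_enc(x) for x in s], "k--", lw=1, label="random usage")
    gc3_values = np.asarray(gc3_values, dtype=float)
    enc_values = np.asarray(enc_values, dtype=float)
    if highlight is None:
        ax.scatter(gc3_values, enc_values, s=8, alpha=0.6)
    else:
        mask = np.asarray(highlight, dtype=bool)
        ax.scatter(gc3_values[~mask], enc_values[~mask], s=8, alpha=0.5, label="all genes")
        ax.scatter(gc3_values[mask], enc_values[mask], s=10, c="red", alpha=0.7, label="unique genes")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_profile_heatmap(z_matrix, genome_ids, sample_ids, out_path):
    """Heatmap of Z-normalised RPKG depth profiles (genomes x samples)."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * len(sample_ids), 1 + 0.3 * len(genome_ids)))
    im = ax.imshow(z_matrix, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(sample_ids)), sample_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genome_ids)), genome_ids, fontsize=7)
    fig.colorbar(im, ax=ax, label="Z(RPKG)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
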