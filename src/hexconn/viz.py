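"""Reference figures: the 13-class motif gallery and census bar charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .motifs import MotifProfile, _adj_of, enumerate_classes


def plot_motif_gallery(path=None):
    """Draw the representative digraph of each of the 13 triad classes.

    Lets users line the deterministic numbering up against published motif
    galleries visually; comparisons across conventions should key on
    canonical codes, not ordinals.
    """
    classes = enumerate_classes()
    fig, axes = plt.subplots(2, 7, figsize=(14, 4.2))
    pos = np.array(
        [[0.0, 1.0], [-0.87, -0.5], [0.87, -0.5]]
    )
    for ax, cls in zip(axes.flat, classes):
        adj = _adj_of(cls.canonical_code)
        ax.scatter(pos[:, 0], pos[:, 1], s=200, zorder=3, color="#444")
        for i in range(3):
            for j in range(3):
                if adj[i, j]:
                    d = pos[j] - pos[i]
                    dn = d / np.hypot(*d)
                    off = 0.07 * np.array([-dn[1], dn[0]]) if adj[j, i] else 0.0
                    start = pos[i] + 0.22 * dn + off
                    end = pos[j] - 0.22 * dn + off
                    ax.annotate(
                        "", xy=end, xytext=start,
                        arrowprops=dict(arrowstyle="-|>", lw=1.5, color="#1f77b4"),
                    )
        ax.set_title(f"class {cls.class_id}\n({cls.n_edges} edges)", fontsize=9)
        ax.set_xlim(-1.4, 1.4)
        ax.set_ylim(-1.1, 1.5)
        ax.axis("off")
    axes.flat[-1].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_motif_profile(profile: MotifProfile, path=None, title="Three-node motif profile"):
    """Bar chart of the 13 motif frequencies of one network."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ids = sorted(profile.frequencies)
    ax.bar(ids, [profile.frequencies[i] for i in ids], color="#1f77b4")
    ax.set_xticks(ids)
    ax.set_xlabel("motif class")
    ax.set_ylabel("frequency")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
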