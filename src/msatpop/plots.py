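"""Optional figures: membership bar plot and DAPC scatter/strip plot."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def membership_barplot(q: np.ndarray, sample_ids, path, group_of=None) -> None:
    """Stacked vertical bars of cluster membership per lineage."""
    n, k = q.shape
    fig, ax = plt.subplots(figsize=(max(4, n * 0.35), 2.8))
    bottom = np.zeros(n)
    x = np.arange(n)
    for c in range(k):
        ax.bar(x, q[:, c], bottom=bottom, width=0.9, label=f"cluster {c + 1}")
        bottom += q[:, c]
    ax.set_xticks(x)
    ax.set_xticklabels(sample_ids, rotation=90, fontsize=6)
    ax.set_ylabel("membership")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=6, ncol=k)
    if group_of is not None:
        for i in range(1, n):
            if group_of[sample_ids[i]] != group_of[sample_ids[i - 1]]:
                ax.axvline(i - 0.5, color="k", lw=1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dapc_plot(coords: np.ndarray, groups, path) -> None:
    """Scatter on the first two discriminant axes (strip plot when only one)."""
    uniq = list(dict.fromkeys(groups))
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    y = coords[:, 1] if coords.shape[1] > 1 else np.zeros(coords.shape[0])
    for g in uniq:
        rows = [i for i, lab in enumerate(groups) if lab == g]
        ax.scatter(coords[rows, 0], y[rows], label=g, alpha=0.8)
    ax.set_xlabel("LD1")
    ax.set_ylabel("LD2" if coords.shape[1] > 1 else "")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
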