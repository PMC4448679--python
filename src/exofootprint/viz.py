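"""Plots: sequence color chart, 5' coverage heatmap, footprint profiles.

Every quantity plotted here is also exported as TSV by the CLI; the
figures are derived artifacts only.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .coverage import FootprintProfile, ProfileMatrix
from .dna import encode
from .stats import PermutationEnvelope

_BASE_COLORS = ListedColormap(["#2ca02c", "#1f77b4", "#ff7f0e", "#d62728", "#bbbbbb"])


def plot_sequence_chart(seqs: list[str], path, title: str = "matched sequences") -> None:
    """Color chart of matched sequences, one row per site (A/C/G/T/other)."""
    mat = np.stack([encode(s) for s in seqs])
    height = max(2.0, min(10.0, 0.02 * len(seqs) + 1.5))
    fig, ax = plt.subplots(figsize=(6, height))
    ax.imshow(mat, aspect="auto", cmap=_BASE_COLORS, vmin=0, vmax=4, interpolation="nearest")
    ax.set_xlabel("motif position")
    ax.set_ylabel("site")
    ax.set_title(title)
    handles = [plt.Rectangle((0, 0), 1, 1, color=_BASE_COLORS(i)) for i in range(4)]
    ax.legend(handles, list("ACGT"), loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage_heatmap(matrix: ProfileMatrix, path, title: str = "5' coverage") -> None:
    """Two-panel heatmap of forward and reverse 5' counts per site."""
    order = np.argsort(-matrix.site_totals(), kind="stable")
    vmax = max(1.0, np.percentile(matrix.values, 99.5))
    fig, axes = plt.subplots(1, 2, figsize=(9, 5), sharey=True)
    for ax, s, label in ((axes[0], 0, "forward"), (axes[1], 1, "reverse")):
        im = ax.imshow(
            matrix.values[order, :, s],
            aspect="auto",
            cmap="Reds" if s == 0 else "Blues",
            vmin=0,
            vmax=vmax,
            extent=[matrix.positions[0], matrix.positions[-1], matrix.n_sites, 0],
            interpolation="nearest",
        )
        ax.set_title(label)
        ax.set_xlabel("position relative to motif center (bp)")
        fig.colorbar(im, ax=ax, shrink=0.7)
    axes[0].set_ylabel("sites (most occupied first)")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_footprint(
    profile: FootprintProfile,
    path,
    envelope: PermutationEnvelope | None = None,
    title: str = "footprint profile",
) -> None:
    """Per-site-normalized footprint with optional permuted-motif envelope."""
    fwd, rev = profile.normalized()
    fig, ax = plt.subplots(figsize=(7, 4))
    if envelope is not None:
        ax.fill_between(
            envelope.positions, envelope.forward_q1, envelope.forward_q3,
            color="#d62728", alpha=0.15, linewidth=0,
        )
        ax.fill_between(
            envelope.positions, envelope.reverse_q1, envelope.reverse_q3,
            color="#1f77b4", alpha=0.15, linewidth=0,
        )
        ax.plot(envelope.positions, envelope.forward_median, ":", color="#d62728", lw=1)
        ax.plot(envelope.positions, envelope.reverse_median, ":", color="#1f77b4", lw=1)
    ax.plot(profile.positions, fwd, color="#d62728", lw=1.5, label="forward 5' ends")
    ax.plot(profile.positions, rev, color="#1f77b4", lw=1.5, label="reverse 5' ends")
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_xlabel("position relative to motif center (bp)")
    ax.set_ylabel("mean 5' coverage per site")
    ax.set_title(f"{title} (n={profile.n_sites})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_profiles(profiles: list[FootprintProfile], path, title: str = "clusters") -> None:
    k = len(profiles)
    fig, axes = plt.subplots(k, 1, figsize=(6, 2.2 * k), sharex=True, squeeze=False)
    for c, (ax, pr) in enumerate(zip(axes[:, 0], profiles)):
        fwd, rev = pr.normalized()
        ax.plot(pr.positions, fwd, color="#d62728", lw=1.2)
        ax.plot(pr.positions, rev, color="#1f77b4", lw=1.2)
        ax.set_ylabel(f"cluster {c}\n(n={pr.n_sites})", fontsize=8)
    axes[-1, 0].set_xlabel("position relative to motif center (bp)")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
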