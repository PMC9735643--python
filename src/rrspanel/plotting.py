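"""Optional matplotlib figures: fragment profiles, PCA scatter, assignplots.

Import is deferred to call time and the Agg backend is forced, so headless
pipeline runs never touch a display.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_profiles(profiles: dict[str, "object"], path: str | Path, smoothed: bool = True) -> None:
    """Overlay fragment-mass profiles of several enzyme combinations."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label, profile in profiles.items():
        y = (
            profile.smoothed_mass
            if smoothed and profile.smoothed_mass is not None
            else profile.mass_per_bin
        )
        ax.plot(profile.bin_centers, y, label=label, lw=1.2)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("fragment mass (bp per bin)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca(scores: np.ndarray, labels: Sequence[str], path: str | Path,
             components: tuple[int, int] = (0, 1)) -> None:
    """Scatter two PCs coloured by variety label."""
    plt = _plt()
    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in dict.fromkeys(labels):
        idx = [k for k, l in enumerate(labels) if l == lab]
        ax.scatter(scores[idx, i], scores[idx, j], s=18, label=lab)
    ax.set_xlabel(f"PC{i + 1}")
    ax.set_ylabel(f"PC{j + 1}")
    ax.legend(frameon=False, fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_assignments(posterior: np.ndarray, individuals: Sequence[str],
                     path: str | Path) -> None:
    """Assignplot-style heat map of posterior membership per individual."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * len(individuals))))
    im = ax.imshow(posterior, aspect="auto", cmap="Reds", vmin=0, vmax=1)
    ax.set_xlabel("cluster")
    ax.set_ylabel("individual")
    ax.set_xticks(np.arange(posterior.shape[1]),
                  [str(c + 1) for c in range(posterior.shape[1])])
    ax.set_yticks(np.arange(len(individuals)), individuals, fontsize=4)
    fig.colorbar(im, ax=ax, label="posterior membership")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bic_curve(scan, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(scan.k_values, scan.bic, "o-", ms=4)
    ax.axvline(scan.selected_k, color="crimson", ls="--", lw=1,
               label=f"selected k = {scan.selected_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("BIC")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
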