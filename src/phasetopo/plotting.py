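"""Rendering helpers: TFT label mosaics and TFL heatmaps.

Colors follow the run-wide label colormap (dark blue .. bright yellow,
gray for unassigned); scalp positions use the montage's 2-D projection
(x right, y front).  These are convenience views — all quantitative output
lives in the TSV artifacts.
"""

from __future__ import annotations

import numpy as np

from .labeling import label_color, mask_to_hex
from .maps import TFTMap
from .sim_eeg import ElectrodeMontage


def plot_tft(
    tft: TFTMap,
    montage: ElectrodeMontage,
    universe: set[str] | None = None,
    path: str | None = None,
):
    """Mosaic of scalp maps, one per (band, window) cell of a TFT map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_ch = montage.n_channels
    if universe is None:
        universe = {
            mask_to_hex(int(m), n_ch) for m in np.unique(tft.labels)
        }
    n_bands, n_win, _ = tft.labels.shape
    fig, axes = plt.subplots(
        n_bands, n_win, figsize=(1.1 * n_win, 1.1 * n_bands), squeeze=False
    )
    xy = montage.positions[:, :2]
    for k in range(n_bands):
        for w in range(n_win):
            ax = axes[n_bands - 1 - k, w]  # low bands at the bottom
            colors = [
                np.array(
                    label_color(mask_to_hex(int(tft.labels[k, w, j]), n_ch),
                                universe, n_ch)
                ) / 255.0
                for j in range(n_ch)
            ]
            ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=18)
            ax.set_xticks([])
            ax.set_yticks([])
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_tfl(distances: np.ndarray, n_channels: int, path: str | None = None):
    """Heatmap of a per-channel TFL map with the 0..n_channels scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        distances, aspect="auto", origin="lower", cmap="viridis",
        vmin=0, vmax=n_channels,
    )
    ax.set_xlabel("window")
    ax.set_ylabel("band")
    fig.colorbar(im, ax=ax, label="Levenshtein distance")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
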