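"""Static plots: stability line plots and embedding scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["stability_lineplot", "embedding_scatter"]


def stability_lineplot(records: pd.DataFrame, path: str | Path) -> None:
    """Line plot of per-sample coordinate sums across iterations.

    Each line is one sample; the y-value is x + y of its embedding in
    that iteration, the color its cluster in the last plotted iteration.
    """
    fig, ax = plt.subplots(figsize=(10, 5))
    last_iter = records["iteration"].max()
    last = records[records["iteration"] == last_iter].set_index("sample")
    for sample, sub in records.groupby("sample"):
        sub = sub.sort_values("iteration")
        label = int(last.loc[sample, "label"]) if sample in last.index else 0
        ax.plot(sub["iteration"], sub["coord_sum"], lw=0.8, alpha=0.7,
                color=plt.get_cmap("tab10")(label % 10))
    ax.set_xlabel("iteration")
    ax.set_ylabel("x + y coordinate sum")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def embedding_scatter(
    coords: np.ndarray,
    color: np.ndarray | pd.Series,
    path: str | Path,
    title: str = "",
) -> None:
    """Scatter of one embedding colored by cluster label or reaction value."""
    color = np.asarray(color)
    fig, ax = plt.subplots(figsize=(6, 5))
    if np.issubdtype(color.dtype, np.integer):
        for lab in np.unique(color):
            m = color == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=25,
                       label=f"cluster {lab}" if lab else "outliers",
                       color=plt.get_cmap("tab10")(int(lab) % 10))
        ax.legend(frameon=False, fontsize=8)
    else:
        sc = ax.scatter(coords[:, 0], coords[:, 1], s=25, c=color,
                        cmap="viridis")
        fig.colorbar(sc, ax=ax)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
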