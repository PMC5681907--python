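"""Positional variance diagrams."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["positional_variance_diagram"]


def positional_variance_diagram(
    pv: np.ndarray,
    event_labels: list[str],
    *,
    title: str = "",
    ax: plt.Axes | None = None,
    path: str | Path | None = None,
) -> plt.Axes:
    """Grayscale heatmap of position frequencies, ML ordering on the vertical axis.

    Rows are events in maximum-likelihood order (top = earliest), columns are
    sequence positions; darker means the event lands at that position more
    often. A fully certain sequence appears as a black diagonal.
    """
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(6, max(3, 0.28 * len(event_labels))))
    ax.imshow(pv, cmap="gray_r", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_yticks(range(len(event_labels)))
    ax.set_yticklabels(event_labels, fontsize=7)
    ax.set_xlabel("sequence position")
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        if created:
            plt.close(ax.figure)
    return ax
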