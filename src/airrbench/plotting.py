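"""Basic heatmap output for performance grids."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .benchmark import PerformanceGrid, discretize_boundary

__all__ = ["save_heatmaps"]


def _pivot(df: pd.DataFrame, column: str) -> pd.DataFrame:
    return df.pivot(index="value", columns="witness_rate", values=column)


def save_heatmaps(
    grid: PerformanceGrid,
    directory,
    acc_threshold: float = 0.7,
    sd_threshold: float = 0.1,
    prefix: str = "grid",
) -> list[Path]:
    """Write mean / sd / boundary heatmaps as PNG; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = grid.to_dataframe()
    boundary = discretize_boundary(grid, acc_threshold, sd_threshold)
    df["adequate"] = [
        float(boundary[(v, r)]) for v, r in zip(df["value"], df["witness_rate"])
    ]
    paths = []
    panels = [
        ("mean_balanced_accuracy", "mean balanced accuracy", "viridis", (0.5, 1.0)),
        ("sd_balanced_accuracy", "sd balanced accuracy", "magma", (0.0, 0.25)),
        ("adequate", f"adequate (mean≥{acc_threshold}, sd≤{sd_threshold})", "Blues", (0, 1)),
    ]
    for column, title, cmap, (vmin, vmax) in panels:
        pivot = _pivot(df, column)
        fig, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 2, 0.6 * len(pivot) + 2))
        im = ax.imshow(pivot.values, cmap=cmap, vmin=vmin, vmax=vmax, aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), [str(c) for c in pivot.columns])
        ax.set_yticks(range(len(pivot.index)), [str(i) for i in pivot.index])
        ax.set_xlabel("witness rate (%)")
        ax.set_ylabel("property value")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        path = directory / f"{prefix}_{column}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
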