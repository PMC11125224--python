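"""Attention-node summaries and skeleton overlay figures.

The attention map of a sample is an F x N array in (0, 1). Three views
are exported: the single frame with the largest across-node standard
deviation (where the attention is most selective), the per-sample mean
over frames, and per-level means over samples sharing an ordinal level.
Figures color joints on a fixed [0, 1] scale so they are comparable
across samples and levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .skeleton import SkeletonTopology
from .synth import joint_rest_positions

__all__ = ["AttentionSummary", "select_frame", "summarize", "render",
           "summary_to_csv"]


@dataclass
class AttentionSummary:
    per_frame: np.ndarray  # (F, N)
    frame_selected: int  # 0-based index of the max-std frame
    per_sample_mean: np.ndarray  # (N,)
    per_level_mean: pd.DataFrame  # index = level, columns = joint index; NaN row if empty


def select_frame(v: np.ndarray) -> int:
    """Frame whose attention values have the largest across-node standard
    deviation (population convention; lowest index on ties)."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 1:
        raise ValueError("attention map must be F x N")
    stds = v.std(axis=1)  # population (/N) std; the argmax is convention-free
    return int(np.argmax(stds))


def summarize(v: np.ndarray, level: int,
              level_maps: dict[int, list[np.ndarray]] | None = None) -> AttentionSummary:
    """Summarize one sample's attention map.

    ``level_maps`` optionally supplies per-sample mean attention vectors
    grouped by ordinal level (this sample included) for the per-level
    averages; levels with no samples yield a NaN row.
    """
    v = np.asarray(v, dtype=np.float64)
    per_sample = v.mean(axis=0)
    if level_maps is None:
        level_maps = {level: [per_sample]}
    levels = sorted(level_maps)
    table = pd.DataFrame(
        [
            np.mean(level_maps[lv], axis=0) if level_maps[lv] else
            np.full(v.shape[1], np.nan)
            for lv in levels
        ],
        index=pd.Index(levels, name="level"),
    )
    return AttentionSummary(
        per_frame=v,
        frame_selected=select_frame(v),
        per_sample_mean=per_sample,
        per_level_mean=table,
    )


def summary_to_csv(summary: AttentionSummary, prefix) -> list[str]:
    """Write the summary arrays as CSV files (``<prefix>_frames.csv``,
    ``<prefix>_sample_mean.csv``, ``<prefix>_level_means.csv``)."""
    prefix = str(prefix)
    paths = []
    frames = pd.DataFrame(
        summary.per_frame,
        index=pd.Index(range(1, summary.per_frame.shape[0] + 1), name="frame"),
        columns=[f"joint{j + 1}" for j in range(summary.per_frame.shape[1])],
    )
    frames["selected"] = [int(i == summary.frame_selected) for i in range(len(frames))]
    for name, obj in [
        ("frames", frames),
        ("sample_mean", pd.DataFrame([summary.per_sample_mean],
                                     columns=frames.columns[:-1])),
        ("level_means", summary.per_level_mean),
    ]:
        path = f"{prefix}_{name}.csv"
        obj.to_csv(path)
        paths.append(path)
    return paths


def render(summary: AttentionSummary, topology: SkeletonTopology, out_path) -> str:
    """Draw the skeleton with joints sized/colored by attention at the
    selected frame; deterministic layout, fixed [0, 1] color scale."""
    pos = joint_rest_positions(topology)[:, :2]
    values = summary.per_frame[summary.frame_selected]
    fig, ax = plt.subplots(figsize=(4, 5))
    for i, j in topology.intra_body_edges:
        ax.plot(*zip(pos[i - 1], pos[j - 1]), color="0.6", lw=1.5, zorder=1)
    sc = ax.scatter(
        pos[:, 0], pos[:, 1], c=values, cmap="viridis", vmin=0.0, vmax=1.0,
        s=80 + 320 * values, zorder=2, edgecolors="k", linewidths=0.5,
    )
    fig.colorbar(sc, ax=ax, label="attention")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"frame {summary.frame_selected + 1}")
    fig.savefig(out_path, dpi=110, metadata={"Software": "stagcn"})
    plt.close(fig)
    return str(out_path)
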