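"""Skeleton topology, spatial adjacency partitioning and motion preprocessing.

A skeleton is a static graph of body joints; a motion sequence attaches a
coordinate vector to every joint in every frame. Spatial graph convolution
needs the intra-body adjacency split into partitions (the ST-GCN family's
``uni`` / ``distance`` / ``spatial`` labelling strategies) and each
partition symmetrically normalized with an added self-loop,
``Λ^{-1/2}(A + I)Λ^{-1/2}`` with ``Λ_nn = Σ_i(A_ni + I_ni)``.

Joints are indexed 1..N at the API surface (as in topology JSON files) and
0-based internally; arrays are channel-first ``(C, F, N)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SkeletonTopology",
    "MotionSequence",
    "LabeledSample",
    "SpatialPartition",
    "build_partition",
    "normalize_adjacency",
    "downsample",
    "quartile_bin",
    "load_topology",
    "save_topology",
    "load_motion_csv",
    "save_motion_csv",
    "save_dataset_h5",
    "load_dataset_h5",
    "save_dataset_csv",
    "load_dataset_csv",
]

PARTITION_STRATEGIES = ("uni", "distance", "spatial")


@dataclass(frozen=True)
class SkeletonTopology:
    """Joints, intra-body edges and the root joint of a skeleton graph.

    Edges are unordered 1-based joint-index pairs; the root joint anchors
    the centripetal/centrifugal spatial partitioning.
    """

    n_joints: int
    joint_names: tuple[str, ...]
    intra_body_edges: tuple[tuple[int, int], ...]
    root_joint: int = 1

    def __post_init__(self):
        n = self.n_joints
        if n < 1:
            raise ValueError("n_joints must be positive")
        if len(self.joint_names) != n:
            raise ValueError("joint_names length must equal n_joints")
        if not 1 <= self.root_joint <= n:
            raise ValueError("root_joint out of range")
        seen = set()
        for i, j in self.intra_body_edges:
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValueError(f"edge ({i},{j}) endpoint out of [1..{n}]")
            if i == j:
                raise ValueError(f"self-loop edge ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add(key)
        if n > 1 and not nx.is_connected(self.graph()):
            warnings.warn("skeleton graph is not connected", stacklevel=2)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_joints))
        g.add_edges_from((i - 1, j - 1) for i, j in self.intra_body_edges)
        return g

    def adjacency(self) -> np.ndarray:
        """Symmetric binary N x N adjacency (no self-loops)."""
        a = np.zeros((self.n_joints, self.n_joints))
        for i, j in self.intra_body_edges:
            a[i - 1, j - 1] = a[j - 1, i - 1] = 1.0
        return a


@dataclass
class MotionSequence:
    """One trial: an F x N x C array of joint coordinates (default C=3)."""

    data: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("motion data must be F x N x C")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("motion data contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_joints(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def channel_first(self) -> np.ndarray:
        """Return the (C, F, N) view used by the network."""
        return np.ascontiguousarray(self.data.transpose(2, 0, 1))


@dataclass
class LabeledSample:
    """A motion sequence with its ordinal skill label (1..M)."""

    sequence: MotionSequence
    label: int
    score: float | None = None
    split: str = "train"
    sample_id: str = ""

    def __post_init__(self):
        if int(self.label) != self.label or self.label < 1:
            raise ValueError("label must be a positive integer")
        self.label = int(self.label)


@dataclass
class SpatialPartition:
    """H binary N x N matrices covering the skeleton adjacency.

    ``matrices[h][n, m] = 1`` means node ``m`` contributes to node ``n``
    in partition ``h``.
    """

    matrices: np.ndarray  # (H, N, N)
    strategy: str
    normalized: np.ndarray = field(init=False)

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("partition must be (H, N, N)")
        if np.any(self.matrices < 0):
            raise ValueError("partition matrices must be nonnegative")
        self.normalized = np.stack([normalize_adjacency(a) for a in self.matrices])

    @property
    def n_partitions(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_joints(self) -> int:
        return self.matrices.shape[1]


def build_partition(topology: SkeletonTopology, strategy: str = "spatial") -> SpatialPartition:
    """Split the skeleton adjacency into partition matrices.

    ``uni``: one matrix, all neighbours.  ``distance``: self vs. neighbours.
    ``spatial``: self (plus equal-hop-distance neighbours), centripetal
    (neighbour closer to the root) and centrifugal (farther).  Nodes
    unreachable from the root fall back to the plain neighbour class with
    a warning.
    """
    if strategy not in PARTITION_STRATEGIES:
        raise ValueError(f"unknown partition strategy {strategy!r}")
    n = topology.n_joints
    adj = topology.adjacency()
    if strategy == "uni":
        return SpatialPartition(adj[None], strategy)
    if strategy == "distance":
        return SpatialPartition(np.stack([np.eye(n), adj]), strategy)

    dist = nx.single_source_shortest_path_length(topology.graph(), topology.root_joint - 1)
    mats = np.zeros((3, n, n))
    mats[0] += np.eye(n)
    warned = False
    for i in range(n):
        for j in range(n):
            if adj[i, j] == 0:
                continue
            if i not in dist or j not in dist:
                if not warned:
                    warnings.warn(
                        "node(s) unreachable from root; using distance-style "
                        "partition for their edges",
                        stacklevel=2,
                    )
                    warned = True
                mats[1, i, j] = 1.0
            elif dist[j] < dist[i]:
                mats[1, i, j] = 1.0  # centripetal: source closer to root
            elif dist[j] > dist[i]:
                mats[2, i, j] = 1.0  # centrifugal
            else:
                mats[0, i, j] = 1.0  # equal hop distance joins the self class
    return SpatialPartition(mats, strategy)


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: Λ^{-1/2}(A + I)Λ^{-1/2}."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("adjacency must be nonnegative and finite")
    ai = a + np.eye(a.shape[0])
    d = ai.sum(axis=1)  # >= 1 always, no degenerate rows
    dinv = d**-0.5
    return dinv[:, None] * ai * dinv[None, :]


def downsample(seq: MotionSequence, target_frames: int) -> MotionSequence:
    """Keep ``target_frames`` frames at regular intervals (pure index
    selection, endpoints retained; no interpolation)."""
    f = seq.n_frames
    if target_frames < 2:
        raise ValueError("target_frames must be at least 2")
    if target_frames > f:
        raise ValueError(f"target_frames {target_frames} exceeds frame count {f}")
    idx = np.floor(np.linspace(0, f - 1, target_frames) + 0.5).astype(int)
    return MotionSequence(seq.data[idx], frame_rate=seq.frame_rate)


def quartile_bin(scores, m: int = 4) -> np.ndarray:
    """Assign ordinal labels 1..m by m-quantile cut points of the scores.

    Higher score -> higher label; a score exactly on a cut point goes to
    the lower class.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if m < 2:
        raise ValueError("need at least two classes")
    if np.unique(scores).size < m:
        raise ValueError(f"need at least {m} distinct scores")
    cuts = np.quantile(scores, np.arange(1, m) / m)
    return 1 + (cuts[None, :] < scores[:, None]).sum(axis=1)


# ---------------------------------------------------------------------- I/O
def load_topology(path) -> SkeletonTopology:
    """Read a topology JSON: {"joints": [...], "edges": [[i,j],...], "root": r}."""
    with open(path) as fh:
        obj = json.load(fh)
    joints = tuple(obj["joints"])
    edges = tuple((int(i), int(j)) for i, j in obj["edges"])
    return SkeletonTopology(len(joints), joints, edges, int(obj.get("root", 1)))


def save_topology(topology: SkeletonTopology, path) -> None:
    obj = {
        "joints": list(topology.joint_names),
        "edges": [list(e) for e in topology.intra_body_edges],
        "root": topology.root_joint,
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def load_motion_csv(path, n_joints: int, n_channels: int = 3) -> MotionSequence:
    """One row per frame, joint-major columns (j1_c1, j1_c2, ..., jN_cC)."""
    arr = pd.read_csv(path, header=None).to_numpy(dtype=np.float64)
    if arr.shape[1] != n_joints * n_channels:
        raise ValueError(
            f"expected {n_joints * n_channels} columns, found {arr.shape[1]}"
        )
    return MotionSequence(arr.reshape(arr.shape[0], n_joints, n_channels))


def save_motion_csv(seq: MotionSequence, path) -> None:
    flat = seq.data.reshape(seq.n_frames, -1)
    pd.DataFrame(flat).to_csv(path, header=False, index=False)


def save_dataset_h5(samples: list[LabeledSample], path) -> None:
    """Write samples to an HDF5 container (groups sample_0000, ... with
    /data, /label, /score, /split) plus a root-level manifest."""
    with h5py.File(path, "w") as fh:
        for k, s in enumerate(samples):
            g = fh.create_group(f"sample_{k:04d}")
            g.create_dataset("data", data=s.sequence.data)
            g.attrs["label"] = s.label
            g.attrs["split"] = s.split
            g.attrs["sample_id"] = s.sample_id or f"sample_{k:04d}"
            if s.score is not None:
                g.attrs["score"] = float(s.score)


def save_dataset_csv(samples: list[LabeledSample], directory) -> None:
    """Write one motion CSV per sample plus a ``manifest.csv`` mapping
    file -> label / score / split."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, s in enumerate(samples):
        sid = s.sample_id or f"sample_{k:04d}"
        fname = f"{sid}.csv"
        save_motion_csv(s.sequence, directory / fname)
        rows.append({"file": fname, "sample_id": sid, "label": s.label,
                     "score": s.score, "split": s.split,
                     "n_joints": s.sequence.n_joints,
                     "n_channels": s.sequence.n_channels})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def load_dataset_csv(directory) -> list[LabeledSample]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    samples = []
    for row in manifest.itertuples():
        seq = load_motion_csv(directory / row.file, int(row.n_joints),
                              int(row.n_channels))
        score = None if pd.isna(row.score) else float(row.score)
        samples.append(LabeledSample(seq, int(row.label), score=score,
                                     split=str(row.split),
                                     sample_id=str(row.sample_id)))
    return samples


def load_dataset_h5(path) -> list[LabeledSample]:
    samples = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            samples.append(
                LabeledSample(
                    sequence=MotionSequence(g["data"][...]),
                    label=int(g.attrs["label"]),
                    score=float(g.attrs["score"]) if "score" in g.attrs else None,
                    split=str(g.attrs.get("split", "train")),
                    sample_id=str(g.attrs.get("sample_id", key)),
                )
            )
    return samples
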