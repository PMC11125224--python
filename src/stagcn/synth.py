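"""Synthetic skeleton motion with controllable ordinal skill structure.

The generator emulates the empirical signature the model is built to
detect: higher skill levels recruit additional (here, upper-body)
joints. Every sample is a sinusoidal gait-like trajectory around a
stick-figure rest pose; samples of ordinal level l add an extra motion
amplitude ``l * effect_size`` on a designated set of salient joints, plus
isotropic Gaussian noise. Non-salient joints carry no class information
by construction, which gives a ground-truth importance map for attention
sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import LabeledSample, MotionSequence, SkeletonTopology

__all__ = ["SynthConfig", "make_topology", "joint_rest_positions", "generate_dataset",
           "importance_map"]


@dataclass
class SynthConfig:
    """Generator settings.

    ``effect_size`` is the per-level increment of salient-joint motion
    amplitude (same units as the coordinates, i.e. body-lengths);
    ``noise_sd`` the coordinate-wise Gaussian noise standard deviation.
    ``salient_joints`` are 1-based; the default (set in __post_init__)
    marks the arm chains - the "upper body" of the stick figure.
    """

    n_joints: int = 8
    frames: int = 32
    n_classes: int = 4
    samples_per_class: int = 40
    effect_size: float = 1.0
    noise_sd: float = 0.1
    salient_joints: tuple[int, ...] = ()
    seed: int = 0
    split_seed: int = 12345  # independent of the data seed
    test_fraction: float = 0.2
    base_amplitude: float = 0.3
    gait_cycles: float = 2.0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two ordinal classes")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be positive")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be nonnegative")
        if not self.salient_joints:
            topo = make_topology(self.n_joints)
            self.salient_joints = tuple(
                i + 1 for i, name in enumerate(topo.joint_names) if "arm" in name
            ) or (self.n_joints,)
        if any(not 1 <= j <= self.n_joints for j in self.salient_joints):
            raise ValueError("salient joints out of range")


_CHAINS = ("spine", "l_arm", "r_arm", "l_leg", "r_leg")
# 2-D layout directions for each chain, used for rest poses and plotting
_CHAIN_DIR = {
    "spine": (0.0, 1.0),
    "l_arm": (-0.8, 0.3),
    "r_arm": (0.8, 0.3),
    "l_leg": (-0.4, -1.0),
    "r_leg": (0.4, -1.0),
}


def make_topology(n_joints: int) -> SkeletonTopology:
    """Deterministic stick-figure tree: pelvis root, spine chain (arms
    attach to its top), two arms, two legs; joints are dealt to the chains
    round-robin until ``n_joints`` is reached."""
    if n_joints < 2:
        raise ValueError("need at least two joints")
    names = ["pelvis"]
    parent: list[int] = [0]  # parent joint index (0-based), root points at itself
    chain_tip = {name: 0 for name in _CHAINS}  # current attachment point
    chain_len = {name: 0 for name in _CHAINS}
    i = 0
    while len(names) < n_joints:
        chain = _CHAINS[i % len(_CHAINS)]
        i += 1
        if chain in ("l_arm", "r_arm"):
            # arms hang off the top of the spine when it exists
            attach = chain_tip[chain] if chain_len[chain] else chain_tip["spine"]
        else:
            attach = chain_tip[chain]
        chain_len[chain] += 1
        names.append(f"{chain}{chain_len[chain]}")
        parent.append(attach)
        chain_tip[chain] = len(names) - 1
    edges = tuple((parent[j] + 1, j + 1) for j in range(1, n_joints))
    return SkeletonTopology(n_joints, tuple(names), edges, root_joint=1)


def joint_rest_positions(topology: SkeletonTopology) -> np.ndarray:
    """(N, 3) deterministic rest pose (z = 0), also used as plot layout."""
    pos = np.zeros((topology.n_joints, 3))
    children: dict[int, list[int]] = {}
    parent = {}
    for a, b in topology.intra_body_edges:
        parent[b - 1] = a - 1
        children.setdefault(a - 1, []).append(b - 1)
    step = 0.5
    for j in range(1, topology.n_joints):
        name = topology.joint_names[j]
        chain = name.rstrip("0123456789")
        dx, dy = _CHAIN_DIR.get(chain, (0.0, 1.0))
        norm = float(np.hypot(dx, dy))
        pos[j, 0] = pos[parent[j], 0] + step * dx / norm
        pos[j, 1] = pos[parent[j], 1] + step * dy / norm
    return pos


def generate_dataset(cfg: SynthConfig) -> list[LabeledSample]:
    """Generate a shuffled, stratified-split labelled dataset.

    Levels 1..M share the same base gait; level l moves the salient
    joints with extra amplitude ``l * effect_size``. With effect_size 0
    the class-conditional distributions are identical.
    """
    topo = make_topology(cfg.n_joints)
    rest = joint_rest_positions(topo)
    rng = np.random.default_rng(cfg.seed)
    n, f, m = cfg.n_joints, cfg.frames, cfg.n_classes
    t = np.linspace(0.0, 1.0, f, endpoint=False)
    phase = 2.0 * np.pi * np.arange(n) / n  # deterministic per-joint phase offsets
    # deterministic unit motion direction per joint (mostly sagittal)
    ang = np.pi / 5.0 * np.arange(n)
    direction = np.stack([np.cos(ang), np.sin(ang), 0.2 * np.ones(n)], axis=1)
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    salient = np.zeros(n, dtype=bool)
    salient[[j - 1 for j in cfg.salient_joints]] = True

    samples: list[LabeledSample] = []
    for level in range(1, m + 1):
        for k in range(cfg.samples_per_class):
            jitter = rng.uniform(0.0, 2.0 * np.pi)
            carrier = np.sin(
                2.0 * np.pi * cfg.gait_cycles * t[:, None] + phase[None, :] + jitter
            )  # (F, N)
            amp = np.full(n, cfg.base_amplitude)
            amp[salient] += level * cfg.effect_size
            motion = carrier[:, :, None] * amp[None, :, None] * direction[None, :, :]
            data = rest[None, :, :] + motion
            data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
            score = level + rng.uniform(-0.25, 0.25)
            samples.append(
                LabeledSample(
                    sequence=MotionSequence(data),
                    label=level,
                    score=float(score),
                    sample_id=f"L{level}_{k:03d}",
                )
            )

    # stratified split, then a global shuffle; both driven by split_seed so
    # the partition is independent of the data randomness
    split_rng = np.random.default_rng(cfg.split_seed)
    for level in range(1, m + 1):
        idx = [i for i, s in enumerate(samples) if s.label == level]
        n_test = int(round(cfg.test_fraction * len(idx)))
        test_idx = split_rng.choice(idx, size=n_test, replace=False)
        for i in test_idx:
            samples[i].split = "test"
    order = split_rng.permutation(len(samples))
    return [samples[i] for i in order]


def importance_map(cfg: SynthConfig) -> np.ndarray:
    """(F, N) binary ground-truth importance: 1 on salient joints."""
    mask = np.zeros((cfg.frames, cfg.n_joints))
    for j in cfg.salient_joints:
        mask[:, j - 1] = 1.0
    return mask
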