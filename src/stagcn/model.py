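"""The full classifier: feature extractor -> attention branch ->
confidence reweighting -> perception branch, with ablation variants.

Variants (mirroring the ablation grid):

* ``stgcn``   - attention bypassed entirely (V=1, C=1, E=0): a plain
                spatiotemporal GCN classifier; only ``p_per`` is produced.
* ``stagcn``  - attention nodes/edges active, no confidence (C=1).
* ``confsta`` - sample-level confidence (one scalar per sample).
* ``pm``      - node-level confidence (per joint per frame), the full model.

During training the reference class for the confidence probe is the
ground-truth label; at inference it is the argmax of the unmasked
attention-branch posterior.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import (
    AttentionBranch,
    apply_attention,
    apply_confidence,
    confidence_matrix,
)
from .autodiff import Tensor
from .graph_conv import FeatureExtractor
from .perception import PerceptionBranch
from .skeleton import SkeletonTopology, build_partition

__all__ = ["ModelConfig", "ModelOutput", "SkillClassifier", "save_checkpoint", "load_checkpoint"]

VARIANTS = ("stgcn", "stagcn", "confsta", "pm")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The default is the desk-scale preset (three extractor blocks at
    16/32/64 channels); ``paper_scale()`` returns an ST-GCN-sized stack.
    """

    n_classes: int = 4
    in_channels: int = 3
    fe_channels: list[int] = field(default_factory=lambda: [16, 32, 64])
    mid_channels: int = 32
    n_head_blocks: int = 2
    kernel_size: int = 9
    dropout: float = 0.1
    partition_strategy: str = "spatial"
    edge_heads: int = 3
    edge_dim: int = 8
    node_hidden: int = 16
    variant: str = "pm"
    confidence_mode: str = "node_frame"
    perception_input: str = "confidence_adjusted"  # or "raw"
    seed: int = 0

    @staticmethod
    def paper_scale(**overrides) -> "ModelConfig":
        cfg = ModelConfig(fe_channels=[64, 64, 128, 128, 256], mid_channels=256)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.kernel_size % 2 == 0:
            raise ValueError("temporal kernel size must be odd")
        if self.variant == "confsta":
            self.confidence_mode = "sample"


@dataclass
class ModelOutput:
    p_per: Tensor
    p_att: Tensor | None
    v: Tensor | None  # attention nodes (B, F, N)
    e: Tensor | None  # attention edges (B, phi, N, N)
    c: np.ndarray | None  # confidence matrix (B, F, N), detached
    yfe: Tensor

    def predicted(self, branch: str = "per") -> np.ndarray:
        """1-based argmax labels (lowest index wins ties)."""
        p = self.p_per if branch == "per" else self.p_att
        return np.argmax(p.data, axis=1) + 1


class SkillClassifier:
    """End-to-end expert-novice level classifier over skeleton motion."""

    def __init__(self, topology: SkeletonTopology, config: ModelConfig):
        self.topology = topology
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.partition = build_partition(topology, config.partition_strategy)
        self.extractor = FeatureExtractor(
            self.partition, config.fe_channels, config.in_channels,
            config.kernel_size, rng, dropout=config.dropout,
        )
        fe_out = self.extractor.out_channels
        self.attention = AttentionBranch(
            fe_out, config.n_classes, rng,
            hidden=config.node_hidden, edge_heads=config.edge_heads,
            edge_dim=config.edge_dim,
        )
        per_in = config.in_channels if config.perception_input == "raw" else fe_out
        self.perception = PerceptionBranch(
            self.partition, per_in, config.mid_channels, config.n_classes,
            config.edge_heads, config.kernel_size, rng,
            n_head_blocks=config.n_head_blocks, dropout=config.dropout,
        )
        self._modules = [self.extractor, self.attention, self.perception]

    # --------------------------------------------------------------- plumbing
    def parameters(self):
        return [p for m in self._modules for p in m.parameters()]

    def named_parameters(self):
        for prefix, m in zip(("extractor", "attention", "perception"), self._modules):
            for name, p in m.named_parameters(prefix + "."):
                yield name, p

    def train(self, mode: bool = True):
        for m in self._modules:
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for m in self._modules:
            m.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for prefix, m in zip(("extractor", "attention", "perception"), self._modules):
            for name, arr in m.state_dict().items():
                state[f"{prefix}.{name}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, m in zip(("extractor", "attention", "perception"), self._modules):
            sub = {
                name[len(prefix) + 1:]: arr
                for name, arr in state.items()
                if name.startswith(prefix + ".")
            }
            m.load_state_dict(sub)

    # ---------------------------------------------------------------- forward
    def forward(self, x, ref_classes=None) -> ModelOutput:
        """Run the network on a (B, C, F, N) batch.

        ``ref_classes``: 1-based ground-truth labels used as the confidence
        reference during training; when omitted the unmasked attention-branch
        prediction is used instead.
        """
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        cfg = self.config
        yfe = self.extractor(x)
        b, _, f, n = yfe.shape

        if cfg.variant == "stgcn":
            # attention bypassed: identity gates, empty attention graph
            e = Tensor(np.zeros((b, cfg.edge_heads, n, n)))
            x_per = x if cfg.perception_input == "raw" else yfe
            p_per = self.perception(x_per, e)
            return ModelOutput(p_per=p_per, p_att=None, v=None, e=e, c=None, yfe=yfe)

        v = self.attention.attention_nodes(yfe, f)
        e = self.attention.attention_edges(yfe)
        yan = apply_attention(yfe, v)
        p_att = self.attention.posterior(yan)

        c_arr = None
        if cfg.variant in ("confsta", "pm"):
            weight, bias = self.attention.head_arrays()
            if ref_classes is None:
                ref = np.argmax(p_att.data, axis=1) + 1
            else:
                ref = np.asarray(ref_classes, dtype=int)
            # measurement only: computed on detached arrays, re-entering the
            # graph as a constant
            c_arr = confidence_matrix(
                v.data, yfe.data, weight, bias, ref, mode=cfg.confidence_mode
            )
            x_att = apply_confidence(yan, Tensor(c_arr))
        else:  # stagcn: no confidence adjustment
            x_att = yan

        x_per = x if cfg.perception_input == "raw" else x_att
        p_per = self.perception(x_per, e)
        return ModelOutput(p_per=p_per, p_att=p_att, v=v, e=e, c=c_arr, yfe=yfe)

    __call__ = forward


def save_checkpoint(model: SkillClassifier, path) -> None:
    """Write parameters, buffers and the full configuration to an .npz file."""
    meta = {
        "config": asdict(model.config),
        "topology": {
            "joints": list(model.topology.joint_names),
            "edges": [list(e) for e in model.topology.intra_body_edges],
            "root": model.topology.root_joint,
        },
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> SkillClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    topo_meta = meta["topology"]
    topology = SkeletonTopology(
        len(topo_meta["joints"]), tuple(topo_meta["joints"]),
        tuple(tuple(e) for e in topo_meta["edges"]), topo_meta["root"],
    )
    model = SkillClassifier(topology, ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model
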