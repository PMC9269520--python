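"""The multiple-input-branch (MIB) spatiotemporal graph convolutional network.

Architecture
------------
Each selected input branch (joint / velocity / bone, 6 channels each) is
encoded by its own stack::

    input batchnorm (over the joint·channel axis)
    → initial ST-GCN block (6 → W, no attention)
    → 3 attention-equipped ST-GCN blocks (W → W/2 → W/2 → W)

The branch outputs are fused by channel concatenation and sent through a
two-block mainstream whose first temporal layer in each block has stride
2, compressing the frame axis twice.  A global average pool over frames
and joints feeds a fully connected classifier.

An ST-GCN block is a spatial graph convolution over the partitioned
skeleton adjacency followed by ``block_depth`` temporal convolutions
(separable by default), with batch normalization, a residual connection
from the block input (1×1-projected when shape or stride differ) and —
where enabled — spatiotemporal joint attention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import BRANCH_NAMES
from .graph import SkeletonGraph, kinect_v2_graph, partition_adjacency
from . import nn

__all__ = [
    "ModelConfig",
    "STGCNBlock",
    "MIBNetwork",
    "build_mib_network",
    "count_parameters",
    "temporal_weight_count",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the MIB ST-GCN.

    ``branch_width`` is the output width W of each branch (the interior
    bottleneck blocks use W/2); ``main_width`` is the first mainstream
    width (the second mainstream block doubles it).
    """

    branch_width: int = 64
    main_width: int = 128
    block_depth: int = 2
    temporal_kernel: int = 9
    attention_reduction: int = 4
    strategy: str = "spatial-configuration"
    num_classes: int = 6
    separable: bool = True
    attention_on: bool = True
    seed: int = 0
    branches: tuple[str, ...] = BRANCH_NAMES
    in_channels: int = 6
    attention_in_mainstream: bool = False
    edge_importance: bool = False

    def __post_init__(self) -> None:
        if self.temporal_kernel % 2 == 0:
            raise ValueError("temporal_kernel must be odd")
        if not self.branches:
            raise ValueError("at least one input branch is required")
        unknown = set(self.branches) - set(BRANCH_NAMES)
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")
        half = max(1, self.branch_width // 2)
        for width in (half, self.branch_width):
            if self.attention_on and width % self.attention_reduction:
                raise ValueError(
                    f"attention_reduction {self.attention_reduction} must "
                    f"divide the attention-site width {width}"
                )

    def with_branches(self, branches: tuple[str, ...]) -> "ModelConfig":
        return replace(self, branches=tuple(branches))


class STGCNBlock(nn.Layer):
    """One spatial graph convolution + temporal convolution block."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        adjacency: np.ndarray,
        *,
        kernel: int,
        stride: int,
        depth: int,
        separable: bool,
        attention: bool,
        reduction: int,
        edge_importance: bool,
        next_rng,
    ):
        super().__init__()
        self.gcn = self.add_child(
            nn.SpatialGraphConv(
                in_channels, out_channels, adjacency, next_rng(),
                edge_importance=edge_importance,
            )
        )
        self.bn0 = self.add_child(nn.BatchNorm(out_channels))
        self.relu0 = self.add_child(nn.ReLU())
        self.tcs: list[tuple[nn.TemporalConv, nn.BatchNorm, nn.ReLU | None]] = []
        for i in range(depth):
            tc = self.add_child(
                nn.TemporalConv(
                    out_channels, out_channels, kernel,
                    stride if i == 0 else 1, separable, next_rng(),
                )
            )
            bn = self.add_child(nn.BatchNorm(out_channels))
            act = self.add_child(nn.ReLU()) if i < depth - 1 else None
            self.tcs.append((tc, bn, act))
        # the attention slot always consumes one rng so that models with
        # and without attention share all other initial weights
        att_rng = next_rng()
        self.attention = (
            self.add_child(
                nn.STJointAttention(out_channels, reduction, att_rng)
            )
            if attention
            else None
        )
        res_rng = next_rng()
        if in_channels == out_channels and stride == 1:
            self.res: tuple[nn.TemporalConv, nn.BatchNorm] | None = None
        else:
            self.res = (
                self.add_child(
                    nn.TemporalConv(in_channels, out_channels, 1, stride,
                                    False, res_rng)
                ),
                self.add_child(nn.BatchNorm(out_channels)),
            )
        self.relu_out = self.add_child(nn.ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        h = self.relu0(self.bn0(self.gcn(x)))
        for tc, bn, act in self.tcs:
            h = bn(tc(h))
            if act is not None:
                h = act(h)
        if self.attention is not None:
            h = self.attention(h)
        if self.res is None:
            r = x
        else:
            r = self.res[1](self.res[0](x))
        return self.relu_out(h + r)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gy)
        gh = g
        if self.res is None:
            gr = g
        else:
            gr = self.res[0].backward(self.res[1].backward(g))
        if self.attention is not None:
            gh = self.attention.backward(gh)
        for tc, bn, act in reversed(self.tcs):
            if act is not None:
                gh = act.backward(gh)
            gh = tc.backward(bn.backward(gh))
        gh = self.gcn.backward(self.bn0.backward(self.relu0.backward(gh)))
        return gh + gr


class MIBNetwork(nn.Layer):
    """The full multi-branch network.

    ``forward`` takes a dict mapping branch name → (N, 6, T, V) array
    (channel-first, the conventional feature-map layout) and returns
    (N, num_classes) logits.  The final pre-pool feature map and the
    classifier weights are exposed for class-activation mapping.
    """

    def __init__(self, config: ModelConfig,
                 graph: SkeletonGraph | None = None):
        super().__init__()
        self.config = config
        self.graph = graph if graph is not None else kinect_v2_graph()
        adj = partition_adjacency(self.graph, config.strategy).stacked()
        V = self.graph.num_joints

        seed_seq = np.random.SeedSequence(config.seed)

        def next_rng() -> np.random.Generator:
            return np.random.default_rng(seed_seq.spawn(1)[0])

        w = config.branch_width
        half = max(1, w // 2)
        block_kw = dict(
            kernel=config.temporal_kernel,
            depth=config.block_depth,
            separable=config.separable,
            reduction=config.attention_reduction,
            edge_importance=config.edge_importance,
            next_rng=next_rng,
        )

        self.branch_names = tuple(config.branches)
        self.branches: dict[str, list[nn.Layer]] = {}
        for name in BRANCH_NAMES:  # fixed order → reproducible rng stream
            if name not in self.branch_names:
                continue
            stack: list[nn.Layer] = [
                self.add_child(nn.InputBatchNorm(V, config.in_channels))
            ]
            widths = [(config.in_channels, w, False),
                      (w, half, config.attention_on),
                      (half, half, config.attention_on),
                      (half, w, config.attention_on)]
            for cin, cout, att in widths:
                stack.append(
                    self.add_child(
                        STGCNBlock(cin, cout, adj, stride=1,
                                   attention=att, **block_kw)
                    )
                )
            self.branches[name] = stack

        fused = w * len(self.branch_names)
        main_att = config.attention_on and config.attention_in_mainstream
        self.mainstream = [
            self.add_child(
                STGCNBlock(fused, config.main_width, adj, stride=2,
                           attention=main_att, **block_kw)
            ),
            self.add_child(
                STGCNBlock(config.main_width, 2 * config.main_width, adj,
                           stride=2, attention=main_att, **block_kw)
            ),
        ]
        self.gap = self.add_child(nn.GlobalAveragePool())
        self.fc = self.add_child(
            nn.Linear(2 * config.main_width, config.num_classes, next_rng())
        )
        self.feature_map: np.ndarray | None = None

    # ---- forward / backward -------------------------------------------

    @staticmethod
    def _to_ntvc(x: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(
            x.transpose(0, 2, 3, 1), dtype=nn.DTYPE
        )

    def forward(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        missing = set(self.branch_names) - set(inputs)
        if missing:
            raise ValueError(f"missing input branches: {sorted(missing)}")
        outs = []
        for name in self.branch_names:
            h = self._to_ntvc(inputs[name])
            if h.shape[2] != self.graph.num_joints:
                raise ValueError(
                    f"branch {name!r} has {h.shape[2]} joints, expected "
                    f"{self.graph.num_joints}"
                )
            for layer in self.branches[name]:
                h = layer(h)
            outs.append(h)
        h = np.concatenate(outs, axis=-1)
        self._fused_widths = [o.shape[-1] for o in outs]
        for blk in self.mainstream:
            h = blk(h)
        self.feature_map = h  # (N, T', V, C) — consumed by CAM
        return self.fc(self.gap(h))

    def backward(self, glogits: np.ndarray) -> None:
        g = self.gap.backward(self.fc.backward(glogits))
        for blk in reversed(self.mainstream):
            g = blk.backward(g)
        start = 0
        for name, width in zip(self.branch_names, self._fused_widths):
            gb = g[..., start : start + width]
            start += width
            for layer in reversed(self.branches[name]):
                gb = layer.backward(gb)

    # ---- introspection -------------------------------------------------

    def set_attention_identity(self, on: bool) -> None:
        """Force every attention module to the identity mask (ablation)."""
        for layer in self._iter_layers():
            if isinstance(layer, nn.STJointAttention):
                layer.identity_mode = on

    def attention_scores(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(frame_scores, joint_scores) of each attention site, last pass."""
        return [
            layer.last_scores
            for layer in self._iter_layers()
            if isinstance(layer, nn.STJointAttention)
            and layer.last_scores is not None
        ]

    def _iter_layers(self):
        stack = list(self._children)
        while stack:
            layer = stack.pop()
            yield layer
            stack.extend(layer._children)

    def classifier_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(C × num_classes weight matrix, bias) of the final FC layer."""
        return self.fc.W.data, self.fc.b.data

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: "
                    f"{p.data.shape} vs {arr.shape}"
                )
            p.data[...] = arr


def build_mib_network(
    config: ModelConfig, graph: SkeletonGraph | None = None
) -> MIBNetwork:
    """Construct the MIB ST-GCN for a skeleton graph (default Kinect V2)."""
    return MIBNetwork(config, graph)


def save_checkpoint(model: MIBNetwork, path) -> None:
    """Write model weights to HDF5 with the config echoed as attributes."""
    import json

    import h5py
    from dataclasses import asdict

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("weights")
        for i, p in enumerate(model.parameters()):
            grp.create_dataset(f"p{i:04d}", data=p.data)
        h5.attrs["config"] = json.dumps(asdict(model.config))


def load_checkpoint(path, graph: SkeletonGraph | None = None) -> MIBNetwork:
    """Rebuild a model from an HDF5 checkpoint written by save_checkpoint."""
    import json

    import h5py

    with h5py.File(path, "r") as h5:
        raw = json.loads(h5.attrs["config"])
        raw["branches"] = tuple(raw["branches"])
        config = ModelConfig(**raw)
        model = MIBNetwork(config, graph)
        grp = h5["weights"]
        state = [grp[k][()] for k in sorted(grp.keys())]
    model.load_state(state)
    return model


def temporal_weight_count(
    in_channels: int, out_channels: int, kernel: int, separable: bool
) -> int:
    """Closed-form weight count of one temporal layer (biases excluded).

    Standard convolution: k·C_in·C_out.  Separable: k·C_in (depth-wise)
    + C_in·C_out (point-wise).
    """
    if separable:
        return kernel * in_channels + in_channels * out_channels
    return kernel * in_channels * out_channels


def count_parameters(
    model: MIBNetwork, separable_comparison: bool = False
) -> dict:
    """Per-layer and total trainable-parameter counts.

    With ``separable_comparison`` the report also lists, for every
    temporal layer, the weight count of the standard convolution against
    its separable factorization at the same geometry.
    """
    per_layer = [(p.name, p.size) for p in model.parameters()]
    report: dict = {
        "per_layer": per_layer,
        "total": int(sum(n for _, n in per_layer)),
    }
    if separable_comparison:
        rows = []
        for layer in model._iter_layers():
            if isinstance(layer, nn.TemporalConv) and layer.kernel > 1:
                rows.append(
                    {
                        "in_channels": layer.in_channels,
                        "out_channels": layer.out_channels,
                        "kernel": layer.kernel,
                        "standard": temporal_weight_count(
                            layer.in_channels, layer.out_channels,
                            layer.kernel, False),
                        "separable": temporal_weight_count(
                            layer.in_channels, layer.out_channels,
                            layer.kernel, True),
                    }
                )
        report["temporal_layers"] = rows
    return report
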