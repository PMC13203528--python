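"""Four-branch dual-frame fall classifier network.

The classifier receives four 3x87 streams per window — body-frame and
global-frame acceleration and angular rate — and processes each with an
independent spatio-temporal feature extractor (STFE) of identical structure:

    DS-SE(3->16, k=9) -> MaxPool(2) -> DS-SE(16->32, k=7)
    -> 2 causal temporal blocks (k=3, dilations 1 and 2)
    -> GroupNorm -> global average pool -> 32-dim feature

The four 32-dim features are concatenated (128-dim) and classified by a
two-layer head (128 -> 48 -> 2, batch norm + SiLU + dropout in between,
softmax output).  All depthwise and pointwise convolutions are bias-free:
a separable conv then costs ``Cin*k + Cin*Cout`` weights against
``Cin*Cout*k`` for a standard conv, and the bias-free total of ~30.5 K
trainable scalars serializes to ~59.6 KB in FP16.

A DS-SE block is a depthwise separable temporal convolution with "same"
padding, batch norm, SiLU, then squeeze-and-excitation rescaling applied to
the post-activation features.  A lightweight temporal block (LTB) is two
causal depthwise-separable convolutions (left padding ``(k-1)*d``), each
followed by batch norm, SiLU and dropout, with a residual connection
(identity when channel counts match) and a final SiLU; stacking two LTBs
with dilations 1 and 2 gives a causal receptive field of
``1 + 2*(k-1)*(2^L - 1) = 13`` post-pool steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm1d,
    DepthwiseConv1d,
    Dropout,
    GlobalAvgPool1d,
    GroupNorm,
    Linear,
    MaxPool1d,
    Module,
    PointwiseConv1d,
    RngBox,
    SEBlock,
    Sequential,
    SiLU,
    softmax,
)

__all__ = [
    "ModelSpec",
    "DSSEBlock",
    "LightweightTemporalBlock",
    "SpatioTemporalBranch",
    "FallNet",
    "build_ds_se",
    "build_ltb",
    "build_stfe",
    "build_network",
    "build_reduced_network",
    "count_parameters",
    "STREAM_SUBSETS",
]

# stream indices into the (body accel, body gyro, global accel, global gyro)
# window tensor for each ablation configuration
STREAM_SUBSETS = {"all": (0, 1, 2, 3), "body": (0, 1), "global": (2, 3)}


@dataclass(frozen=True)
class ModelSpec:
    """Architectural hyperparameters of the four-branch classifier."""

    in_channels: int = 3
    t_steps: int = 87
    dsse1_out: int = 16
    dsse1_kernel: int = 9
    dsse2_out: int = 32
    dsse2_kernel: int = 7
    se_reduction: int = 6
    se_bias: bool = True
    tcn_channels: int = 32
    tcn_kernel: int = 3
    tcn_layers: int = 2
    tcn_dropout: float = 0.08
    group_norm_groups: int = 4
    branch_feature_dim: int = 32
    fc_hidden: int = 48
    fc_dropout: float = 0.30
    n_classes: int = 2

    @property
    def fused_dim(self) -> int:
        return 4 * self.branch_feature_dim

    @property
    def receptive_field(self) -> int:
        return 1 + 2 * (self.tcn_kernel - 1) * (2**self.tcn_layers - 1)


class DSSEBlock(Module):
    """Depthwise-separable conv ("same" padding) + BN + SiLU + SE rescaling."""

    def __init__(self, c_in: int, c_out: int, kernel: int, reduction: int,
                 se_bias: bool = True, rng=None):
        super().__init__()
        if min(c_in, c_out, kernel) < 1:
            raise ValueError("channel counts and kernel size must be >= 1")
        if kernel % 2 == 0:
            raise ValueError("same-padded DS-SE requires an odd kernel")
        pad = (kernel - 1) // 2
        self.depthwise = DepthwiseConv1d(c_in, kernel, padding=(pad, pad), rng=rng)
        self.pointwise = PointwiseConv1d(c_in, c_out, rng=rng)
        self.bn = BatchNorm1d(c_out)
        self.act = SiLU()
        self.se = SEBlock(c_out, reduction, bias=se_bias, rng=rng)
        self.body = Sequential(self.depthwise, self.pointwise, self.bn, self.act, self.se)

    @property
    def conv_weight_count(self) -> int:
        return self.depthwise.weight.size + self.pointwise.weight.size

    def forward(self, x):
        return self.body(x)

    def backward(self, grad):
        return self.body.backward(grad)


class _CausalDSConv(Sequential):
    def __init__(self, channels: int, kernel: int, dilation: int, rng=None):
        pad = (kernel - 1) * dilation
        super().__init__(
            DepthwiseConv1d(channels, kernel, dilation=dilation, padding=(pad, 0), rng=rng),
            PointwiseConv1d(channels, channels, rng=rng),
        )


class LightweightTemporalBlock(Module):
    """Residual block of two causal depthwise-separable convolutions."""

    def __init__(self, channels: int, kernel: int, dilation: int, dropout: float,
                 rng_box: RngBox, rng=None, in_channels: int | None = None):
        super().__init__()
        c_in = in_channels if in_channels is not None else channels
        first = _CausalDSConv(channels, kernel, dilation, rng=rng)
        if c_in != channels:
            first.layers[0] = DepthwiseConv1d(c_in, kernel, dilation=dilation,
                                              padding=((kernel - 1) * dilation, 0), rng=rng)
            first.layers[1] = PointwiseConv1d(c_in, channels, rng=rng)
        self.path = Sequential(
            first, BatchNorm1d(channels), SiLU(), Dropout(dropout, rng_box),
            _CausalDSConv(channels, kernel, dilation, rng=rng),
            BatchNorm1d(channels), SiLU(), Dropout(dropout, rng_box),
        )
        self.residual = PointwiseConv1d(c_in, channels, rng=rng) if c_in != channels else None
        self.out_act = SiLU()

    def forward(self, x):
        h = self.path(x) + (self.residual(x) if self.residual is not None else x)
        return self.out_act(h)

    def backward(self, grad):
        g = self.out_act.backward(grad)
        dx = self.path.backward(g)
        dres = self.residual.backward(g) if self.residual is not None else g
        return dx + dres


class SpatioTemporalBranch(Module):
    """One STFE: DS-SE1 -> pool -> DS-SE2 -> DS-TCN -> GN -> GAP -> 32-dim."""

    def __init__(self, spec: ModelSpec, rng_box: RngBox, rng=None):
        super().__init__()
        self.dsse1 = DSSEBlock(spec.in_channels, spec.dsse1_out, spec.dsse1_kernel,
                               spec.se_reduction, spec.se_bias, rng=rng)
        self.pool = MaxPool1d(2, 2)
        self.dsse2 = DSSEBlock(spec.dsse1_out, spec.dsse2_out, spec.dsse2_kernel,
                               spec.se_reduction, spec.se_bias, rng=rng)
        self.tcn = Sequential(*[
            LightweightTemporalBlock(
                spec.tcn_channels, spec.tcn_kernel, 2**i, spec.tcn_dropout,
                rng_box, rng=rng,
                in_channels=spec.dsse2_out if i == 0 else spec.tcn_channels,
            )
            for i in range(spec.tcn_layers)
        ])
        self.gn = GroupNorm(spec.tcn_channels, spec.group_norm_groups)
        self.gap = GlobalAvgPool1d()
        self.body = Sequential(self.dsse1, self.pool, self.dsse2, self.tcn, self.gn, self.gap)

    def forward(self, x):
        return self.body(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def shape_trace(self, x) -> list[tuple[int, ...]]:
        """Shapes after each stage, for a single-window input (B, 3, T)."""
        shapes = []
        for stage in (self.dsse1, self.pool, self.dsse2, self.tcn, self.gn, self.gap):
            x = stage(x)
            shapes.append(x.shape)
        return shapes


class FallNet(Module):
    """The full late-fusion network over a subset of the four streams.

    Branches are structurally identical with independent parameters; the
    classifier input width is ``n_branches * branch_feature_dim``.  Forward
    input is ``(B, n_branches, 3, T)``; output is ``(B, 2)`` logits.
    """

    def __init__(self, spec: ModelSpec | None = None, streams: str = "all",
                 seed: int = 0):
        super().__init__()
        if streams not in STREAM_SUBSETS:
            raise ValueError(f"streams must be one of {sorted(STREAM_SUBSETS)}")
        self.spec = spec or ModelSpec()
        self.streams = streams
        self.stream_indices = STREAM_SUBSETS[streams]
        self.rng_box = RngBox(seed)
        init_rng = np.random.default_rng(seed)
        n_br = len(self.stream_indices)
        self.branches = [SpatioTemporalBranch(self.spec, self.rng_box, rng=init_rng)
                         for _ in range(n_br)]
        fused = n_br * self.spec.branch_feature_dim
        self.fc1 = Linear(fused, self.spec.fc_hidden, bias=True, rng=init_rng)
        self.head = Sequential(
            self.fc1, BatchNorm1d(self.spec.fc_hidden), SiLU(),
            Dropout(self.spec.fc_dropout, self.rng_box),
            Linear(self.spec.fc_hidden, self.spec.n_classes, bias=True, rng=init_rng),
        )
        self._split = None

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def seed_rng(self, seed: int) -> None:
        self.rng_box.seed(seed)

    @property
    def param_dtype(self):
        return self.fc1.weight.data.dtype

    def forward(self, x):
        x = np.asarray(x, dtype=self.param_dtype)
        if x.ndim != 4 or x.shape[1] != self.n_branches:
            raise ValueError(
                f"expected (B, {self.n_branches}, C, T) input, got {x.shape}")
        feats = [br(x[:, i]) for i, br in enumerate(self.branches)]
        self._split = [f.shape[1] for f in feats]
        return self.head(np.concatenate(feats, axis=1))

    def backward(self, grad):
        gf = self.head.backward(grad)
        offs = np.cumsum([0] + self._split)
        douts = []
        for i, br in enumerate(self.branches):
            douts.append(br.backward(gf[:, offs[i]:offs[i + 1]]))
        return np.stack(douts, axis=1)

    def predict_proba(self, x) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            return softmax(self.forward(x))
        finally:
            self.train(was_training)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("parameter count mismatch")
        for i, p in enumerate(params):
            p.data[...] = state[f"p{i}"]

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def export_fp16(self, path) -> float:
        """Flat FP16 export of all trainable parameters; returns size in KB."""
        flat = np.concatenate([p.data.ravel() for p in self.parameters()])
        flat.astype(np.float16).tofile(path)
        return 2.0 * flat.size / 1024.0


def build_ds_se(c_in: int, c_out: int, kernel: int, reduction: int,
                se_bias: bool = True, seed: int = 0) -> DSSEBlock:
    return DSSEBlock(c_in, c_out, kernel, reduction, se_bias,
                     rng=np.random.default_rng(seed))


def build_ltb(channels: int, kernel: int, dilation: int, dropout: float = 0.08,
              seed: int = 0, in_channels: int | None = None) -> LightweightTemporalBlock:
    return LightweightTemporalBlock(channels, kernel, dilation, dropout,
                                    RngBox(seed), rng=np.random.default_rng(seed),
                                    in_channels=in_channels)


def build_stfe(spec: ModelSpec | None = None, seed: int = 0) -> SpatioTemporalBranch:
    spec = spec or ModelSpec()
    return SpatioTemporalBranch(spec, RngBox(seed), rng=np.random.default_rng(seed))


def build_network(spec: ModelSpec | None = None, seed: int = 0) -> FallNet:
    return FallNet(spec, streams="all", seed=seed)


def build_reduced_network(streams: str, spec: ModelSpec | None = None,
                          seed: int = 0) -> FallNet:
    """Two-branch ablation variant consuming only the body-frame or only the
    global-frame streams (fused dim 64); ``streams='all'`` returns the full
    network."""
    return FallNet(spec, streams=streams, seed=seed)


def count_parameters(model: Module) -> tuple[int, float]:
    """(number of trainable scalars, FP16 size in KB at 2 bytes each)."""
    n = model.n_parameters()
    return n, 2.0 * n / 1024.0
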