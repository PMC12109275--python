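"""The three classifier networks.

* **Model 1 — CNN branch**: four Convolution–Normalization–ReLU–Pooling
  stages on the 78x116x3 preprocessed fundus tensor, closed by one
  valid convolution with a 3x5 kernel that collapses the last feature
  map to a single position, yielding a 32-value feature vector.  The
  stage geometry is chosen so the feature-map trace is exactly

      C1 32@78x116, P1 32@39x58, C2 32@18x28, P2 32@16x26,
      C3 32@8x13,  P3 32@6x11,  C4 32@6x11,  P4 32@3x5

  and construction fails loudly, naming the first offending stage, if a
  configuration breaks this trace.
* **Model 2 — ANN branch**: a fully connected ReLU stack (default 4
  layers of 16 nodes) on the two thickness features (WA_MT, WA_RNFL).
* **Model 3 — concatenated model**: the CNN feature vector and the
  ANN's final hidden layer are concatenated (width 32 + 16 by default)
  and passed through a dense head (default 2 layers of 16 nodes) ending
  in a single sigmoid unit that emits p_hat.

Each branch is also available standalone (with its own sigmoid head)
for branch-vs-fusion comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2D,
    Conv2D,
    Dense,
    Flatten,
    FusionNetwork,
    MaxPool2D,
    ReLU,
    Sequential,
    Sigmoid,
)


class ConstructionError(ValueError):
    """A model spec produces an architecture inconsistent with itself."""


@dataclass(frozen=True)
class StageParams:
    """Geometry of one C-N-R-P stage."""

    conv_kernel: tuple[int, int]
    conv_stride: tuple[int, int] = (1, 1)
    conv_padding: tuple[int, int] = (0, 0)
    pool_kernel: tuple[int, int] = (2, 2)
    pool_stride: tuple[int, int] = (2, 2)


#: Stage geometry reproducing the printed feature-map trace.
DEFAULT_STAGES: tuple[StageParams, ...] = (
    StageParams(conv_kernel=(3, 3), conv_stride=(1, 1), conv_padding=(1, 1),
                pool_kernel=(2, 2), pool_stride=(2, 2)),
    StageParams(conv_kernel=(5, 4), conv_stride=(2, 2), conv_padding=(0, 0),
                pool_kernel=(3, 3), pool_stride=(1, 1)),
    StageParams(conv_kernel=(2, 2), conv_stride=(2, 2), conv_padding=(0, 0),
                pool_kernel=(3, 3), pool_stride=(1, 1)),
    StageParams(conv_kernel=(3, 3), conv_stride=(1, 1), conv_padding=(1, 1),
                pool_kernel=(2, 2), pool_stride=(2, 2)),
)

#: The reference trace of (stage label, rows, cols) for a 78x116 input.
PRINTED_TRACE: tuple[tuple[str, int, int], ...] = (
    ("C1", 78, 116), ("P1", 39, 58),
    ("C2", 18, 28), ("P2", 16, 26),
    ("C3", 8, 13), ("P3", 6, 11),
    ("C4", 6, 11), ("P4", 3, 5),
)


@dataclass(frozen=True)
class CnnSpec:
    """CNN branch configuration (Model 1)."""

    input_shape: tuple[int, int, int] = (78, 116, 3)  # rows, cols, channels
    n_kernels: int = 32
    stages: tuple[StageParams, ...] = DEFAULT_STAGES
    final_kernel: tuple[int, int] = (3, 5)

    def __post_init__(self) -> None:
        if self.n_kernels <= 0:
            raise ValueError(f"n_kernels must be > 0, got {self.n_kernels}")
        if any(d <= 0 for d in self.input_shape):
            raise ValueError(f"invalid input shape {self.input_shape}")


@dataclass(frozen=True)
class AnnSpec:
    """ANN branch configuration (Model 2)."""

    n_layers: int = 4
    n_nodes: int = 16
    n_inputs: int = 2

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_nodes < 1 or self.n_inputs < 1:
            raise ValueError("AnnSpec counts must be >= 1")


@dataclass(frozen=True)
class ConcatSpec:
    """Concatenation head configuration (Model 3)."""

    n_layers: int = 2
    n_nodes: int = 16

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_nodes < 1:
            raise ValueError("ConcatSpec counts must be >= 1")


@dataclass(frozen=True)
class ShapeTrace:
    """Ordered (stage label, channels, rows, cols) feature-map sizes."""

    stages: tuple[tuple[str, int, int, int], ...] = field(default_factory=tuple)

    def spatial(self) -> tuple[tuple[str, int, int], ...]:
        return tuple((label, r, c) for label, _, r, c in self.stages)


def cnn_shape_trace(spec: CnnSpec) -> ShapeTrace:
    """Symbolic feature-map trace induced by a CNN spec."""
    h, w = spec.input_shape[0], spec.input_shape[1]
    out = []
    for i, st in enumerate(spec.stages, start=1):
        h = (h + 2 * st.conv_padding[0] - st.conv_kernel[0]) // st.conv_stride[0] + 1
        w = (w + 2 * st.conv_padding[1] - st.conv_kernel[1]) // st.conv_stride[1] + 1
        out.append((f"C{i}", spec.n_kernels, h, w))
        h = (h - st.pool_kernel[0]) // st.pool_stride[0] + 1
        w = (w - st.pool_kernel[1]) // st.pool_stride[1] + 1
        out.append((f"P{i}", spec.n_kernels, h, w))
        if h <= 0 or w <= 0:
            raise ConstructionError(f"stage {i} collapses the feature map to {h}x{w}")
    return ShapeTrace(stages=tuple(out))


def _validate_trace(spec: CnnSpec) -> ShapeTrace:
    trace = cnn_shape_trace(spec)
    if spec.input_shape[:2] == (78, 116):
        for (label, _, r, c), (ref_label, ref_r, ref_c) in zip(trace.stages, PRINTED_TRACE):
            if (r, c) != (ref_r, ref_c):
                raise ConstructionError(
                    f"stage {label} yields {r}x{c}, expected {ref_r}x{ref_c} "
                    f"(reference stage {ref_label})"
                )
    last_r, last_c = trace.stages[-1][2], trace.stages[-1][3]
    if (last_r, last_c) != spec.final_kernel:
        raise ConstructionError(
            f"final convolution kernel {spec.final_kernel} does not cover the "
            f"last feature map {last_r}x{last_c}"
        )
    return trace


def build_cnn_branch(spec: CnnSpec = CnnSpec(), rng: np.random.Generator | None = None) -> Sequential:
    """Build Model 1; output is a flat vector of ``n_kernels`` values."""
    _validate_trace(spec)
    rng = rng or np.random.default_rng()
    layers = []
    in_ch = spec.input_shape[2]
    for st in spec.stages:
        layers.append(
            Conv2D(in_ch, spec.n_kernels, st.conv_kernel, st.conv_stride, st.conv_padding, rng=rng)
        )
        layers.append(BatchNorm2D(spec.n_kernels))
        layers.append(ReLU())
        layers.append(MaxPool2D(st.pool_kernel, st.pool_stride))
        in_ch = spec.n_kernels
    layers.append(Conv2D(spec.n_kernels, spec.n_kernels, spec.final_kernel, rng=rng))
    layers.append(Flatten())
    return Sequential(layers)


def build_ann_branch(spec: AnnSpec = AnnSpec(), rng: np.random.Generator | None = None) -> Sequential:
    """Build Model 2; output is the final hidden layer (width n_nodes)."""
    rng = rng or np.random.default_rng()
    layers: list = []
    width_in = spec.n_inputs
    for _ in range(spec.n_layers):
        layers.append(Dense(width_in, spec.n_nodes, rng=rng))
        layers.append(ReLU())
        width_in = spec.n_nodes
    return Sequential(layers)


def _build_head(n_in: int, spec: ConcatSpec, rng: np.random.Generator) -> Sequential:
    layers: list = []
    width_in = n_in
    for _ in range(spec.n_layers):
        layers.append(Dense(width_in, spec.n_nodes, rng=rng))
        layers.append(ReLU())
        width_in = spec.n_nodes
    layers.append(Dense(width_in, 1, rng=rng))
    layers.append(Sigmoid())
    return Sequential(layers)


def build_concat_model(
    cnn: CnnSpec | None = CnnSpec(),
    ann: AnnSpec | None = AnnSpec(),
    head: ConcatSpec = ConcatSpec(),
    rng: np.random.Generator | int | None = None,
) -> FusionNetwork:
    """Build the fused classifier (or a standalone branch).

    Pass ``cnn=None`` for the thickness-only model or ``ann=None`` for
    the image-only model; with both, the head consumes the concatenated
    width ``n_kernels + ann.n_nodes``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cnn_net = build_cnn_branch(cnn, rng) if cnn is not None else None
    ann_net = build_ann_branch(ann, rng) if ann is not None else None
    width = (cnn.n_kernels if cnn is not None else 0) + (ann.n_nodes if ann is not None else 0)
    if width == 0:
        raise ConstructionError("at least one branch is required")
    return FusionNetwork(cnn_net, ann_net, _build_head(width, head, rng))
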