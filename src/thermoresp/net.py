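"""The two-pathway residual 3-D convolutional respiratory-rate regressor.

The architecture follows the two-stream ("slow/fast") video-recognition
family: the same input window is read at two temporal strides and processed
by two ResNet-style 3-D convolutional branches that exchange information
through time-strided lateral fusion convolutions, with a single linear
output unit regressing breaths per minute.

Two aspects are specific to thermal breathing data and are configurable:

* **Enlarged spatial receptive fields.**  Thermal images are blurry — heat
  diffuses, so informative structure is spread over larger neighbourhoods
  than in visible light.  The stem and residual spatial kernels are
  therefore widened; three canonical configurations pair stem/residual
  kernels (5, 3), (7, 5) and (9, 7), whose analytic effective receptive
  fields are 37, 71 and 105 pixels.
* **A deep fusion kernel.**  The lateral fusion convolution's temporal
  extent (5 to 15) controls how much breathing-cycle context crosses
  between pathways at each fusion point.

Terminology: the *dense* branch reads every ``alpha``-th frame of the
window (32 frames for a 128-frame window at ``alpha=4``) and is narrow;
the *sparse* branch reads every ``beta``-th frame (8 frames at ``beta=16``)
and is 8x wider.  Lateral fusion runs dense -> sparse with temporal stride
``beta / alpha``.

The module also houses the analytic layer-count and effective-receptive-
field (ERF) calculators used to compare configurations: for a residual
network with ``D`` blocks of ``q`` parallel convolutions each, of which
``d`` are skipped, the layer count is ``L = (D - d) * q``, and for a stack
of layers with kernel sizes ``k_l`` and strides ``s_l``

    ERF = sum_l (k_l - 1) * prod_{i<l} s_i + 1.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from ._tensor import Tensor, concat
from .windows import ClipPair

__all__ = [
    "NetConfig",
    "LayerLedger",
    "layer_count",
    "effective_receptive_field",
    "spatial_ledger",
    "build_model",
    "predict_rr",
    "TwoPathwayRegressor",
    "save_model",
    "load_model",
]

#: Bottleneck block counts per residual stage.
_BLOCKS = {"resnet50": (3, 4, 6, 3), "resnet101": (3, 4, 23, 3)}

#: (stem_spatial_k, residual_spatial_k) for the three canonical configurations.
CONFIGURATIONS = {1: (5, 3), 2: (7, 5), 3: (9, 7)}


@dataclass(frozen=True)
class NetConfig:
    """All architecture knobs.

    Defaults are the best-performing configuration of the hyperparameter
    sweep: ResNet50 backbone, stem/residual spatial kernels 7/5
    (configuration 2), fusion kernel 15, ``alpha=4``, ``beta=16``, 128-frame
    window, dropout 0.2.  ``channel_ratio`` is the dense-branch width as a
    fraction of the sparse-branch width (1/8, mirroring the 8-vs-64 stem
    filter counts); ``width_multiplier`` scales every channel count for
    desk-scale runs.
    """

    backbone: str = "resnet50"
    stem_spatial_k: int = 7
    residual_spatial_k: int = 5
    fusion_kernel_t: int = 15
    alpha: int = 4
    beta: int = 16
    window_len: int = 128
    dropout: float = 0.2
    channel_ratio: float = 0.125
    width_multiplier: float = 1.0
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.backbone not in _BLOCKS:
            raise ValueError(f"backbone must be one of {sorted(_BLOCKS)}, got {self.backbone!r}")
        for name in ("stem_spatial_k", "residual_spatial_k", "fusion_kernel_t"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {k}")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must be in [0, 1], got {self.dropout}")
        if self.width_multiplier <= 0:
            raise ValueError(f"width_multiplier must be > 0, got {self.width_multiplier}")
        if self.alpha > self.beta:
            raise ValueError(f"alpha ({self.alpha}) must be <= beta ({self.beta})")
        for name in ("alpha", "beta"):
            s = getattr(self, name)
            if s < 1 or self.window_len % s != 0:
                raise ValueError(f"{name}={s} must divide window_len={self.window_len}")

    @property
    def t_dense(self) -> int:
        return self.window_len // self.alpha

    @property
    def t_sparse(self) -> int:
        return self.window_len // self.beta


@dataclass
class LayerLedger:
    """Ordered (kernel, stride) entries of one pathway's spatial conv stack,
    together with the residual-block bookkeeping (D blocks, d skipped,
    q pathways per block) used by the analytic layer count."""

    entries: list[tuple[int, int]] = field(default_factory=list)
    D: int = 0
    d: int = 0
    q: int = 2

    def __post_init__(self) -> None:
        for k, s in self.entries:
            if k < 1 or s < 1:
                raise ValueError(f"kernel and stride must be >= 1, got ({k}, {s})")
        if not 0 <= self.d <= self.D:
            raise ValueError(f"need 0 <= d <= D, got d={self.d}, D={self.D}")
        if self.q < 1:
            raise ValueError(f"q must be >= 1, got {self.q}")


def layer_count(D: int, d: int, q: int) -> int:
    """Approximate layer count of a residual CNN: ``L = (D - d) * q``.

    ``D`` residual blocks, ``d`` of them bypassed through their skip
    connections, ``q`` parallel convolution pathways per block.
    """
    if not 0 <= d <= D:
        raise ValueError(f"need 0 <= d <= D, got d={d}, D={D}")
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    return (D - d) * q


def effective_receptive_field(ledger: LayerLedger) -> int:
    """Analytic ERF of a layer stack: ``sum_l (k_l - 1) * prod_{i<l} s_i + 1``."""
    if not ledger.entries:
        raise ValueError("layer ledger is empty")
    erf = 1
    jump = 1
    for k, s in ledger.entries:
        erf += (k - 1) * jump
        jump *= s
    return erf


def spatial_ledger(config: NetConfig) -> LayerLedger:
    """Spatial-kernel ledger of one pathway for the analytic ERF.

    One stem entry plus one residual spatial conv per bottleneck block
    (16 for ResNet50, 33 for ResNet101), all at unit stride: the ERF is an
    analysis artifact restricted to spatial resolution, and only under unit
    strides do the three canonical configurations give 37 / 71 / 105.
    The network itself retains its downsampling strides.
    """
    n_blocks = sum(_BLOCKS[config.backbone])
    entries = [(config.stem_spatial_k, 1)]
    entries += [(config.residual_spatial_k, 1)] * n_blocks
    return LayerLedger(entries=entries, D=n_blocks, d=0, q=2)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

class _Bottleneck(nn.Module):
    """1x1x1 -> 1xkxk -> 1x1x1 bottleneck with pre-activation-free residual.

    ``temporal_k`` is the temporal extent of the first 1x1 conv (3 on the
    dense branch everywhere and on the sparse branch's late stages, else 1).
    """

    def __init__(self, c_in, c_mid, c_out, spatial_k, temporal_k, spatial_stride, rng):
        super().__init__()
        self.conv1 = nn.Conv3d(c_in, c_mid, (temporal_k, 1, 1), rng=rng)
        self.bn1 = nn.BatchNorm3d(c_mid)
        self.conv2 = nn.Conv3d(
            c_mid, c_mid, (1, spatial_k, spatial_k),
            stride=(1, spatial_stride, spatial_stride), rng=rng,
        )
        self.bn2 = nn.BatchNorm3d(c_mid)
        self.conv3 = nn.Conv3d(c_mid, c_out, (1, 1, 1), rng=rng)
        self.bn3 = nn.BatchNorm3d(c_out)
        if c_in != c_out or spatial_stride != 1:
            self.proj = nn.Conv3d(
                c_in, c_out, (1, 1, 1), stride=(1, spatial_stride, spatial_stride), rng=rng
            )
            self.proj_bn = nn.BatchNorm3d(c_out)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return (y + shortcut).relu()


class _Fusion(nn.Module):
    """Dense->sparse lateral connection: time-strided conv matching the
    sparse branch's temporal length, output concatenated channel-wise."""

    def __init__(self, c_dense, t_ratio, kernel_t, rng):
        super().__init__()
        self.conv = nn.Conv3d(
            c_dense, 2 * c_dense, (kernel_t, 1, 1),
            stride=(t_ratio, 1, 1), pad=((kernel_t - 1) // 2, 0, 0), rng=rng,
        )
        self.bn = nn.BatchNorm3d(2 * c_dense)
        self.out_channels = 2 * c_dense

    def forward(self, dense: Tensor, sparse: Tensor) -> Tensor:
        fused = self.bn(self.conv(dense)).relu()
        if fused.shape[2] != sparse.shape[2]:
            raise ValueError(
                f"fusion produced temporal length {fused.shape[2]}, "
                f"sparse branch has {sparse.shape[2]}"
            )
        return concat([sparse, fused], axis=1)


def _width(base: float) -> int:
    return max(1, int(round(base)))


class TwoPathwayRegressor(nn.Module):
    """Two-branch residual 3-D CNN with lateral fusion and a linear RR head.

    The dense branch consumes ``(C, Ws/alpha, H, W)``, the sparse branch
    ``(C, Ws/beta, H, W)``.  Stems: temporal kernel 5 on the dense branch,
    1 on the sparse branch, both with the configured spatial kernel and
    spatial stride 2.  Fusion runs after the stem and after every residual
    stage.  The head global-average-pools both branches, concatenates,
    applies dropout, and regresses a single unbounded scalar (bpm).
    """

    def __init__(self, config: NetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        wm = config.width_multiplier
        ratio = config.channel_ratio
        t_ratio = config.beta // config.alpha
        if config.beta % config.alpha != 0:
            raise ValueError("beta must be an integer multiple of alpha for fusion")
        sk = config.stem_spatial_k
        rk = config.residual_spatial_k
        blocks = _BLOCKS[config.backbone]

        # Temporal lengths are preserved by every stage (temporal stride 1);
        # reject configurations whose dense branch is shorter than the
        # fusion kernel's stride coverage.
        t_dense = config.t_dense
        pad_t = (config.fusion_kernel_t - 1) // 2
        if t_dense + 2 * pad_t < config.fusion_kernel_t:
            raise ValueError(
                f"stem fusion: dense temporal length {t_dense} too short for "
                f"fusion kernel {config.fusion_kernel_t}"
            )
        if t_dense % t_ratio != 0:
            raise ValueError(
                f"dense temporal length {t_dense} not divisible by beta/alpha={t_ratio}"
            )

        sparse_base = _width(64 * wm)
        dense_base = _width(64 * wm * ratio)
        self.stem_dense = nn.Sequential(
            nn.Conv3d(config.in_channels, dense_base, (5, sk, sk),
                      stride=(1, 2, 2), rng=rng),
            nn.BatchNorm3d(dense_base), nn.ReLU(),
        )
        self.stem_sparse = nn.Sequential(
            nn.Conv3d(config.in_channels, sparse_base, (1, sk, sk),
                      stride=(1, 2, 2), rng=rng),
            nn.BatchNorm3d(sparse_base), nn.ReLU(),
        )

        fusions = [_Fusion(dense_base, t_ratio, config.fusion_kernel_t, rng)]

        dense_stages, sparse_stages = [], []
        c_dense = dense_base
        c_sparse = sparse_base + fusions[0].out_channels
        for stage, n_blocks in enumerate(blocks):
            mid_s = _width(64 * (2**stage) * wm)
            mid_d = _width(64 * (2**stage) * wm * ratio)
            out_s, out_d = 4 * mid_s, 4 * mid_d
            stride = 1 if stage == 0 else 2
            # dense branch: temporal kernel 3 throughout;
            # sparse branch: 1 in early stages, 3 in the last two.
            tk_sparse = 1 if stage < 2 else 3
            dblocks, sblocks = [], []
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                dblocks.append(_Bottleneck(c_dense, mid_d, out_d, rk, 3, s, rng))
                sblocks.append(_Bottleneck(c_sparse, mid_s, out_s, rk, tk_sparse, s, rng))
                c_dense, c_sparse = out_d, out_s
            dense_stages.append(nn.Sequential(*dblocks))
            sparse_stages.append(nn.Sequential(*sblocks))
            fusions.append(_Fusion(out_d, t_ratio, config.fusion_kernel_t, rng))
            c_sparse = out_s + fusions[-1].out_channels

        self.dense_stages = nn.ModuleList(dense_stages)
        self.sparse_stages = nn.ModuleList(sparse_stages)
        self.fusions = nn.ModuleList(fusions)
        self.dropout = nn.Dropout(config.dropout, rng=np.random.default_rng(seed + 1))
        head_in = c_dense + c_sparse
        self.head = nn.Linear(head_in, 1, rng=rng)
        # Zero-initialised head: early training predicts the bias alone,
        # set to a mid-range resting rate via `init_head_bias`.
        self.head.weight.data[:] = 0.0

    def init_head_bias(self, value: float) -> None:
        self.head.bias.data[:] = np.float32(value)

    def forward(self, dense: Tensor, sparse: Tensor) -> Tensor:
        """Map a batch of clip pairs (N, C, T, H, W) x2 to (N,) predictions."""
        d = self.stem_dense(dense)
        s = self.stem_sparse(sparse)
        s = self.fusions[0](d, s)
        for i in range(len(self.dense_stages)):
            d = self.dense_stages[i](d)
            s = self.sparse_stages[i](s)
            s = self.fusions[i + 1](d, s)
        d_pool = d.mean(axis=(2, 3, 4))
        s_pool = s.mean(axis=(2, 3, 4))
        feats = self.dropout(concat([d_pool, s_pool], axis=1))
        return self.head(feats).reshape(-1)


def build_model(config: NetConfig, seed: int = 0) -> TwoPathwayRegressor:
    """Construct the two-pathway regressor for a configuration."""
    return TwoPathwayRegressor(config, seed=seed)


def _stack_clips(clips: list[ClipPair]) -> tuple[np.ndarray, np.ndarray]:
    dense = np.stack([c.dense_view for c in clips]).astype(np.float32)
    sparse = np.stack([c.sparse_view for c in clips]).astype(np.float32)
    return dense, sparse


def predict_rr(
    model: TwoPathwayRegressor, clips: list[ClipPair], batch_size: int = 16
) -> np.ndarray:
    """Inference-mode RR predictions (bpm), one scalar per clip.

    Deterministic: dropout is disabled and batch-norm uses running
    statistics, so predictions are independent of batch composition.
    """
    if not clips:
        raise ValueError("predict_rr: empty clip list")
    exp = model.config.in_channels
    if clips[0].dense_view.shape[0] != exp:
        raise ValueError(
            f"geometry mismatch: model expects {exp} channels, "
            f"clips have {clips[0].dense_view.shape[0]}"
        )
    was_training = model.training
    model.eval()
    preds = []
    for i in range(0, len(clips), batch_size):
        dense, sparse = _stack_clips(clips[i : i + batch_size])
        out = model(Tensor(dense), Tensor(sparse))
        preds.append(out.data.astype(float))
    model.train(was_training)
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# Checkpointing: single-file zip archive with embedded config JSON
# ---------------------------------------------------------------------------

def save_model(model: TwoPathwayRegressor, path: str | Path) -> None:
    path = Path(path)
    state = model.state_arrays()
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(model.config)))
        zf.writestr("state.npz", buf.getvalue())


def load_model(path: str | Path) -> TwoPathwayRegressor:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        config = NetConfig(**json.loads(zf.read("config.json")))
        state = dict(np.load(io.BytesIO(zf.read("state.npz"))))
    model = build_model(config)
    model.load_state_arrays(state)
    return model
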