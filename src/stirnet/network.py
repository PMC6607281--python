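"""The learned restorer: KR-blocks, SRDN branches, and the conjoint merge.

Architecture
------------
The building unit is the **kernel-regulation block** (KR-block), a serial
mix of kernel sizes with an identity skip:

    in -> 1x1 (reduce) -> 7x7 (width) -> 3x3 (width) ->
          [7x7 features + 3x3 features, pixel-wise sum] -> 1x1 (width) -> + in

The large 7x7 kernel removes noise over a wide receptive field; the 3x3
behind it regulates those features, preserving subtle texture; summation
blends the two; the 1x1 layers bottleneck computation and add
non-linearity (PReLU after every convolution except the final
reconstruction layer).

An **SRDN** (super-resolution denoising network) stacks, fully
convolutionally: two 7x7 feature-extraction layers (128 filters), a 1x1
"shrinking" layer, a chain of KR-blocks (4 by default, each carrying its
identity skip so block outputs flow residually into the next), a 1x1
"expanding" layer, a 3x3 reconstruction layer and a final 3x3 single-channel
layer, plus a global shortcut from the network input to its output (the
network learns a residual correction).  The final layer is the stride-1
form of a transposed convolution — no upscaling happens inside the network,
inputs and outputs share their shape for any H, W.

Three SRDNs — one per cross-section (XY, XT, YT) — are trained
independently on their own patch streams; at inference the three restored
volumes are blended by the **conjoint layer**, a voxel-wise mean.

Implementation
--------------
Layers are implemented directly on numpy (im2col + GEMM convolutions with
hand-written backward passes), trained with Adam on a mean-squared-error
loss.  All computation is float32 and deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .patches import CROSS_SECTIONS, HU_WINDOW, PatchPair, extract_cross_sections, \
    normalize, denormalize, stack_to_volume
from .volume import CTPVolume

__all__ = [
    "LayerSpec",
    "KRBlockSpec",
    "SRDNSpec",
    "STIRSpec",
    "TrainConfig",
    "KRBlock",
    "SRDN",
    "STIRModel",
    "kr_block_forward",
    "srdn_forward",
    "conjoint_merge",
    "train_srdn",
    "restore_volume",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Declarative specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One convolution: kernel size f, filter count n, input channels c."""

    f: int
    n: int
    c: int
    activation: str = "prelu"  # or "none"

    def __post_init__(self) -> None:
        if self.f not in (1, 3, 7):
            raise InvalidInputError(f"kernel size must be 1, 3 or 7, got {self.f}")
        if self.n < 1 or self.c < 1:
            raise InvalidInputError("filter and channel counts must be >= 1")
        if self.activation not in ("prelu", "none"):
            raise InvalidInputError(f"unknown activation {self.activation!r}")

    @property
    def param_count(self) -> int:
        return self.f * self.f * self.c * self.n + self.n


@dataclass(frozen=True)
class KRBlockSpec:
    """Trunk width and 1x1 bottleneck width of a KR-block."""

    width: int = 128
    reduce: int = 64

    def __post_init__(self) -> None:
        if not (1 <= self.reduce <= self.width):
            raise InvalidInputError("require 1 <= reduce <= width")

    def layer_plan(self) -> tuple[LayerSpec, ...]:
        w, r = self.width, self.reduce
        return (
            LayerSpec(1, r, w),           # reduce
            LayerSpec(7, w, r),           # large-kernel extraction
            LayerSpec(3, w, w),           # small-kernel regulation
            LayerSpec(1, w, w),           # blend projection
        )

    @property
    def conv_param_count(self) -> int:
        return sum(l.param_count for l in self.layer_plan())


@dataclass(frozen=True)
class SRDNSpec:
    """Declarative description of one branch network."""

    n_features: int = 128
    kr_blocks: int = 4
    kr: KRBlockSpec = field(default_factory=KRBlockSpec)
    input_shortcut: bool = True

    def __post_init__(self) -> None:
        if self.kr_blocks < 1:
            raise InvalidInputError("need at least one KR-block")
        if self.n_features < 1:
            raise InvalidInputError("n_features must be >= 1")

    @classmethod
    def desk(cls) -> "SRDNSpec":
        """CPU-friendly preset: width 16, reduce 8, a single KR-block."""
        return cls(n_features=16, kr_blocks=1, kr=KRBlockSpec(width=16, reduce=8))

    def layer_plan(self) -> tuple[LayerSpec, ...]:
        nf, w = self.n_features, self.kr.width
        plan: list[LayerSpec] = [
            LayerSpec(7, nf, 1),
            LayerSpec(7, nf, nf),
            LayerSpec(1, w, nf),          # shrink
        ]
        for _ in range(self.kr_blocks):
            plan.extend(self.kr.layer_plan())
        plan.extend([
            LayerSpec(1, nf, w),          # expand
            LayerSpec(3, nf, nf),         # reconstruction
            LayerSpec(3, 1, nf, activation="none"),  # final (stride-1 deconv)
        ])
        return tuple(plan)

    def to_dict(self) -> dict:
        return {"n_features": self.n_features, "kr_blocks": self.kr_blocks,
                "kr": {"width": self.kr.width, "reduce": self.kr.reduce},
                "input_shortcut": self.input_shortcut}

    @classmethod
    def from_dict(cls, d: dict) -> "SRDNSpec":
        return cls(n_features=d["n_features"], kr_blocks=d["kr_blocks"],
                   kr=KRBlockSpec(**d["kr"]), input_shortcut=d["input_shortcut"])


@dataclass(frozen=True)
class STIRSpec:
    """One SRDN spec per cross-section."""

    xy: SRDNSpec = field(default_factory=SRDNSpec)
    xt: SRDNSpec = field(default_factory=SRDNSpec)
    yt: SRDNSpec = field(default_factory=SRDNSpec)

    @classmethod
    def desk(cls) -> "STIRSpec":
        d = SRDNSpec.desk()
        return cls(xy=d, xt=d, yt=d)

    def branch(self, section: str) -> SRDNSpec:
        return getattr(self, section)


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 64
    iterations: int = 1000
    seed: int = 0
    checkpoint_interval: int = 0  # 0 = no checkpoints

    def __post_init__(self) -> None:
        if self.loss != "mse":
            raise InvalidInputError("only the MSE loss is supported")
        if self.optimizer != "adam":
            raise InvalidInputError("only the Adam optimizer is supported")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning rate must be > 0")
        if self.iterations < 0 or self.batch_size < 1:
            raise InvalidInputError("iterations must be >= 0 and batch_size >= 1")


# ---------------------------------------------------------------------------
# Layers (NCHW, float32)
# ---------------------------------------------------------------------------

class Conv2D:
    """Same-padded 2D convolution via im2col + GEMM, with backward pass."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator | None = None,
                 init: str = "he", init_scale: float = 1.0) -> None:
        self.c_in, self.c_out, self.k = c_in, c_out, k
        if init == "zeros" or rng is None:
            self.W = np.zeros((c_out, c_in, k, k), dtype=np.float32)
        else:
            std = init_scale * np.sqrt(2.0 / (c_in * k * k))
            self.W = (rng.standard_normal((c_out, c_in, k, k)) * std).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise InvalidInputError(f"expected {self.c_in} input channels, got {c}")
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k)
        out = cols @ self.W.reshape(self.c_out, -1).T + self.b
        if train:
            self._cols, self._in_shape = cols, x.shape
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward called before a train-mode forward")
        n, c, h, w = self._in_shape
        k, p = self.k, self.k // 2
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, self.c_out)
        self.gW += (g_mat.T @ self._cols).reshape(self.W.shape)
        self.gb += g_mat.sum(axis=0)
        gcols = (g_mat @ self.W.reshape(self.c_out, -1)).reshape(n, h, w, c, k, k)
        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, h, w, k, k)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + h, j:j + w] += gcols[:, :, :, :, i, j]
        self._cols = None
        return gxp[:, :, p:p + h, p:p + w] if p else gxp

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.gW), (self.b, self.gb)]

    @property
    def conv_param_count(self) -> int:
        return self.W.size + self.b.size


class PReLU:
    """Per-channel parametric ReLU, slope initialized at 0.25."""

    def __init__(self, channels: int) -> None:
        self.a = np.full(channels, 0.25, dtype=np.float32)
        self.ga = np.zeros_like(self.a)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        a = self.a.reshape(1, -1, 1, 1)
        return np.where(x > 0, x, a * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward called before a train-mode forward")
        neg = x <= 0
        self.ga += np.einsum("nchw->c", np.where(neg, g * x, 0.0).astype(np.float32))
        self._x = None
        return np.where(neg, g * self.a.reshape(1, -1, 1, 1), g).astype(np.float32)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.a, self.ga)]


class _ConvAct:
    """Convolution followed (optionally) by PReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, rng, init: str,
                 activation: bool = True, init_scale: float = 1.0) -> None:
        self.conv = Conv2D(c_in, c_out, k, rng, init, init_scale)
        self.act = PReLU(c_out) if activation else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.conv.forward(x, train)
        return self.act.forward(y, train) if self.act is not None else y

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.act is not None:
            g = self.act.backward(g)
        return self.conv.backward(g)

    def parameters(self):
        out = self.conv.parameters()
        if self.act is not None:
            out += self.act.parameters()
        return out


# ---------------------------------------------------------------------------
# KR-block and SRDN
# ---------------------------------------------------------------------------

class KRBlock:
    """Kernel-regulation block (see module docstring for the dataflow)."""

    def __init__(self, spec: KRBlockSpec, rng=None, init: str = "he") -> None:
        self.spec = spec
        w, r = spec.width, spec.reduce
        self.reduce = _ConvAct(w, r, 1, rng, init)
        self.large = _ConvAct(r, w, 7, rng, init)
        self.small = _ConvAct(w, w, 3, rng, init)
        self.project = _ConvAct(w, w, 1, rng, init)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.reduce.forward(x, train)
        b = self.large.forward(a, train)
        c = self.small.forward(b, train)
        d = self.project.forward(b + c, train)
        return d + x

    def backward(self, g: np.ndarray) -> np.ndarray:
        gs = self.project.backward(g)
        gb = gs + self.small.backward(gs)
        ga = self.large.backward(gb)
        return self.reduce.backward(ga) + g

    def parameters(self):
        return (self.reduce.parameters() + self.large.parameters()
                + self.small.parameters() + self.project.parameters())

    @property
    def conv_param_count(self) -> int:
        return sum(m.conv.conv_param_count
                   for m in (self.reduce, self.large, self.small, self.project))


class SRDN:
    """One branch network; fully convolutional, shape-preserving."""

    def __init__(self, spec: SRDNSpec | None = None, seed: int = 0,
                 init: str = "he") -> None:
        self.spec = spec or SRDNSpec()
        rng = np.random.default_rng(seed) if init != "zeros" else None
        nf, w = self.spec.n_features, self.spec.kr.width
        self.feat1 = _ConvAct(1, nf, 7, rng, init)
        self.feat2 = _ConvAct(nf, nf, 7, rng, init)
        self.shrink = _ConvAct(nf, w, 1, rng, init)
        self.blocks = [KRBlock(self.spec.kr, rng, init)
                       for _ in range(self.spec.kr_blocks)]
        self.expand = _ConvAct(w, nf, 1, rng, init)
        self.recon1 = _ConvAct(nf, nf, 3, rng, init)
        # residual head starts small so the initial map is near-identity
        self.recon2 = _ConvAct(nf, 1, 3, rng, init, activation=False, init_scale=0.1)

    def _modules(self):
        return [self.feat1, self.feat2, self.shrink, *self.blocks,
                self.expand, self.recon1, self.recon2]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) in [0, 1]; returns the same shape."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise InvalidInputError(f"expected (N, 1, H, W) input, got {x.shape}")
        y = x
        for m in self._modules():
            y = m.forward(y, train)
        return y + x if self.spec.input_shortcut else y

    def backward(self, g: np.ndarray) -> np.ndarray:
        gin = g
        for m in reversed(self._modules()):
            gin = m.backward(gin)
        return gin + g if self.spec.input_shortcut else gin

    def parameters(self):
        out = []
        for m in self._modules():
            out += m.parameters()
        return out

    def zero_grad(self) -> None:
        for _, grad in self.parameters():
            grad[...] = 0.0

    @property
    def conv_param_count(self) -> int:
        return sum(spec.param_count for spec in self.spec.layer_plan())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": w for i, (w, _) in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (w, _) in enumerate(self.parameters()):
            w[...] = arrays[f"p{i}"]


class STIRModel:
    """Three trained SRDN branches keyed by cross-section."""

    def __init__(self, branches: dict[str, SRDN]) -> None:
        self.branches = dict(branches)

    @classmethod
    def from_spec(cls, spec: STIRSpec, seed: int = 0, init: str = "he") -> "STIRModel":
        return cls({sec: SRDN(spec.branch(sec), seed=seed + i, init=init)
                    for i, sec in enumerate(CROSS_SECTIONS)})


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------

def kr_block_forward(x: np.ndarray, block: KRBlock) -> np.ndarray:
    """Run one KR-block on an (H, W, width) feature tensor."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise InvalidInputError("expected an (H, W, C) feature tensor")
    if x.shape[2] != block.spec.width:
        raise InvalidInputError(
            f"expected {block.spec.width} channels, got {x.shape[2]}")
    out = block.forward(x.transpose(2, 0, 1)[None])
    return out[0].transpose(1, 2, 0)


def srdn_forward(image: np.ndarray, model: SRDN) -> np.ndarray:
    """Restore one 2D image (any H, W >= 7) on the normalized [0, 1] scale."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise InvalidInputError("expected a single-channel 2D image")
    return model.forward(image[None, None])[0, 0]


def conjoint_merge(vol_xy: CTPVolume, vol_xt: CTPVolume,
                   vol_yt: CTPVolume) -> CTPVolume:
    """Voxel-wise arithmetic mean of the three branch volumes."""
    if not (vol_xy.shape == vol_xt.shape == vol_yt.shape):
        raise InvalidInputError(
            f"branch shapes differ: {vol_xy.shape}, {vol_xt.shape}, {vol_yt.shape}")
    mean = (vol_xy.data.astype(np.float64) + vol_xt.data + vol_yt.data) / 3.0
    return vol_xy.with_data(mean)


def _pairs_to_arrays(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input_patch for p in pairs]).astype(np.float32)[:, None]
    y = np.stack([p.label_patch for p in pairs]).astype(np.float32)[:, None]
    return x, y


class _Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            w -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)


def train_srdn(pairs: list[PatchPair], spec: SRDNSpec | None = None,
               cfg: TrainConfig = TrainConfig(),
               checkpoint_dir: str | Path | None = None,
               init: str = "he") -> tuple[SRDN, np.ndarray]:
    """Minimize the MSE between restored and label patches with Adam.

    Deterministic given ``cfg.seed`` and a fixed iteration schedule.
    Returns the trained model and the per-iteration loss trace.
    """
    if not pairs:
        raise InvalidInputError("empty training set")
    x_all, y_all = _pairs_to_arrays(pairs)
    model = SRDN(spec, seed=cfg.seed, init=init)
    if cfg.iterations == 0:
        return model, np.empty(0)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))  # fixed-seed shuffle for i.i.d. batches
    x_all, y_all = x_all[order], y_all[order]
    opt = _Adam(model.parameters(), cfg.learning_rate)
    trace = np.empty(cfg.iterations, dtype=np.float64)
    n = len(pairs)
    for it in range(cfg.iterations):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        xb, yb = x_all[idx], y_all[idx]
        out = model.forward(xb, train=True)
        diff = out - yb
        trace[it] = float(np.mean(diff ** 2))
        model.zero_grad()
        model.backward((2.0 / diff.size) * diff.astype(np.float32))
        opt.step()
        if checkpoint_dir and cfg.checkpoint_interval \
                and (it + 1) % cfg.checkpoint_interval == 0:
            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            np.savez(ckpt / f"step_{it + 1:06d}.npz", **model.state_arrays())
    return model, trace


def restore_volume(degraded: CTPVolume, model: STIRModel,
                   hu_window: tuple[float, float] = HU_WINDOW
                   ) -> tuple[CTPVolume, dict[str, CTPVolume]]:
    """Restore a full volume: per-section full-image SRDN passes, restacked
    and blended by the conjoint mean.  Returns (conjoint, per-branch volumes)
    so spatial-only / temporal-only arms can be evaluated too."""
    missing = [s for s in CROSS_SECTIONS if s not in model.branches]
    if missing:
        raise ConfigurationError(f"missing trained branches: {missing}")
    vol_n = degraded.with_data(normalize(degraded.data, hu_window, clip=True))
    branch_vols: dict[str, CTPVolume] = {}
    for sec in CROSS_SECTIONS:
        images = extract_cross_sections(vol_n, sec)
        outs = [srdn_forward(img, model.branches[sec]) for img in images]
        restored = stack_to_volume(outs, sec, dt=degraded.dt,
                                   pixel_size=degraded.pixel_size)
        branch_vols[sec] = restored.with_data(denormalize(restored.data, hu_window))
    conjoint = conjoint_merge(branch_vols["xy"], branch_vols["xt"], branch_vols["yt"])
    return conjoint, branch_vols


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------

def save_model(model: STIRModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    specs = {}
    for sec, srdn in model.branches.items():
        np.savez(directory / f"{sec}.npz", **srdn.state_arrays())
        specs[sec] = srdn.spec.to_dict()
    (directory / "stir_spec.json").write_text(json.dumps(specs, indent=1))


def load_model(directory: str | Path) -> STIRModel:
    directory = Path(directory)
    spec_path = directory / "stir_spec.json"
    if not spec_path.exists():
        raise ConfigurationError(f"{directory} does not contain stir_spec.json")
    specs = json.loads(spec_path.read_text())
    branches = {}
    for sec, spec_dict in specs.items():
        srdn = SRDN(SRDNSpec.from_dict(spec_dict), init="zeros")
        with np.load(directory / f"{sec}.npz") as arrays:
            srdn.load_state_arrays(dict(arrays))
        branches[sec] = srdn
    return STIRModel(branches)
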