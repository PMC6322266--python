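"""Residual U-net valve segmentation: architecture, preprocessing, inference.

The network is a 2D encoder-decoder with skip connections between the
contracting and expanding paths; each resolution level is a residual block
(two 3x3 convolutions with an identity shortcut, projected by a 1x1
convolution when the channel count changes).  Residual shortcuts keep
gradients well-conditioned in the deeper profiles.  Only the magnitude
image is fed to the network; the phase channel plays no part in
segmentation.  Inference is per-frame and fully deterministic: per-pixel
argmax over the two class logits, with exact ties resolved to non-valve.

Two profiles are provided: the default clinical-scale profile (depth 5,
32 base filters, 256x256 inputs) and a reduced desk-scale profile
(depth 3, 8 base filters, 64x64 inputs) used for fast experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import PCSeries, SegmentationMap
from .nn import Conv2d, MaxPool2x2, ReLU, Upsample2x

__all__ = [
    "ModelConfig",
    "GeometryRecord",
    "ResidualUNet",
    "preprocess",
    "preprocess_frames",
    "inverse_map_masks",
    "segment",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    depth: number of resolution levels (the bottleneck sits at level
    depth-1, so spatial size is divided by 2^(depth-1)); base_filters:
    channels at the top level, doubling per level; input_size: square
    working resolution the preprocessor produces.
    """

    depth: int = 5
    base_filters: int = 32
    in_channels: int = 1
    out_classes: int = 2
    use_residual: bool = True
    input_size: int = 256

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.out_classes != 2:
            raise ValueError("binary valve/non-valve segmentation requires out_classes=2")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}"
            )

    @classmethod
    def reduced(cls) -> "ModelConfig":
        return cls(depth=3, base_filters=8, input_size=64)


class _ResidualBlock:
    """conv3x3 -> ReLU -> conv3x3, plus identity (or 1x1-projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng, name: str, residual: bool = True):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, f"{name}.conv2")
        self.residual = residual
        self.proj = (
            Conv2d(in_ch, out_ch, 1, rng, f"{name}.proj")
            if residual and in_ch != out_ch
            else None
        )
        self.relu_out = ReLU()

    def layers(self):
        out = [self.conv1, self.conv2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x, train=True):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        y = self.conv2.forward(h, train)
        if self.residual:
            y = y + (self.proj.forward(x, train) if self.proj is not None else x)
        return self.relu_out.forward(y, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        if self.residual:
            dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx


class ResidualUNet:
    """Encoder-decoder with skip connections and residual blocks per level.

    Accepts any square input whose side is divisible by 2^(depth-1) and
    emits per-pixel logits for the two classes at input resolution.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = [cfg.base_filters * 2**l for l in range(cfg.depth)]
        self.channels = ch
        d = cfg.depth
        self.enc = []
        in_ch = cfg.in_channels
        for l in range(d):
            self.enc.append(
                _ResidualBlock(in_ch, ch[l], rng, f"enc{l}", cfg.use_residual)
            )
            in_ch = ch[l]
        self.pools = [MaxPool2x2() for _ in range(d - 1)]
        self.ups, self.red, self.red_relu, self.dec = [], [], [], []
        for idx, l in enumerate(range(d - 2, -1, -1)):
            self.ups.append(Upsample2x())
            self.red.append(Conv2d(ch[l + 1], ch[l], 3, rng, f"red{idx}"))
            self.red_relu.append(ReLU())
            self.dec.append(
                _ResidualBlock(2 * ch[l], ch[l], rng, f"dec{idx}", cfg.use_residual)
            )
        self.head = Conv2d(ch[0], cfg.out_classes, 1, rng, "head")

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        params = []
        for block in self.enc + self.dec:
            for layer in block.layers():
                params.extend(layer.parameters())
        for conv in self.red:
            params.extend(conv.parameters())
        params.extend(self.head.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            if name not in state:
                raise KeyError(f"checkpoint missing parameter {name}")
            if state[name].shape != p.shape:
                raise ValueError(
                    f"parameter {name}: checkpoint shape {state[name].shape} "
                    f"!= model shape {p.shape}"
                )
            p[...] = state[name]

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}")
        h, w = x.shape[2:]
        div = 2 ** (self.cfg.depth - 1)
        if h != w or h % div != 0:
            raise ValueError(
                f"input must be square with side divisible by {div}, got {h}x{w}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x)
        x = x.astype(np.float32, copy=False)
        d = self.cfg.depth
        skips = []
        h = x
        for l in range(d - 1):
            h = self.enc[l].forward(h, train)
            skips.append(h)
            h = self.pools[l].forward(h, train)
        h = self.enc[d - 1].forward(h, train)
        for idx, l in enumerate(range(d - 2, -1, -1)):
            h = self.ups[idx].forward(h, train)
            h = self.red_relu[idx].forward(self.red[idx].forward(h, train), train)
            h = np.concatenate([h, skips[l]], axis=1)
            h = self.dec[idx].forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.cfg.depth
        grad = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * (d - 1)
        for idx in reversed(range(d - 1)):
            l = d - 2 - idx
            grad = self.dec[idx].backward(grad)
            c = self.channels[l]
            dred, dskips[l] = grad[:, :c], grad[:, c:]
            grad = self.red[idx].backward(self.red_relu[idx].backward(dred))
            grad = self.ups[idx].backward(grad)
        grad = self.enc[d - 1].backward(grad)
        for l in reversed(range(d - 1)):
            grad = self.pools[l].backward(grad)
            grad = grad + dskips[l]
            grad = self.enc[l].backward(grad)
        return grad

    def predict_logits(self, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference logits for a (N, H, W) normalized frame stack."""
        outs = []
        for start in range(0, frames.shape[0], batch_size):
            batch = frames[start : start + batch_size, None].astype(np.float32)
            outs.append(self.forward(batch, train=False))
        return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryRecord:
    """Everything needed to map padded-grid masks back to native geometry."""

    native_shape: tuple[int, int]
    zoom: float
    resampled_shape: tuple[int, int]
    pad_top: int
    pad_left: int
    target: int


def _geometry_for(shape: tuple[int, int], target: int) -> GeometryRecord:
    h, w = shape
    zoom = 1.0
    rh, rw = h, w
    if max(h, w) > target:
        zoom = target / max(h, w)
        rh, rw = int(round(h * zoom)), int(round(w * zoom))
    if rh > target or rw > target:
        raise ValueError(f"frame {shape} does not fit target {target} after resampling")
    # center with the extra pixel on the bottom/right when the gap is odd
    pad_top = (target - rh) // 2
    pad_left = (target - rw) // 2
    return GeometryRecord((h, w), zoom, (rh, rw), pad_top, pad_left, target)


def preprocess_frames(
    frames: np.ndarray, target: int = 256
) -> tuple[np.ndarray, GeometryRecord]:
    """Resample (if needed), center-zero-pad to target x target, min-max rescale.

    The rescale is per-exam (one min/max across all frames), preserving
    relative frame intensities; a constant stack maps to all zeros.
    """
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("expected a non-empty (n_frames, H, W) stack")
    geom = _geometry_for(frames.shape[1:], target)
    # rescale on native content (not the zero padding) so a constant stack
    # degenerates to all zeros rather than all ones
    lo, hi = float(frames.min()), float(frames.max())
    if hi > lo:
        frames = (frames.astype(np.float64) - lo) / (hi - lo)
    else:
        frames = np.zeros_like(frames, dtype=np.float64)
    out = np.zeros((frames.shape[0], target, target), dtype=np.float64)
    for n, frame in enumerate(frames):
        if geom.zoom != 1.0:
            resampled = ndimage.zoom(frame, geom.zoom, order=1)
            resampled = resampled[: geom.resampled_shape[0], : geom.resampled_shape[1]]
        else:
            resampled = frame
        rh, rw = resampled.shape
        out[n, geom.pad_top : geom.pad_top + rh, geom.pad_left : geom.pad_left + rw] = resampled
    return out.astype(np.float32), geom


def preprocess(series: PCSeries, target: int = 256) -> tuple[np.ndarray, GeometryRecord]:
    """Normalized magnitude stack + geometry record for a series."""
    return preprocess_frames(series.magnitude, target=target)


def inverse_map_masks(masks: np.ndarray, geom: GeometryRecord) -> np.ndarray:
    """Map padded-grid binary masks back to native geometry (nearest-neighbor)."""
    rh, rw = geom.resampled_shape
    cropped = masks[:, geom.pad_top : geom.pad_top + rh, geom.pad_left : geom.pad_left + rw]
    if geom.zoom == 1.0:
        return cropped.astype(np.uint8)
    h, w = geom.native_shape
    out = np.zeros((masks.shape[0], h, w), dtype=np.uint8)
    for n, frame in enumerate(cropped):
        back = ndimage.zoom(frame.astype(np.uint8), 1.0 / geom.zoom, order=0)
        out[n, : min(h, back.shape[0]), : min(w, back.shape[1])] = back[:h, :w]
    return out


def segment(series: PCSeries, model: ResidualUNet) -> SegmentationMap:
    """Fully automatic valve segmentation of an exam.

    Per-pixel argmax over the two class logits; an exact tie goes to
    non-valve (class 0).  The mask is inverse-mapped to native geometry.
    """
    if not isinstance(model, ResidualUNet):
        raise TypeError(f"expected a ResidualUNet, got {type(model).__name__}")
    frames, geom = preprocess(series, target=model.cfg.input_size)
    logits = model.predict_logits(frames)
    # argmax returns the first index on ties, and class 0 is non-valve
    labels = np.argmax(logits, axis=1).astype(np.uint8)
    return SegmentationMap(inverse_map_masks(labels, geom))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    model: ResidualUNet,
    path: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Save parameters with the embedded ModelConfig and training metadata."""
    path = Path(path)
    record = {"config": asdict(model.cfg), "metadata": metadata or {}}
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["__meta__"] = np.array(json.dumps(record))
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **payload)
    return path


def load_checkpoint(path: str | Path) -> tuple[ResidualUNet, dict]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        if "__meta__" not in z.files:
            raise ValueError(f"{path} is not a model checkpoint")
        record = json.loads(str(z["__meta__"]))
        cfg = ModelConfig(**record["config"])
        model = ResidualUNet(cfg, seed=0)
        state = {k[len("param/") :]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model, record.get("metadata", {})
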