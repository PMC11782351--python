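"""Virtual staining: bright-field -> fluorescence image regression.

The network is a UNet whose convolution blocks are residual channel-attention
(RCA) blocks: two 3x3 convolutions with ReLU, a channel-attention gate
(global average pool per channel -> bottleneck MLP of width ``channels / r``
-> sigmoid gate scaling each channel), and a residual addition of the block
input (through a 1x1 projection when channel counts differ).  The encoder
halves resolution and doubles channels per level; the decoder mirrors it with
nearest-neighbor upsampling and skip concatenation; a 1x1 linear head emits
one channel.

Training minimizes MSE (or MAE) over seeded random patches cropped from the
input pairs, with optional 8-fold dihedral augmentation, using Adam.  Inputs
and targets are percentile-normalized to [0, 1]; predictions are therefore in
normalized units, which is immaterial downstream because both the overlap
score and Otsu segmentation are intensity-rank based.

One trained model maps bright-field to one structure's channel; multiplex
("triple") staining applies several single-channel models to the same
bright-field image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "TrainedModel", "TrainingHistory",
           "build_model", "normalize", "train", "predict", "predict_multiplex",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 4
    base_channels: int = 16
    attention_reduction_r: int = 16
    patch_size_px: int = 128
    loss: str = "mse"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.patch_size_px % (2 ** self.depth) != 0:
            raise ValueError("patch_size must be divisible by 2^depth")
        if self.attention_reduction_r > self.base_channels * 2 ** self.depth:
            raise ValueError("attention_reduction_r too large for the channel widths")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)


class _RCABlock:
    """Two 3x3 convs + channel attention + residual addition of the input."""

    def __init__(self, rng, c_in, c_out, r):
        self.c_in, self.c_out = c_in, c_out
        self.conv1 = _conv_init(rng, c_out, c_in, 3)
        self.conv2 = _conv_init(rng, c_out, c_out, 3)
        hidden = max(c_out // r, 1)
        self.fc1 = _dense_init(rng, c_out, hidden)
        self.fc2 = _dense_init(rng, hidden, c_out)
        self.proj = _conv_init(rng, c_out, c_in, 1) if c_in != c_out else None

    def params(self):
        ps = [*self.conv1, *self.conv2, *self.fc1, *self.fc2]
        if self.proj is not None:
            ps += list(self.proj)
        return ps

    def __call__(self, x, gate_store=None, gate_inject=None, key=None):
        h = nn.relu(nn.conv2d(x, *self.conv1))
        h = nn.relu(nn.conv2d(h, *self.conv2))
        if gate_inject is not None:
            g = nn.Tensor(np.broadcast_to(gate_inject[key], (h.data.shape[0],
                                                             h.data.shape[1])))
        else:
            g = nn.global_avg_pool(h)
            g = nn.relu(nn.dense(g, *self.fc1))
            g = nn.sigmoid(nn.dense(g, *self.fc2))
            if gate_store is not None:
                gate_store[key] = g.data.mean(axis=0)
        h = nn.scale_channels(h, g)
        res = x if self.proj is None else nn.conv2d(x, *self.proj)
        return nn.add(h, res)

    def attention_gate(self, x):
        """The gate values alone (for contract tests)."""
        h = nn.relu(nn.conv2d(x, *self.conv1))
        h = nn.relu(nn.conv2d(h, *self.conv2))
        g = nn.global_avg_pool(h)
        g = nn.relu(nn.dense(g, *self.fc1))
        return nn.sigmoid(nn.dense(g, *self.fc2))


def _conv_init(rng, c_out, c_in, k):
    fan_in = c_in * k * k
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
    return nn.Parameter(w), nn.Parameter(np.zeros(c_out))


def _dense_init(rng, f_in, f_out):
    w = rng.normal(0.0, np.sqrt(2.0 / f_in), size=(f_in, f_out))
    return nn.Parameter(w), nn.Parameter(np.zeros(f_out))


class _RCAUNet:
    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        c, d, r = config.base_channels, config.depth, config.attention_reduction_r
        self.enc = []
        ch = 1
        for i in range(d):
            self.enc.append(_RCABlock(rng, ch, c * 2 ** i, r))
            ch = c * 2 ** i
        self.bottleneck = _RCABlock(rng, ch, c * 2 ** d, r)
        self.dec = []
        for i in reversed(range(d)):
            self.dec.append(_RCABlock(rng, c * 2 ** (i + 1) + c * 2 ** i, c * 2 ** i, r))
        self.head = _conv_init(rng, 1, c, 1)
        self.config = config

    def params(self):
        ps = []
        for b in self.enc + [self.bottleneck] + self.dec:
            ps += b.params()
        ps += list(self.head)
        return ps

    def forward(self, x: nn.Tensor, gate_store=None, gate_inject=None) -> nn.Tensor:
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h, gate_store, gate_inject, key=f"enc{i}")
            skips.append(h)
            h = nn.maxpool2(h)
        h = self.bottleneck(h, gate_store, gate_inject, key="bottleneck")
        for i, (block, skip) in enumerate(zip(self.dec, reversed(skips))):
            h = nn.upsample2(h)
            h = block(nn.concat(h, skip), gate_store, gate_inject, key=f"dec{i}")
        return nn.conv2d(h, *self.head)

    def predict_array(self, batch: np.ndarray, gate_store=None,
                      gate_inject=None) -> np.ndarray:
        return self.forward(nn.Tensor(batch), gate_store, gate_inject).data


@dataclass
class TrainedModel:
    """RCA-UNet weights plus the normalization scheme and target channel name."""

    net: _RCAUNet
    config: ModelConfig
    norm: dict
    channel_name: str = ""
    trained: bool = False


def build_model(config: ModelConfig, channel_name: str = "") -> TrainedModel:
    """Seeded, untrained model obeying the architecture contract."""
    return TrainedModel(net=_RCAUNet(config), config=config,
                        norm={"low_pct": 1.0, "high_pct": 99.0},
                        channel_name=channel_name, trained=False)


def normalize(image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Affine map of [P_low, P_high] to [0, 1], clipped."""
    if not low_pct < high_pct:
        raise ValueError("low_pct must be < high_pct")
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi <= lo:
        raise ValueError("degenerate intensity range: cannot normalize (constant image?)")
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


_DIHEDRAL = [lambda p: p,
             lambda p: np.rot90(p, 1, axes=(-2, -1)),
             lambda p: np.rot90(p, 2, axes=(-2, -1)),
             lambda p: np.rot90(p, 3, axes=(-2, -1)),
             lambda p: p[..., ::-1],
             lambda p: np.rot90(p[..., ::-1], 1, axes=(-2, -1)),
             lambda p: np.rot90(p[..., ::-1], 2, axes=(-2, -1)),
             lambda p: np.rot90(p[..., ::-1], 3, axes=(-2, -1))]


def train(model: TrainedModel, pairs, config: ModelConfig = None):
    """Train on (bright-field, target) image pairs; returns (model, history).

    Each epoch draws one random patch per pair (uniform window position,
    optional dihedral augmentation) and sweeps them in seeded shuffled
    minibatches.  Deterministic given the config seed and a fixed BLAS thread
    policy.
    """
    cfg = config or model.config
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one training pair")
    ps = cfg.patch_size_px
    norm_pairs = []
    for i, (bf, tgt) in enumerate(pairs):
        bf, tgt = np.asarray(bf, dtype=np.float32), np.asarray(tgt, dtype=np.float32)
        if bf.shape != tgt.shape:
            raise ValueError(f"pair {i}: shape mismatch {bf.shape} vs {tgt.shape}")
        if bf.shape[0] < ps or bf.shape[1] < ps:
            raise ValueError(f"pair {i}: image smaller than patch_size {ps}")
        norm_pairs.append((normalize(bf, model.norm["low_pct"], model.norm["high_pct"]),
                           _norm_target(tgt, model.norm)))

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    loss_fn = nn.mse_loss if cfg.loss == "mse" else nn.mae_loss
    history = TrainingHistory()
    n = len(norm_pairs)
    for _ in range(cfg.epochs):
        xs, ys = [], []
        for bf, tgt in norm_pairs:
            r = rng.integers(0, bf.shape[0] - ps + 1)
            c = rng.integers(0, bf.shape[1] - ps + 1)
            px, py = bf[r:r + ps, c:c + ps], tgt[r:r + ps, c:c + ps]
            if cfg.augment:
                f = _DIHEDRAL[rng.integers(0, 8)]
                px, py = f(px), f(py)
            xs.append(px)
            ys.append(py)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = np.ascontiguousarray(np.stack([xs[i] for i in idx])[:, None])
            yb = np.ascontiguousarray(np.stack([ys[i] for i in idx])[:, None])
            opt.zero_grad()
            loss = loss_fn(model.net.forward(nn.Tensor(xb)), yb)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(epoch_losses)))
    model.trained = True
    return model, history


def _norm_target(tgt, norm):
    """Targets use the same percentile scheme; already-[0,1] flat targets pass through."""
    lo, hi = np.percentile(tgt, [norm["low_pct"], norm["high_pct"]])
    if hi <= lo:  # near-constant target (e.g. mostly background): keep raw scale
        return np.clip(tgt, 0.0, 1.0).astype(np.float32)
    return np.clip((tgt - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def _pad_to_multiple(img, mult):
    h, w = img.shape
    ph = (-h) % mult
    pw = (-w) % mult
    return np.pad(img, ((0, ph), (0, pw)), mode="reflect"), h, w


def predict(model: TrainedModel, image: np.ndarray, tile: int = None,
            overlap: int = None, allow_untrained: bool = True) -> np.ndarray:
    """Virtually stain one bright-field image.

    Images up to 256 px on a side are processed whole (padded to a multiple of
    ``2^depth``); larger ones are processed as overlapping tiles.  Tiled
    prediction is a two-pass scheme: the channel-attention gates are first
    captured from one pass over the whole image (downsampled 2x when very
    large) and then injected into every tile, so tiles agree with the
    whole-image computation except near their borders; each tile's outer
    margin is discarded and the remainder blended with a Hann-style feather.
    """
    img = np.asarray(image, dtype=np.float32)
    if not model.trained and not allow_untrained:
        raise ValueError("model is untrained")
    mult = 2 ** model.config.depth
    if img.shape[0] < mult or img.shape[1] < mult:
        raise ValueError(f"image smaller than the minimum tile ({mult} px)")
    x = normalize(img, model.norm["low_pct"], model.norm["high_pct"]).astype(np.float32)

    if tile is None and max(x.shape) <= 256:
        xp, h, w = _pad_to_multiple(x, mult)
        out = model.net.predict_array(xp[None, None])[0, 0]
        return out[:h, :w].astype(np.float32)

    tile = tile or max(model.config.patch_size_px, 4 * mult)
    overlap = overlap if overlap is not None else max(tile // 2, 2 * mult)
    overlap = max(overlap, mult)
    if tile % mult or overlap >= tile:
        raise ValueError("tile must be a multiple of 2^depth and larger than overlap")

    xp, h, w = _pad_to_multiple(x, mult)
    hp, wp = xp.shape

    # pass 1: attention gates from a single global view
    gates = {}
    gv = xp if max(xp.shape) <= 512 else xp[::2, ::2]
    gvp, _, _ = _pad_to_multiple(gv, mult)
    model.net.predict_array(gvp[None, None], gate_store=gates)

    step = tile - overlap
    margin = overlap // 2
    acc = np.zeros((hp, wp), dtype=np.float64)
    wsum = np.zeros((hp, wp), dtype=np.float64)
    rows = sorted({min(r, max(hp - tile, 0)) for r in range(0, max(hp - overlap, 1), step)})
    cols = sorted({min(c, max(wp - tile, 0)) for c in range(0, max(wp - overlap, 1), step)})
    for r in rows:
        for c in cols:
            th = min(tile, hp - r)
            tw = min(tile, wp - c)
            patch = xp[r:r + th, c:c + tw]
            pp, th0, tw0 = _pad_to_multiple(patch, mult)
            pred = model.net.predict_array(pp[None, None],
                                           gate_inject=gates)[0, 0][:th0, :tw0]
            # keep the interior; tile edges flush with the image keep their border
            t0r = 0 if r == 0 else margin
            t0c = 0 if c == 0 else margin
            t1r = th if r + th >= hp else th - margin
            t1c = tw if c + tw >= wp else tw - margin
            wwin = np.outer(_feather_1d(th, t0r, t1r), _feather_1d(tw, t0c, t1c))
            acc[r:r + th, c:c + tw] += pred * wwin
            wsum[r:r + th, c:c + tw] += wwin
    out = acc / np.maximum(wsum, 1e-12)
    return out[:h, :w].astype(np.float32)


def _feather_1d(n, lo, hi):
    """Raised-cosine weights supported on [lo, hi) of an n-sample axis."""
    w = np.zeros(n)
    m = hi - lo
    w[lo:hi] = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(m) + 0.5) / m)
    w[lo:hi] = np.maximum(w[lo:hi], 1e-4)
    return w


def predict_multiplex(models, image: np.ndarray, **kw) -> np.ndarray:
    """Apply several single-channel models to one bright-field image.

    Returns a (n_models, H, W) stack — e.g. membrane + nucleus + vacuole gives
    a triple virtual stain.
    """
    return np.stack([predict(m, image, **kw) for m in models])


# ---------------------------------------------------------------------------
# serialization: framework weights + JSON config sidecar

def save_model(model: TrainedModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.net.params())}
    np.savez(d / "weights.npz", **arrays)
    sidecar = {"config": asdict(model.config), "norm": model.norm,
               "channel_name": model.channel_name, "trained": model.trained,
               "format_version": 1}
    (d / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(directory) -> TrainedModel:
    d = Path(directory)
    sidecar = json.loads((d / "model.json").read_text())
    cfg = ModelConfig(**sidecar["config"])
    model = build_model(cfg, channel_name=sidecar["channel_name"])
    with np.load(d / "weights.npz") as data:
        for i, p in enumerate(model.net.params()):
            arr = data[f"p{i}"]
            assert arr.shape == p.data.shape
            p.data = arr.astype(np.float32)
    model.norm = sidecar["norm"]
    model.trained = sidecar["trained"]
    return model
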