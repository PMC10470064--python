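"""HARnet: residual backbone with three hybrid attention modules and GAP head.

The hybrid attention module gates a refined bottom branch with the sigmoid
of two context terms computed from the input X (C x H x W):

* local context   P(X) = p21(p11(X))  — two pointwise convolutions C -> C/r -> C
* global context  G(X) = p22(p12(g(X))) — the same bottleneck applied to the
  per-channel global average g(X), broadcast over space
* bottom branch   B(X) — variant-specific: H1 runs two bottom-up (3x3/2 max
  pool) / top-down (bilinear) stages interleaved with residual units, H2 one
  such stage (B = R2(I1(M1(R1(X))))), H3 is the identity map
* output          X' = sigmoid(P(X) + G(X)) * B(X), elementwise

The backbone is a pre-activation ResNet: 7x7/2 stem + 3x3/2 max pool, three
residual stages with an attention module after each, and a final projection
stage widening to the GAP width (2048 by default).  Multi-view features are
the per-channel global averages of the three attention outputs plus the GAP
vector itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import NUM_CLASSES
from .nn import (
    Adam,
    inference_mode,
    BatchNorm2d,
    BilinearResize,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    sigmoid,
    softmax,
    softmax_cross_entropy,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class HybridAttentionConfig:
    variant: str  # "H1" | "H2" | "H3"
    channels: int
    reduction: int = 4

    def __post_init__(self):
        if self.variant not in ("H1", "H2", "H3"):
            raise ConfigurationError(f"unknown attention variant {self.variant!r}")
        if self.channels % self.reduction:
            raise ConfigurationError("channels must be divisible by reduction")


@dataclass
class HarnetConfig:
    """Architecture configuration.

    ``stage_widths`` are the channel counts of the three residual stages;
    ``final_width`` is the projection-stage width feeding GAP (2048 by
    default); ``stage_units`` the residual-unit counts per stage.
    """

    input_size: int = 512
    num_classes: int = NUM_CLASSES
    stem_width: int = 64
    stage_widths: tuple = (256, 512, 1024)
    final_width: int = 2048
    stage_units: tuple = (3, 4, 6)
    final_units: int = 1
    reduction: int = 4
    seed: int = 0

    @classmethod
    def tiny(cls, seed=0):
        """Width-reduced preset (widths / 8, 128 px input) for CPU runs."""
        return cls(
            input_size=128,
            stem_width=8,
            stage_widths=(32, 64, 128),
            final_width=256,
            stage_units=(1, 1, 1),
            final_units=1,
            seed=seed,
        )


@dataclass
class TrainConfig:
    epochs: int = 300
    initial_lr: float = 1e-3
    lr_drop_epoch: int = 60
    lr_drop_factor: float = 0.1
    batch_size: int = 16
    seed: int = 0

    def lr_at(self, epoch):
        """Learning rate during a 0-based epoch (drop at ``lr_drop_epoch``)."""
        return self.initial_lr * (self.lr_drop_factor if epoch >= self.lr_drop_epoch else 1.0)


@dataclass
class MultiViewFeatures:
    """Pooled vectors from the attention taps and the GAP layer."""

    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    g: np.ndarray

    def tap(self, name):
        return getattr(self, name)


TAP_ORDER = ("h1", "h2", "h3", "g")


class ResidualUnit(Module):
    """Pre-activation residual unit: BN-ReLU-conv3x3-BN-ReLU-conv3x3 + shortcut.

    The shortcut is the identity when shape is preserved, else a 1x1
    projection convolution applied to the pre-activation.
    """

    def __init__(self, cin, cout, stride=1, rng=None, dtype=np.float32):
        self.bn1 = BatchNorm2d(cin, dtype=dtype)
        self.relu1 = ReLU()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.relu2 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng, dtype=dtype)
        self.projection = None
        if stride != 1 or cin != cout:
            self.projection = Conv2d(cin, cout, 1, stride=stride, pad=0, bias=False,
                                     rng=rng, dtype=dtype)

    def forward(self, x, train=False):
        pre = self.relu1.forward(self.bn1.forward(x, train), train)
        f = self.conv2.forward(
            self.relu2.forward(self.bn2.forward(self.conv1.forward(pre, train), train), train),
            train,
        )
        if self.projection is None:
            self._short_from_pre = False
            return f + x
        self._short_from_pre = True
        return f + self.projection.forward(pre, train)

    def backward(self, dout):
        df = self.conv2.backward(dout)
        df = self.conv1.backward(self.bn2.backward(self.relu2.backward(df)))
        if self._short_from_pre:
            dpre = df + self.projection.backward(dout)
            return self.bn1.backward(self.relu1.backward(dpre))
        dx = self.bn1.backward(self.relu1.backward(df))
        return dx + dout


class HybridAttention(Module):
    """Hybrid attention module; see module docstring for the equations."""

    def __init__(self, cfg: HybridAttentionConfig, rng=None, dtype=np.float32):
        self.cfg = cfg
        c, r = cfg.channels, cfg.reduction
        cmid = c // r
        # top branch P: pointwise conv bottleneck on the full map
        self.p11 = Conv2d(c, cmid, 1, pad=0, rng=rng, dtype=dtype)
        self.p_relu = ReLU()
        self.p21 = Conv2d(cmid, c, 1, pad=0, rng=rng, dtype=dtype)
        # middle branch G: same bottleneck on the pooled vector
        self.gap = GlobalAvgPool()
        self.p12 = Linear(c, cmid, rng=rng, dtype=dtype)
        self.g_relu = ReLU()
        self.p22 = Linear(cmid, c, rng=rng, dtype=dtype)
        # bottom branch B by variant
        if cfg.variant == "H3":
            self.bottom = None
        elif cfg.variant == "H2":
            self.bottom = _DownUp(c, stages=1, rng=rng, dtype=dtype)
        else:  # H1
            self.bottom = _DownUp(c, stages=2, rng=rng, dtype=dtype)

    def forward(self, x, train=False):
        p = self.p21.forward(self.p_relu.forward(self.p11.forward(x, train), train), train)
        gvec = self.p22.forward(
            self.g_relu.forward(self.p12.forward(self.gap.forward(x, train), train), train),
            train,
        )
        g = gvec[:, :, None, None]
        b = x if self.bottom is None else self.bottom.forward(x, train)
        s = sigmoid(p + g)
        self._cache = (s, b)
        return s * b

    def backward(self, dout):
        s, b = self._cache
        db = dout * s
        dlogit = dout * b * s * (1.0 - s)
        dx = self.p11.backward(self.p_relu.backward(self.p21.backward(dlogit)))
        dgvec = dlogit.sum(axis=(2, 3))
        dx += self.gap.backward(
            self.p12.backward(self.g_relu.backward(self.p22.backward(dgvec)))
        )
        if self.bottom is None:
            dx += db
        else:
            dx += self.bottom.backward(db)
        return dx


class _DownUp(Module):
    """Bottom-up top-down branch: residual units around max-pool/upsample stages."""

    def __init__(self, c, stages, rng=None, dtype=np.float32):
        self.stages = stages
        self.r_in = ResidualUnit(c, c, rng=rng, dtype=dtype)
        self.downs = [MaxPool2d(3, 2, 1) for _ in range(stages)]
        self.mids = [ResidualUnit(c, c, rng=rng, dtype=dtype) for _ in range(stages)]
        self.ups = [None] * stages  # built at forward time (need sizes)
        self.r_out = ResidualUnit(c, c, rng=rng, dtype=dtype)
        self._up_units = [ResidualUnit(c, c, rng=rng, dtype=dtype) for _ in range(stages - 1)]

    def forward(self, x, train=False):
        h = self.r_in.forward(x, train)
        sizes = []
        for d, m in zip(self.downs, self.mids):
            sizes.append(h.shape[2:])
            h = m.forward(d.forward(h, train), train)
        for i in range(self.stages):
            size = sizes[-1 - i]
            if self.ups[i] is None or self.ups[i].out_hw != tuple(size):
                self.ups[i] = BilinearResize(tuple(size))
            h = self.ups[i].forward(h, train)
            if i < self.stages - 1:
                h = self._up_units[i].forward(h, train)
        return self.r_out.forward(h, train)

    def backward(self, dout):
        d = self.r_out.backward(dout)
        for i in reversed(range(self.stages)):
            if i < self.stages - 1:
                d = self._up_units[i].backward(d)
            d = self.ups[i].backward(d)
        for dpool, m in zip(reversed(self.downs), reversed(self.mids)):
            d = dpool.backward(m.backward(d))
        return self.r_in.backward(d)


class HARnet(Module):
    """The full network; ``forward`` stores the three attention tap maps."""

    def __init__(self, cfg: HarnetConfig, dtype=np.float32):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        w0 = cfg.stem_width
        self.stem = Sequential(
            Conv2d(3, w0, 7, stride=2, rng=rng, dtype=dtype),
            BatchNorm2d(w0, dtype=dtype),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        widths = cfg.stage_widths
        self.stages = []
        self.attentions = []
        cin = w0
        for si, (wd, nu) in enumerate(zip(widths, cfg.stage_units)):
            stride = 1 if si == 0 else 2
            units = [ResidualUnit(cin, wd, stride=stride, rng=rng, dtype=dtype)]
            units += [ResidualUnit(wd, wd, rng=rng, dtype=dtype) for _ in range(nu - 1)]
            self.stages.append(Sequential(*units))
            self.attentions.append(
                HybridAttention(
                    HybridAttentionConfig(f"H{si + 1}", wd, cfg.reduction), rng=rng, dtype=dtype
                )
            )
            cin = wd
        funits = [ResidualUnit(cin, cfg.final_width, stride=2, rng=rng, dtype=dtype)]
        funits += [
            ResidualUnit(cfg.final_width, cfg.final_width, rng=rng, dtype=dtype)
            for _ in range(cfg.final_units - 1)
        ]
        self.final_stage = Sequential(*funits)
        self.post_bn = BatchNorm2d(cfg.final_width, dtype=dtype)
        self.post_relu = ReLU()
        self.pool = GlobalAvgPool()
        self.fc = Linear(cfg.final_width, cfg.num_classes, rng=rng, dtype=dtype)
        self.taps = {}

    @property
    def tap_widths(self):
        return {
            "h1": self.cfg.stage_widths[0],
            "h2": self.cfg.stage_widths[1],
            "h3": self.cfg.stage_widths[2],
            "g": self.cfg.final_width,
        }

    def forward(self, x, train=False):
        h = self.stem.forward(x, train)
        for i, (st, att) in enumerate(zip(self.stages, self.attentions)):
            h = att.forward(st.forward(h, train), train)
            self.taps[f"h{i + 1}"] = h
        h = self.final_stage.forward(h, train)
        h = self.post_relu.forward(self.post_bn.forward(h, train), train)
        g = self.pool.forward(h, train)
        self.taps["g"] = g
        return self.fc.forward(g, train)

    def backward(self, dout):
        d = self.fc.backward(dout)
        d = self.pool.backward(d)
        d = self.post_bn.backward(self.post_relu.backward(d))
        d = self.final_stage.backward(d)
        for st, att in zip(reversed(self.stages), reversed(self.attentions)):
            d = st.backward(att.backward(d))
        return self.stem.backward(d)

    def n_params(self):
        return sum(p.data.size for p in self.params())


def build_harnet(cfg: HarnetConfig, dtype=np.float32) -> HARnet:
    """Build HARnet; input size must survive the 5 stride-2 reductions."""
    if cfg.input_size % 32:
        raise ConfigurationError("input_size must be divisible by 32")
    return HARnet(cfg, dtype=dtype)


def _as_batch(images, dtype=np.float32):
    """uint8 HxWx3 images -> normalized NCHW float batch."""
    x = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    x = (x / 255.0 - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(dtype)


def predict_proba(model: HARnet, images, batch_size=16):
    out = []
    with inference_mode():
        for i in range(0, len(images), batch_size):
            logits = model.forward(_as_batch(images[i : i + batch_size]), train=False)
            out.append(softmax(logits))
    return np.concatenate(out)


def train_harnet(model: HARnet, images, labels, tcfg: TrainConfig):
    """Cross-entropy training with Adam and the single-step LR schedule.

    Returns a history dict with per-epoch ``loss``, ``accuracy`` and ``lr``.
    """
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if labels.min() < 0 or labels.max() >= model.cfg.num_classes:
        raise ValueError("label out of range")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params(), lr=tcfg.initial_lr)
    n = len(images)
    history = {"loss": [], "accuracy": [], "lr": []}
    for epoch in range(tcfg.epochs):
        opt.lr = tcfg.lr_at(epoch)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb = _as_batch([images[j] for j in idx])
            yb = labels[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits.astype(logits.dtype))
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
        history["lr"].append(opt.lr)
    return history


def extract_multiview(model: HARnet, image, input_size=None) -> MultiViewFeatures:
    """Per-channel global averages of the attention taps plus the GAP vector."""
    size = input_size or model.cfg.input_size
    im = np.asarray(image)
    if im.shape[0] != size or im.shape[1] != size:
        from .preprocess import resize_to_input

        im = resize_to_input(im, size)
    with inference_mode():
        model.forward(_as_batch([im]), train=False)
    pooled = {k: v.mean(axis=(2, 3))[0] if v.ndim == 4 else v[0] for k, v in model.taps.items()}
    return MultiViewFeatures(h1=pooled["h1"], h2=pooled["h2"], h3=pooled["h3"], g=pooled["g"])


def extract_multiview_batch(model: HARnet, images, batch_size=16):
    """Vectorized multi-view extraction for a list of images."""
    feats = {k: [] for k in TAP_ORDER}
    with inference_mode():
        for i in range(0, len(images), batch_size):
            model.forward(_as_batch(images[i : i + batch_size]), train=False)
            for k in ("h1", "h2", "h3"):
                feats[k].append(model.taps[k].mean(axis=(2, 3)))
            feats["g"].append(model.taps["g"])
    return {k: np.concatenate(v) for k, v in feats.items()}


def _state_arrays(model: HARnet):
    """Parameters plus batch-norm running statistics, in traversal order."""
    arrays = [p.data for p in model.params()]

    def bn_buffers(mod):
        out = []
        for v in mod.__dict__.values():
            if isinstance(v, BatchNorm2d):
                out += [v]
            elif isinstance(v, Module):
                out += bn_buffers(v)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out += bn_buffers(item)
        return out

    for bn in bn_buffers(model):
        arrays += [bn.running_mean, bn.running_var]
    return arrays, bn_buffers(model)


def save_checkpoint(model: HARnet, out_dir):
    """Write the architecture YAML and all weights/buffers to a directory."""
    import yaml
    from dataclasses import asdict
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.cfg)
    cfg["stage_widths"] = list(cfg["stage_widths"])
    cfg["stage_units"] = list(cfg["stage_units"])
    (out / "arch.yaml").write_text(yaml.safe_dump(cfg))
    arrays, _ = _state_arrays(model)
    np.savez(out / "weights.npz", **{f"a{i}": a for i, a in enumerate(arrays)})
    return out


def load_checkpoint(ckpt_dir) -> HARnet:
    """Rebuild a HARnet from :func:`save_checkpoint` output."""
    import yaml
    from pathlib import Path

    ckpt = Path(ckpt_dir)
    cfg = yaml.safe_load((ckpt / "arch.yaml").read_text())
    cfg["stage_widths"] = tuple(cfg["stage_widths"])
    cfg["stage_units"] = tuple(cfg["stage_units"])
    model = build_harnet(HarnetConfig(**cfg))
    data = np.load(ckpt / "weights.npz")
    arrays, bns = _state_arrays(model)
    if len(data.files) != len(arrays):
        raise ValueError("checkpoint does not match architecture")
    params = model.params()
    for i, p in enumerate(params):
        p.data[...] = data[f"a{i}"]
    off = len(params)
    for j, bn in enumerate(bns):
        bn.running_mean[...] = data[f"a{off + 2 * j}"]
        bn.running_var[...] = data[f"a{off + 2 * j + 1}"]
    return model


def save_attention_maps(model: HARnet, image, out_dir):
    """Dump channel-mean heat maps of the three attention taps as PNGs."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    extract_multiview(model, image)
    paths = []
    for k in ("h1", "h2", "h3"):
        m = model.taps[k].mean(axis=1)[0]
        rng_ = m.max() - m.min()
        m8 = np.zeros_like(m, dtype=np.uint8) if rng_ <= 0 else (
            (m - m.min()) / rng_ * 255
        ).astype(np.uint8)
        p = out / f"attention_{k}.png"
        iio.imwrite(p, m8)
        paths.append(p)
    return paths
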