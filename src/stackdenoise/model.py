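"""Frame-attention transformer U-net for image-stack restoration.

The network operates on ``[B, C, F, H, W]`` tensors.  Its building block is
a transformer-style cell whose key/query/value maps are 2D convolutions
applied independently to every frame, with soft attention computed *between
frames*: per head, scores pool over channels and pixels to an F x F matrix
(mode ``"pooled"``, the default, linear in pixel count) or are kept per
pixel (mode ``"pixelwise"``).  Cells use pre-norm residual sublayers with
instance normalization and a two-conv GELU mixer.

The U-net runs ``n_down_levels`` encoder stages (cells then a stride-2
channel-doubling conv) and the mirror-image decoder stages (nearest x2
upsample + conv, skip concatenation, merge conv, cells), wrapped in a
pre-conv / post-conv pair and a long additive skip from input to output.
The post-conv is zero-initialized so an untrained network is the identity.

No positional encoding is used across frames, so the whole network is
equivariant to frame permutations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _autodiff as ad
from ._autodiff import Var
from .errors import ConfigError, NumericError

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_model",
    "parameter_count",
    "param_shapes",
    "conv_project_kqv",
    "frame_attention",
    "cell_forward",
    "forward",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    base_channels: int = 32
    n_down_levels: int = 2
    cells_per_level: int = 4
    n_heads: int = 4
    proj_kernel: int = 3
    mixer_kernel: int = 3
    mixer_expansion: int = 2
    attention_mode: str = "pooled"
    norm: str = "instance"
    activation: str = "gelu"

    def validate(self) -> None:
        if self.in_channels < 1 or self.base_channels < 1:
            raise ConfigError("in_channels and base_channels must be >= 1")
        if self.n_down_levels < 1 or self.cells_per_level < 1:
            raise ConfigError("n_down_levels and cells_per_level must be >= 1")
        if self.base_channels % self.n_heads != 0:
            raise ConfigError(
                f"base_channels ({self.base_channels}) must be divisible by n_heads ({self.n_heads})"
            )
        for k in (self.proj_kernel, self.mixer_kernel):
            if k < 1 or k % 2 == 0:
                raise ConfigError(f"kernels must be odd and >= 1, got {k}")
        if self.mixer_expansion < 1:
            raise ConfigError("mixer_expansion must be >= 1")
        if self.attention_mode not in ("pooled", "pixelwise"):
            raise ConfigError(f"unknown attention_mode {self.attention_mode!r}")
        if self.norm != "instance" or self.activation != "gelu":
            raise ConfigError("only instance norm and gelu activation are supported")

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        cfg = cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})
        cfg.validate()
        return cfg


@dataclass
class ModelParams:
    """All learned tensors, keyed by layer path, plus the shaping config."""

    config: ModelConfig
    tensors: dict[str, np.ndarray] = field(default_factory=dict)

    def validate_shapes(self) -> None:
        expected = param_shapes(self.config)
        if set(expected) != set(self.tensors):
            missing = set(expected) - set(self.tensors)
            extra = set(self.tensors) - set(expected)
            raise ConfigError(f"parameter set mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
        for name, shape in expected.items():
            t = self.tensors[name]
            if t.shape != shape:
                raise ConfigError(f"parameter {name}: shape {t.shape} != expected {shape}")
            if not np.all(np.isfinite(t)):
                raise NumericError(f"parameter {name} contains non-finite values")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tensors):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.tensors[name]).tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# parameter bookkeeping


def _cell_shapes(shapes: dict, prefix: str, c: int, cfg: ModelConfig) -> None:
    k, mk, e = cfg.proj_kernel, cfg.mixer_kernel, cfg.mixer_expansion
    shapes[f"{prefix}.proj.w"] = (c, c, k, k)
    shapes[f"{prefix}.proj.b"] = (c,)
    for name in ("k", "q", "v", "attn_out"):
        shapes[f"{prefix}.{name}.w"] = (c, c, k, k)
        shapes[f"{prefix}.{name}.b"] = (c,)
    for n in ("norm1", "norm2"):
        shapes[f"{prefix}.{n}.g"] = (c,)
        shapes[f"{prefix}.{n}.b"] = (c,)
    shapes[f"{prefix}.mix1.w"] = (e * c, c, mk, mk)
    shapes[f"{prefix}.mix1.b"] = (e * c,)
    shapes[f"{prefix}.mix2.w"] = (c, e * c, mk, mk)
    shapes[f"{prefix}.mix2.b"] = (c,)


def param_shapes(cfg: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Declared shape of every learnable tensor, keyed by layer path."""
    cfg.validate()
    k = cfg.proj_kernel
    c_in, base, levels = cfg.in_channels, cfg.base_channels, cfg.n_down_levels
    shapes: dict[str, tuple[int, ...]] = {}
    shapes["pre.w"] = (base, c_in, k, k)
    shapes["pre.b"] = (base,)
    for lvl in range(levels):
        c = base * 2**lvl
        for i in range(cfg.cells_per_level):
            _cell_shapes(shapes, f"down{lvl}.cell{i}", c, cfg)
        shapes[f"down{lvl}.pool.w"] = (2 * c, c, k, k)
        shapes[f"down{lvl}.pool.b"] = (2 * c,)
    cur = base * 2**levels
    for j in range(levels):
        out = cur // 2
        shapes[f"up{j}.up.w"] = (out, cur, k, k)
        shapes[f"up{j}.up.b"] = (out,)
        shapes[f"up{j}.merge.w"] = (out, 2 * out, k, k)
        shapes[f"up{j}.merge.b"] = (out,)
        for i in range(cfg.cells_per_level):
            _cell_shapes(shapes, f"up{j}.cell{i}", out, cfg)
        cur = out
    shapes["post.w"] = (c_in, base, k, k)
    shapes["post.b"] = (c_in,)
    return shapes


def parameter_count(cfg: ModelConfig) -> int:
    """Total learnable scalar count, deterministic in the config."""
    return int(sum(int(np.prod(s)) for s in param_shapes(cfg).values()))


def init_model(cfg: ModelConfig, seed: int) -> ModelParams:
    """Deterministic fan-in-scaled normal init; the post-conv is
    zero-initialized so forward(x) == x through the long skip at start."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    tensors: dict[str, np.ndarray] = {}
    for name, shape in param_shapes(cfg).items():
        if name.endswith(".g"):
            tensors[name] = np.ones(shape)
        elif name.endswith(".b"):
            tensors[name] = np.zeros(shape)
        elif name.startswith("post."):
            tensors[name] = np.zeros(shape)
        else:
            fan_in = int(np.prod(shape[1:]))
            tensors[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return ModelParams(config=cfg, tensors=tensors)


# ---------------------------------------------------------------------------
# forward pieces (Var level)


def _wrap(params: ModelParams, trainable: bool) -> dict[str, Var]:
    mk = ad.leaf if trainable else ad.const
    return {name: mk(t) for name, t in params.tensors.items()}


def _conv5(x: Var, pv: Mapping[str, Var], name: str, stride: int = 1) -> Var:
    """Apply a 2D conv identically to every frame of [B, C, F, H, W]."""
    b, c, f, h, w = x.shape
    x4 = ad.reshape(ad.transpose(x, (0, 2, 1, 3, 4)), (b * f, c, h, w))
    y4 = ad.conv2d(x4, pv[f"{name}.w"], pv[f"{name}.b"], stride=stride)
    _, co, ho, wo = y4.shape
    return ad.transpose(ad.reshape(y4, (b, f, co, ho, wo)), (0, 2, 1, 3, 4))


def _frame_attention_var(
    k: Var, q: Var, v: Var, n_heads: int, mode: str, score_sink: list | None = None
) -> Var:
    b, c, f, h, w = k.shape
    if c % n_heads != 0:
        raise ConfigError(f"channels ({c}) not divisible by n_heads ({n_heads})")
    dh = c // n_heads
    hw = h * w

    def split(t: Var, pool: bool) -> Var:
        t = ad.reshape(t, (b, n_heads, dh, f, hw))
        if pool:
            # [B, nh, F, dh*HW]
            return ad.reshape(ad.transpose(t, (0, 1, 3, 2, 4)), (b, n_heads, f, dh * hw))
        # [B, nh, HW, F, dh]
        return ad.transpose(t, (0, 1, 4, 3, 2))

    if mode == "pooled":
        qs, ks, vs = split(q, True), split(k, True), split(v, True)
        scale = 1.0 / np.sqrt(dh * hw)
        scores = ad.mul(ad.matmul(qs, ad.transpose(ks, (0, 1, 3, 2))), scale)  # [B,nh,F,F]
        attn = ad.softmax(scores)
        if score_sink is not None:
            score_sink.append(attn)
        out = ad.matmul(attn, vs)  # [B, nh, F, dh*HW]
        out = ad.transpose(ad.reshape(out, (b, n_heads, f, dh, hw)), (0, 1, 3, 2, 4))
        return ad.reshape(out, (b, c, f, h, w))
    elif mode == "pixelwise":
        qs, ks, vs = split(q, False), split(k, False), split(v, False)
        scale = 1.0 / np.sqrt(dh)
        scores = ad.mul(ad.matmul(qs, ad.transpose(ks, (0, 1, 2, 4, 3))), scale)  # [B,nh,HW,F,F]
        attn = ad.softmax(scores)
        if score_sink is not None:
            score_sink.append(attn)
        out = ad.matmul(attn, vs)  # [B, nh, HW, F, dh]
        out = ad.transpose(out, (0, 1, 4, 3, 2))  # [B, nh, dh, F, HW]
        return ad.reshape(out, (b, c, f, h, w))
    raise ConfigError(f"unknown attention mode {mode!r}")


def _cell_var(
    x: Var, pv: Mapping[str, Var], prefix: str, cfg: ModelConfig, score_sink: list | None = None,
    norm_stats: Mapping | None = None, norm_sink: dict | None = None,
) -> Var:
    def norm(t: Var, name: str) -> Var:
        stats = norm_stats.get(name) if norm_stats is not None else None
        sink = norm_sink.setdefault(name, []) if norm_sink is not None else None
        return ad.instance_norm(t, pv[f"{name}.g"], pv[f"{name}.b"], stats=stats, sink=sink)

    p = _conv5(x, pv, f"{prefix}.proj")
    a = norm(p, f"{prefix}.norm1")
    kk = _conv5(a, pv, f"{prefix}.k")
    qq = _conv5(a, pv, f"{prefix}.q")
    vv = _conv5(a, pv, f"{prefix}.v")
    att = _frame_attention_var(kk, qq, vv, cfg.n_heads, cfg.attention_mode, score_sink)
    att = _conv5(att, pv, f"{prefix}.attn_out")
    y = ad.add(p, att)
    n2 = norm(y, f"{prefix}.norm2")
    hmix = _conv5(n2, pv, f"{prefix}.mix1")
    hmix = ad.gelu(hmix)
    hmix = _conv5(hmix, pv, f"{prefix}.mix2")
    return ad.add(y, hmix)


def _upsample5(x: Var) -> Var:
    b, c, f, h, w = x.shape
    x4 = ad.reshape(ad.transpose(x, (0, 2, 1, 3, 4)), (b * f, c, h, w))
    y4 = ad.upsample2x(x4)
    return ad.transpose(ad.reshape(y4, (b, f, c, 2 * h, 2 * w)), (0, 2, 1, 3, 4))


def _unet_var(x: Var, pv: Mapping[str, Var], cfg: ModelConfig, score_sink: list | None = None,
              norm_stats: Mapping | None = None, norm_sink: dict | None = None) -> Var:
    b, c, f, h, w = x.shape
    if c != cfg.in_channels:
        raise ConfigError(f"input has {c} channels, model expects {cfg.in_channels}")
    m = 2**cfg.n_down_levels
    ph, pw = (-h) % m, (-w) % m
    t = ad.pad_end_reflect_hw(x, ph, pw)
    t = _conv5(t, pv, "pre")
    skips: list[Var] = []
    for lvl in range(cfg.n_down_levels):
        for i in range(cfg.cells_per_level):
            t = _cell_var(t, pv, f"down{lvl}.cell{i}", cfg, score_sink, norm_stats, norm_sink)
        skips.append(t)
        t = _conv5(t, pv, f"down{lvl}.pool", stride=2)
    for j in range(cfg.n_down_levels):
        t = _upsample5(t)
        t = _conv5(t, pv, f"up{j}.up")
        t = ad.concat([t, skips[cfg.n_down_levels - 1 - j]], axis=1)
        t = _conv5(t, pv, f"up{j}.merge")
        for i in range(cfg.cells_per_level):
            t = _cell_var(t, pv, f"up{j}.cell{i}", cfg, score_sink, norm_stats, norm_sink)
    t = _conv5(t, pv, "post")
    if ph or pw:
        t = ad.crop_hw(t, h, w)
    return ad.add(t, x)


def forward_var(
    params: ModelParams, x: Var, trainable_pv: Mapping[str, Var] | None = None,
    score_sink: list | None = None, norm_stats: Mapping | None = None,
    norm_sink: dict | None = None,
) -> Var:
    """Var-level forward pass; used directly by the training loop."""
    pv = trainable_pv if trainable_pv is not None else _wrap(params, trainable=False)
    return _unet_var(x, pv, params.config, score_sink, norm_stats, norm_sink)


# ---------------------------------------------------------------------------
# public array-level API


def forward(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """Run the U-net on ``x[B, C, F, H, W]``; output shape equals input shape."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 5:
        raise ConfigError(f"expected [B,C,F,H,W] input, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise NumericError("non-finite values in network input")
    return forward_var(params, ad.const(x)).data


def conv_project_kqv(x: np.ndarray, cell_tensors: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame convolutional K/Q/V projections of ``x[B, C, F, H, W]``.

    ``cell_tensors`` holds ``k.w/k.b/q.w/q.b/v.w/v.b``.  No cross-frame
    mixing happens here; channel count is preserved.
    """
    xv = ad.const(np.asarray(x, dtype=np.float64))
    pv = {name: ad.const(t) for name, t in cell_tensors.items()}
    outs = []
    for name in ("k", "q", "v"):
        outs.append(_conv5(xv, pv, name).data)
    return tuple(outs)


def frame_attention(
    k: np.ndarray, q: np.ndarray, v: np.ndarray, n_heads: int, mode: str = "pooled",
    return_scores: bool = False,
):
    """Multi-head soft attention across frames (before output projection).

    Scores per head are F x F in ``pooled`` mode (summed over channels and
    pixels, scaled by 1/sqrt(d_h * H * W)) and F x F *per pixel* in
    ``pixelwise`` mode.  Softmax rows sum to 1.
    """
    kv, qv, vv = (ad.const(np.asarray(t, dtype=np.float64)) for t in (k, q, v))
    if not (kv.shape == qv.shape == vv.shape):
        raise ConfigError("K, Q, V must share one shape")
    sink: list = []
    out = _frame_attention_var(kv, qv, vv, n_heads, mode, sink).data
    if return_scores:
        return out, sink[0].data
    return out


def cell_forward(x: np.ndarray, cell_tensors: Mapping[str, np.ndarray], cfg: ModelConfig) -> np.ndarray:
    """One transformer cell: input projection, pre-norm attention sublayer,
    pre-norm convolutional mixer sublayer, residuals around both."""
    xv = ad.const(np.asarray(x, dtype=np.float64))
    pv = {name: ad.const(t) for name, t in cell_tensors.items()}
    pv = {f"cell.{name}": t for name, t in pv.items()}
    return _cell_var(xv, pv, "cell", cfg).data


def extract_cell_tensors(params: ModelParams, prefix: str) -> dict[str, np.ndarray]:
    """Pull one cell's tensors out of a full parameter set, unprefixed."""
    plen = len(prefix) + 1
    return {name[plen:]: t for name, t in params.tensors.items() if name.startswith(prefix + ".")}
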