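"""Two-stage training (backbone pretraining + few-pair fine-tuning) and
tiled inference.

The loss is ``w_mse * MSE + w_ssim * (1 - SSIM3D)`` on normalized patches;
optimization is Adam with global gradient-norm clipping.  Randomness is
fully derived from one master seed: the patch batch of (epoch e, step s)
is drawn from ``default_rng([seed, e, s])``, so adding epochs never shifts
earlier batches.  Validation is full-stack tiled inference (not patches)
so the history tracks deployment behavior.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from . import metrics as me
from .errors import ConfigError, NumericError
from .io import ImageStack, Manifest, StackPair, normalize_pair, normalize_stack
from .model import ModelConfig, ModelParams, forward_var, init_model

logger = logging.getLogger("stackdenoise")

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "TilingSpec",
    "sample_patches",
    "loss",
    "train_backbone",
    "finetune",
    "infer",
    "save_checkpoint",
    "load_checkpoint",
    "load_checkpoint_info",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    steps_per_epoch: int = 20
    batch_size: int = 2
    patch_shape: tuple[int, int, int] = (8, 128, 128)
    learning_rate: float = 1e-4
    lr_finetune: float = 2.5e-5
    loss_weights: tuple[float, float] = (1.0, 0.1)  # (mse, ssim)
    grad_clip: float = 1.0
    ssim_window: int = 11
    seed: int = 0
    compute_dtype: str = "float32"  # training-step precision; weights stored float64

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.steps_per_epoch < 1 or self.batch_size < 1:
            raise ConfigError("steps_per_epoch and batch_size must be >= 1")
        fp, hp, wp = self.patch_shape
        if fp < 1 or hp < 8 or wp < 8:
            raise ConfigError(f"patch_shape must be >= (1, 8, 8), got {self.patch_shape}")
        w_mse, w_ssim = self.loss_weights
        if w_mse < 0 or w_ssim < 0 or (w_mse == 0 and w_ssim == 0):
            raise ConfigError("loss weights must be >= 0 and not both zero")

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["patch_shape"] = list(self.patch_shape)
        d["loss_weights"] = list(self.loss_weights)
        return d

    @classmethod
    def from_dict(cls, d) -> "TrainConfig":
        kw = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        if "patch_shape" in kw:
            kw["patch_shape"] = tuple(kw["patch_shape"])
        if "loss_weights" in kw:
            kw["loss_weights"] = tuple(kw["loss_weights"])
        cfg = cls(**kw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class TilingSpec:
    """Spatial tiling for inference; frames are chunked without overlap."""

    tile: tuple[int, int, int] = (8, 64, 64)
    overlap: int = 8
    blend: str = "feather"

    def validate(self) -> None:
        ft, ht, wt = self.tile
        if ft < 1 or ht < 8 or wt < 8:
            raise ConfigError(f"tile must be >= (1, 8, 8), got {self.tile}")
        if self.overlap < 0 or 2 * self.overlap >= min(ht, wt):
            raise ConfigError(f"overlap must satisfy 0 <= 2*overlap < min tile side, got {self.overlap}")
        if self.blend != "feather":
            raise ConfigError("only feather blending is supported")


@dataclass
class Checkpoint:
    params: ModelParams
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    stage: str = "backbone"
    parent_id: str | None = None

    def __post_init__(self):
        if self.stage not in ("backbone", "finetuned"):
            raise ConfigError(f"stage must be 'backbone' or 'finetuned', got {self.stage!r}")
        if self.stage == "finetuned" and not self.parent_id:
            raise ConfigError("finetuned checkpoints must carry a parent_id")


# ---------------------------------------------------------------------------
# data plumbing


def _patch_positions(rng: np.random.Generator, stack_shape, patch_shape, n: int) -> list[tuple[int, int, int]]:
    _, f, h, w = stack_shape
    fp, hp, wp = patch_shape
    fp = min(fp, f)
    if hp > h or wp > w:
        raise ConfigError(f"patch {patch_shape} larger than stack frames {(f, h, w)}")
    return [
        (
            int(rng.integers(0, f - fp + 1)),
            int(rng.integers(0, h - hp + 1)),
            int(rng.integers(0, w - wp + 1)),
        )
        for _ in range(n)
    ]


def sample_patches(pair: StackPair, patch_shape, n: int, seed,
                   return_positions: bool = False):
    """n random co-located patch pairs from a normalized pair.

    Both members are normalized with the LOW member's statistics first and
    cropped at identical positions.  Deterministic in ``seed``.
    """
    norm, _ = normalize_pair(pair)
    rng = np.random.default_rng(seed)
    fp, hp, wp = patch_shape
    fp = min(fp, norm.low.shape[1])
    positions = _patch_positions(rng, norm.low.shape, patch_shape, n)
    out = []
    for f0, h0, w0 in positions:
        sl = (slice(None), slice(f0, f0 + fp), slice(h0, h0 + hp), slice(w0, w0 + wp))
        out.append((norm.low.voxels[sl], norm.high.voxels[sl]))
    if return_positions:
        return out, positions
    return out


def loss(pred, target, weights=(1.0, 0.1), ssim_window: int = 11):
    """Weighted MSE + (1 - SSIM3D) on [B, C, F, H, W] arrays or Vars."""
    pv = pred if isinstance(pred, ad.Var) else ad.const(np.asarray(pred, dtype=np.float64))
    tv = target if isinstance(target, ad.Var) else ad.const(np.asarray(target, dtype=np.float64))
    if pv.shape != tv.shape:
        raise ValueError(f"loss shape mismatch: {pv.shape} vs {tv.shape}")
    w_mse, w_ssim = weights
    diff = ad.sub(pv, tv)
    total = ad.mul(ad.vmean(ad.mul(diff, diff)), w_mse)
    if w_ssim > 0:
        ssim = me.ssim3d_var(pv, tv, window=ssim_window)
        total = ad.add(total, ad.mul(ad.sub(ad.const(1.0), ssim), w_ssim))
    if isinstance(pred, ad.Var):
        return total
    return float(total.data)


# ---------------------------------------------------------------------------
# optimizer


class _Adam:
    def __init__(self, names, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {n: 0.0 for n in names}
        self.v = {n: 0.0 for n in names}
        self.t = 0

    def step(self, tensors: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for n, g in grads.items():
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            tensors[n] -= self.lr * (self.m[n] / b1t) / (np.sqrt(self.v[n] / b2t) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for n in grads:
            grads[n] *= scale


# ---------------------------------------------------------------------------
# training loops


def _load_pairs(manifest: Manifest, split: str) -> list[StackPair]:
    return [manifest.load_pair(e) for e in manifest.split(split)]


def _validate_model(params: ModelParams, val_pairs, cfg: TrainConfig, tiling) -> tuple[float, float]:
    """Full-stack tiled-inference validation: (mean loss, mean PSNR)."""
    if not val_pairs:
        return float("nan"), float("nan")
    ckpt = Checkpoint(params=params, train_config=cfg)
    losses, psnrs = [], []
    for pair in val_pairs:
        out = infer(ckpt, pair.low, tiling)
        norm, nparams = normalize_pair(pair)
        out_n, _ = normalize_stack(out, params=nparams)
        losses.append(loss(out_n.voxels[np.newaxis], norm.high.voxels[np.newaxis],
                           cfg.loss_weights, cfg.ssim_window))
        psnrs.append(me.psnr(out_n, norm.high))
    return float(np.mean(losses)), float(np.mean(psnrs))


def zero_shot_val_loss(checkpoint: Checkpoint, manifest: Manifest, split: str = "val",
                       tiling: TilingSpec | None = None) -> float:
    """Validation loss of a checkpoint applied as-is to a (new) dataset."""
    pairs = _load_pairs(manifest, split)
    if not pairs:
        raise ConfigError(f"manifest has no {split!r} entries")
    val_loss, _ = _validate_model(checkpoint.params, pairs, checkpoint.train_config, tiling)
    return val_loss


def _train_loop(params: ModelParams, manifest: Manifest, cfg: TrainConfig, lr: float,
                stage: str, parent_id: str | None, tiling: TilingSpec | None) -> Checkpoint:
    cfg.validate()
    train_pairs = _load_pairs(manifest, "train")
    if not train_pairs:
        raise ConfigError("manifest has no train entries")
    val_pairs = _load_pairs(manifest, "val")
    # normalize once; training samples crops from cached normalized stacks
    norm_pairs = [normalize_pair(p)[0] for p in train_pairs]
    dtype = np.dtype(cfg.compute_dtype)
    work = {n: t.astype(dtype) for n, t in params.tensors.items()}
    opt = _Adam(work.keys(), lr)
    history: list[dict] = []
    fp, hp, wp = cfg.patch_shape
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for step in range(cfg.steps_per_epoch):
            rng = np.random.default_rng([cfg.seed, epoch, step])
            lows, highs = [], []
            fp_eff = min(fp, min(p.low.shape[1] for p in norm_pairs))
            for _ in range(cfg.batch_size):
                pair = norm_pairs[int(rng.integers(0, len(norm_pairs)))]
                (f0, h0, w0), = _patch_positions(rng, pair.low.shape, (fp_eff, hp, wp), 1)
                sl = (slice(None), slice(f0, f0 + fp_eff), slice(h0, h0 + hp), slice(w0, w0 + wp))
                lows.append(pair.low.voxels[sl])
                highs.append(pair.high.voxels[sl])
            xb = np.stack(lows).astype(dtype)
            yb = np.stack(highs).astype(dtype)
            pv = {n: ad.leaf(t) for n, t in work.items()}
            pred = forward_var(params, ad.const(xb), trainable_pv=pv)
            lval = loss(pred, ad.const(yb), cfg.loss_weights, cfg.ssim_window)
            if not np.isfinite(lval.data):
                raise NumericError(
                    f"non-finite loss at epoch {epoch} step {step} (batch seed [{cfg.seed},{epoch},{step}])"
                )
            ad.backward(lval)
            grads = {n: pv[n].grad for n in work if pv[n].grad is not None}
            _clip_grads(grads, cfg.grad_clip)
            opt.step(work, grads)
            epoch_losses.append(float(lval.data))
        params.tensors = {n: t.astype(np.float64) for n, t in work.items()}
        val_loss, val_psnr = _validate_model(params, val_pairs, cfg, tiling)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_psnr": val_psnr,
        }
        history.append(row)
        logger.info("%s epoch %d: train_loss=%.5g val_loss=%.5g val_psnr=%.3f",
                    stage, epoch, row["train_loss"], val_loss, val_psnr)
    return Checkpoint(params=params, train_config=cfg, history=history, stage=stage,
                      parent_id=parent_id)


def train_backbone(manifest: Manifest, model_config: ModelConfig, train_config: TrainConfig,
                   tiling: TilingSpec | None = None) -> Checkpoint:
    """Stage 1: train from scratch on pooled data; deterministic in seed."""
    model_config.validate()
    params = init_model(model_config, train_config.seed)
    return _train_loop(params, manifest, train_config, train_config.learning_rate,
                       "backbone", None, tiling)


def finetune(backbone: Checkpoint, manifest: Manifest, train_config: TrainConfig,
             tiling: TilingSpec | None = None) -> Checkpoint:
    """Stage 2: adapt all backbone weights (nothing frozen) at a reduced
    learning rate on a few new pairs."""
    train_config.validate()
    parent = backbone.params.content_hash()
    params = ModelParams(
        config=backbone.params.config,
        tensors={n: t.copy() for n, t in backbone.params.tensors.items()},
    )
    return _train_loop(params, manifest, train_config, train_config.lr_finetune,
                       "finetuned", parent, tiling)


# ---------------------------------------------------------------------------
# inference


def _feather_profile(length: int, overlap: int, has_prev: bool, has_next: bool) -> np.ndarray:
    w = np.ones(length)
    if overlap > 0:
        ramp = (np.arange(1, overlap + 1)) / (overlap + 1)
        if has_prev:
            w[:overlap] = ramp
        if has_next:
            w[-overlap:] = ramp[::-1]
    return w


def _tile_starts(size: int, tile: int, overlap: int) -> list[int]:
    if tile >= size:
        return [0]
    step = tile - overlap
    starts = list(range(0, size - tile, step))
    starts.append(size - tile)
    return sorted(set(starts))


def infer(checkpoint: Checkpoint, stack: ImageStack, tiling: TilingSpec | None = None) -> ImageStack:
    """Normalize by the input's own statistics, run the network tile by
    tile with feather blending, and denormalize back.

    Multi-channel stacks are processed channel-by-channel when the model
    was built for a single channel.
    """
    params = checkpoint.params
    cfg = params.config
    c = stack.shape[0]
    if c != cfg.in_channels:
        if cfg.in_channels == 1:
            chans = []
            for ci in range(c):
                sub = ImageStack(voxels=stack.voxels[ci : ci + 1], axis_label=stack.axis_label,
                                 dtype_origin=stack.dtype_origin)
                chans.append(infer(checkpoint, sub, tiling).voxels[0])
            return ImageStack(voxels=np.stack(chans), axis_label=stack.axis_label,
                              dtype_origin=stack.dtype_origin)
        raise ConfigError(f"stack has {c} channels but model expects {cfg.in_channels}")

    from .io import denormalize_stack  # local to avoid import noise at top

    norm, nparams = normalize_stack(stack, clip=False)
    dtype = np.dtype(checkpoint.train_config.compute_dtype)
    v = norm.voxels.astype(dtype)  # [C, F, H, W]
    fwd_tensors = {n: t.astype(dtype) for n, t in params.tensors.items()}
    fwd_pv = {n: ad.const(t) for n, t in fwd_tensors.items()}
    _, f, h, w = v.shape
    if tiling is None:
        tiling = TilingSpec(tile=(f, h, w), overlap=0)
    tiling.validate()
    ft, ht, wt = tiling.tile
    ft, ht, wt = min(ft, f), min(ht, h), min(wt, w)
    ov = tiling.overlap if (ht < h or wt < w) else 0

    out = np.zeros_like(v)
    weight = np.zeros((h, w))
    f_starts = _tile_starts(f, ft, 0)
    h_starts = _tile_starts(h, ht, ov)
    w_starts = _tile_starts(w, wt, ov)
    n_tiles = len(f_starts) * len(h_starts) * len(w_starts)

    def tiles():
        for f0 in f_starts:
            for h0 in h_starts:
                for w0 in w_starts:
                    yield f0, h0, w0, np.ascontiguousarray(
                        v[np.newaxis, :, f0 : f0 + ft, h0 : h0 + ht, w0 : w0 + wt]
                    )

    norm_stats = None
    if n_tiles > 1:
        # calibration pass: aggregate every norm layer's moments over all
        # tiles so the second pass normalizes with stack-wide statistics
        # (keeps tiled inference consistent with whole-stack inference)
        agg: dict[str, list] = {}
        for _, _, _, tile in tiles():
            sink: dict = {}
            forward_var(params, ad.const(tile), trainable_pv=fwd_pv, norm_sink=sink)
            for name, entries in sink.items():
                for mu, var, count in entries:
                    mu = mu.reshape(-1)
                    var = var.reshape(-1)
                    s = agg.setdefault(name, [0.0, 0.0, 0.0])
                    s[0] += count
                    s[1] += count * mu
                    s[2] += count * (var + mu**2)
        norm_stats = {}
        for name, (cnt, s1, s2) in agg.items():
            mu_g = s1 / cnt
            norm_stats[name] = (mu_g, np.maximum(s2 / cnt - mu_g**2, 0.0))

    # spatial blend weights are identical for every frame chunk
    for h0 in h_starts:
        for w0 in w_starts:
            wh = _feather_profile(ht, ov, h0 > 0, h0 + ht < h)
            ww = _feather_profile(wt, ov, w0 > 0, w0 + wt < w)
            weight[h0 : h0 + ht, w0 : w0 + wt] += np.outer(wh, ww)
    if not np.all(weight > 0):
        raise NumericError("tile blending left uncovered voxels")

    seam = 0.0
    for f0 in f_starts:
        acc = np.zeros((v.shape[0], ft, h, w))
        mn = np.full_like(acc, np.inf)
        mx = np.full_like(acc, -np.inf)
        for h0 in h_starts:
            for w0 in w_starts:
                tile = np.ascontiguousarray(
                    v[np.newaxis, :, f0 : f0 + ft, h0 : h0 + ht, w0 : w0 + wt]
                )
                pred = forward_var(params, ad.const(tile), trainable_pv=fwd_pv,
                                   norm_stats=norm_stats).data[0]
                wh = _feather_profile(ht, ov, h0 > 0, h0 + ht < h)
                ww = _feather_profile(wt, ov, w0 > 0, w0 + wt < w)
                sl = (slice(None), slice(None), slice(h0, h0 + ht), slice(w0, w0 + wt))
                acc[sl] += pred * np.outer(wh, ww)
                mn[sl] = np.minimum(mn[sl], pred)
                mx[sl] = np.maximum(mx[sl], pred)
        out[:, f0 : f0 + ft] = acc / weight
        seam = max(seam, float(np.max(mx - mn)))
    if n_tiles > 1:
        logger.info("tiled inference: %d tiles, max overlap discrepancy %.3g", n_tiles, seam)
    result = ImageStack(voxels=out, axis_label=stack.axis_label, dtype_origin=stack.dtype_origin)
    return denormalize_stack(result, nparams)


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Single-file archive: tensors + JSON meta (config, history, stage)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_config": ckpt.params.config.to_dict(),
        "train_config": ckpt.train_config.to_dict(),
        "history": ckpt.history,
        "stage": ckpt.stage,
        "parent_id": ckpt.parent_id,
    }
    arrays = {f"tensor/{n}": t for n, t in ckpt.params.tensors.items()}
    with open(path, "wb") as fh:  # file handle keeps the exact name (no .npz suffix)
        np.savez(fh, __meta__=np.array(json.dumps(meta)), **arrays)


def _read_meta(npz) -> dict:
    meta = json.loads(str(npz["__meta__"]))
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ConfigError(f"unsupported checkpoint format version {meta.get('format_version')}")
    return meta


def load_checkpoint_info(path) -> dict:
    """Config-only inspection without materializing the weight tensors."""
    with np.load(Path(path), allow_pickle=False) as npz:
        return _read_meta(npz)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        meta = _read_meta(npz)
        tensors = {k[len("tensor/"):]: np.asarray(npz[k], dtype=np.float64)
                   for k in npz.files if k.startswith("tensor/")}
    params = ModelParams(config=ModelConfig.from_dict(meta["model_config"]), tensors=tensors)
    params.validate_shapes()
    return Checkpoint(
        params=params,
        train_config=TrainConfig.from_dict(meta["train_config"]),
        history=meta["history"],
        stage=meta["stage"],
        parent_id=meta["parent_id"],
    )
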