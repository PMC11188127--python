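"""Image-quality metrics and evaluation harnesses.

PSNR follows the standard 10*log10(range^2 / MSE) definition with an
infinity sentinel at zero error.  SSIM3D is a volumetric structural
similarity index: a separable 3D Gaussian window (default 11 points,
sigma 1.5, truncated per axis to fit small volumes) slides over
(frame, H, W) with symmetric edge padding; k1=0.01, k2=0.03.

The SSIM core is written on the autodiff ops so the training loss can
differentiate through exactly the same formula this module reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from ._autodiff import Var
from .errors import ConfigError
from .io import ImageStack, Manifest, normalize_pair

__all__ = [
    "psnr",
    "ssim3d",
    "EvalReport",
    "RobustnessCurve",
    "evaluate_pairs",
    "robustness_curve",
    "finetune_vs_scratch",
]


def psnr(x, ref, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when x == ref exactly."""
    xa = x.voxels if isinstance(x, ImageStack) else np.asarray(x, dtype=np.float64)
    ra = ref.voxels if isinstance(ref, ImageStack) else np.asarray(ref, dtype=np.float64)
    if xa.shape != ra.shape:
        raise ValueError(f"psnr shape mismatch: {xa.shape} vs {ra.shape}")
    if data_range <= 0:
        raise ConfigError("data_range must be > 0")
    mse = float(np.mean((xa - ra) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def _gaussian_kernel(width: int, sigma: float) -> np.ndarray:
    r = np.arange(width) - (width - 1) / 2.0
    k = np.exp(-0.5 * (r / sigma) ** 2)
    return k / k.sum()


def _axis_window(requested: int, dim: int) -> int:
    """Largest odd width <= min(requested, dim)."""
    w = min(requested, dim)
    if w % 2 == 0:
        w -= 1
    return max(w, 1)


def _ssim3d_vol_var(x: Var, y: Var, window: int, sigma: float, k1: float, k2: float,
                    data_range: float) -> Var:
    """Mean SSIM over one [..., F, H, W] volume, autodiff-capable."""
    if window % 2 == 0:
        raise ConfigError(f"ssim3d window must be odd, got {window}")
    shape = x.shape
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def blur(t: Var) -> Var:
        for off, dim in zip(range(3), shape[-3:]):
            w = _axis_window(window, dim)
            if w > 1:
                t = ad.conv1d_fixed(t, _gaussian_kernel(w, sigma), axis=t.data.ndim - 3 + off)
        return t

    mu_x = blur(x)
    mu_y = blur(y)
    mu_xx = ad.mul(mu_x, mu_x)
    mu_yy = ad.mul(mu_y, mu_y)
    mu_xy = ad.mul(mu_x, mu_y)
    s_xx = ad.sub(blur(ad.mul(x, x)), mu_xx)
    s_yy = ad.sub(blur(ad.mul(y, y)), mu_yy)
    s_xy = ad.sub(blur(ad.mul(x, y)), mu_xy)
    num = ad.mul(ad.add(ad.mul(mu_xy, 2.0), c1), ad.add(ad.mul(s_xy, 2.0), c2))
    den = ad.mul(ad.add(ad.add(mu_xx, mu_yy), c1), ad.add(ad.add(s_xx, s_yy), c2))
    return ad.vmean(ad.div(num, den))


def ssim3d_var(x: Var, y: Var, window: int = 11, sigma: float = 1.5,
               k1: float = 0.01, k2: float = 0.03, data_range: float = 1.0) -> Var:
    """SSIM3D of batched volumes [..., F, H, W] as a differentiable node."""
    return _ssim3d_vol_var(x, y, window, sigma, k1, k2, data_range)


def ssim3d(x, ref, window: int = 11, sigma: float = 1.5, k1: float = 0.01,
           k2: float = 0.03, data_range: float = 1.0) -> float:
    """Volumetric structural similarity in [-1, 1]; 1.0 iff x == ref."""
    xa = x.voxels if isinstance(x, ImageStack) else np.asarray(x, dtype=np.float64)
    ra = ref.voxels if isinstance(ref, ImageStack) else np.asarray(ref, dtype=np.float64)
    if xa.shape != ra.shape:
        raise ValueError(f"ssim3d shape mismatch: {xa.shape} vs {ra.shape}")
    return float(ssim3d_var(ad.const(xa), ad.const(ra), window, sigma, k1, k2, data_range).data)


# ---------------------------------------------------------------------------
# evaluation harnesses


@dataclass
class EvalReport:
    per_pair: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    config_hash: str = ""
    seed: int | None = None

    _COLUMNS = ("psnr_input", "psnr_output", "ssim3d_input", "ssim3d_output")

    def finalize(self) -> "EvalReport":
        if not self.per_pair:
            raise ConfigError("EvalReport requires at least one pair")
        self.summary = {}
        for col in self._COLUMNS:
            vals = np.array([row[col] for row in self.per_pair], dtype=np.float64)
            self.summary[f"{col}_mean"] = float(vals.mean())
            self.summary[f"{col}_std"] = float(vals.std())
        return self

    def to_dict(self) -> dict:
        return {
            "per_pair": self.per_pair,
            "summary": self.summary,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }


@dataclass
class RobustnessCurve:
    points: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ns = [p["n_average"] for p in self.points]
        if ns != sorted(set(ns)):
            raise ConfigError("robustness curve n values must be strictly increasing")

    def to_dict(self) -> dict:
        return {"points": self.points}


def evaluate_pairs(checkpoint, manifest: Manifest, split: str = "test", tiling=None) -> EvalReport:
    """Run inference on each pair's low member and score input and output
    against the high member, on the normalized [0, 1] scale (low-member
    statistics, matching the training-time convention)."""
    from .train import infer  # local import: avoid a module cycle

    entries = manifest.split(split)
    if not entries:
        raise ConfigError(f"manifest has no entries in split {split!r}")
    report = EvalReport(config_hash=checkpoint.params.content_hash(), seed=checkpoint.train_config.seed)
    for entry in entries:
        pair = manifest.load_pair(entry)
        output = infer(checkpoint, pair.low, tiling)
        norm_pair, params = normalize_pair(pair)
        out_n, _ = _renormalize(output, params)
        row = {
            "pair_id": entry.pair_id,
            "psnr_input": psnr(norm_pair.low, norm_pair.high),
            "psnr_output": psnr(out_n, norm_pair.high),
            "ssim3d_input": ssim3d(norm_pair.low, norm_pair.high),
            "ssim3d_output": ssim3d(out_n, norm_pair.high),
        }
        report.per_pair.append(row)
    return report.finalize()


def _renormalize(stack: ImageStack, params):
    from .io import normalize_stack

    return normalize_stack(stack, params=params)


def robustness_curve(checkpoint, series, n_values: Sequence[int] = (1, 4, 8, 16, 32, 64)) -> RobustnessCurve:
    """Score the model across the running-average series.

    For each requested n the model is run on member n; input and output are
    scored against the true clean stack (``*_clean``) and against member N,
    the acquisition-style ground truth (``*_ref``).
    """
    from .train import infer

    n_total = len(series.members)
    points = []
    for n in n_values:
        if not 1 <= n <= n_total:
            raise ValueError(f"n_average {n} outside series 1..{n_total}")
        member = series.members[n - 1]
        output = infer(checkpoint, member, None)
        refs = {"clean": series.clean, "ref": series.members[-1]}
        row = {"n_average": int(n)}
        for tag, ref in refs.items():
            norm_ref, params = _series_norm(member, ref)
            norm_in, _ = _renormalize(member, params)
            norm_out, _ = _renormalize(output, params)
            row[f"psnr_in_{tag}"] = psnr(norm_in, norm_ref)
            row[f"psnr_out_{tag}"] = psnr(norm_out, norm_ref)
            row[f"ssim_in_{tag}"] = ssim3d(norm_in, norm_ref)
            row[f"ssim_out_{tag}"] = ssim3d(norm_out, norm_ref)
        points.append(row)
    return RobustnessCurve(points=points)


def _series_norm(member: ImageStack, ref: ImageStack):
    from .io import normalize_stack

    _, params = normalize_stack(member)
    norm_ref, _ = normalize_stack(ref, params=params)
    return norm_ref, params


def finetune_vs_scratch(backbone, manifest: Manifest, train_config, n_seeds: int = 3,
                        tiling=None, return_checkpoints: bool = False) -> dict:
    """Fine-tune-from-backbone vs identically budgeted from-scratch training.

    Runs both arms once per seed, evaluates each on the manifest's test
    split, and reports per-seed rows plus means for both arms.
    """
    import dataclasses

    from .train import finetune, train_backbone

    if n_seeds < 3:
        raise ConfigError("finetune_vs_scratch requires n_seeds >= 3")
    rows = []
    checkpoints: dict[str, list] = {"finetune": [], "scratch": []}
    for s in range(n_seeds):
        cfg_s = dataclasses.replace(train_config, seed=train_config.seed + 1000 * s)
        ft = finetune(backbone, manifest, cfg_s)
        scratch = train_backbone(manifest, backbone.params.config, cfg_s)
        checkpoints["finetune"].append(ft)
        checkpoints["scratch"].append(scratch)
        for arm, ckpt in (("finetune", ft), ("scratch", scratch)):
            rep = evaluate_pairs(ckpt, manifest, "test", tiling)
            rows.append(
                {
                    "seed": cfg_s.seed,
                    "arm": arm,
                    "psnr": rep.summary["psnr_output_mean"],
                    "ssim3d": rep.summary["ssim3d_output_mean"],
                }
            )
    table = {"per_seed": rows, "mean": {}}
    for arm in ("finetune", "scratch"):
        sel = [r for r in rows if r["arm"] == arm]
        table["mean"][arm] = {
            "psnr": float(np.mean([r["psnr"] for r in sel])),
            "ssim3d": float(np.mean([r["ssim3d"] for r in sel])),
        }
    if return_checkpoints:
        table["checkpoints"] = checkpoints
    return table
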