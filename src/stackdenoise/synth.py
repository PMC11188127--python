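"""Synthetic fluorescence-microscopy pair simulator.

Phantom structure families:

* ``filaments`` — smoothed random-walk curves rasterized with bilinear
  sub-pixel splatting, drifting slowly across frames;
* ``blobs`` — Gaussian spots with small per-frame jitter;
* ``tubes`` — branching curvilinear networks, constant across frames.

Frames are correlated on purpose (slow drift rather than independent
redraws) so cross-frame attention has coherent signal to exploit.

Noise model: Poisson shot noise at ``photon_level`` photons per unit
intensity plus additive Gaussian read noise, optionally averaged over
``n_average`` independent repeats — the standard photon-limited camera
model, also used to build running-average series (member n = mean of the
first n of N single-shot repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .io import ImageStack, Manifest, ManifestEntry, save_manifest, write_stack

__all__ = [
    "PhantomSpec",
    "NoiseParams",
    "AverageSeries",
    "make_clean_stack",
    "degrade",
    "make_pair_dataset",
    "make_average_series",
]

_KINDS = ("filaments", "blobs", "tubes")


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "filaments"
    shape: tuple[int, int, int] = (8, 64, 64)
    density: int = 10
    intensity_range: tuple[float, float] = (0.5, 1.0)
    psf_sigma: float = 1.0
    background: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"phantom kind must be one of {_KINDS}, got {self.kind!r}")
        f, h, w = self.shape
        if f < 1 or h < 1 or w < 1:
            raise ConfigError(f"zero-area phantom shape {self.shape}")
        lo, hi = self.intensity_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"intensity_range must satisfy 0 <= lo < hi <= 1, got {self.intensity_range}")
        if self.psf_sigma < 0:
            raise ConfigError("psf_sigma must be >= 0")
        if not (0.0 <= self.background < 1.0):
            raise ConfigError("background must lie in [0, 1)")
        if self.density < 1:
            raise ConfigError("density must be >= 1")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "shape": list(self.shape),
            "density": self.density,
            "intensity_range": list(self.intensity_range),
            "psf_sigma": self.psf_sigma,
            "background": self.background,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class NoiseParams:
    """photon_level: expected photons at unit intensity; read_sigma in
    photon units; n_average: independent repeats averaged together."""

    photon_level: float = 30.0
    read_sigma: float = 1.0
    n_average: int = 1

    def validate(self) -> None:
        if self.photon_level <= 0:
            raise ConfigError("photon_level must be > 0")
        if self.read_sigma < 0:
            raise ConfigError("read_sigma must be >= 0")
        if self.n_average < 1:
            raise ConfigError("n_average must be >= 1")

    def to_dict(self) -> dict:
        return {"photon_level": self.photon_level, "read_sigma": self.read_sigma,
                "n_average": self.n_average}


@dataclass
class AverageSeries:
    """Running-average series: ``members[n-1]`` is the mean of the first n
    of N single-shot repeats; member N doubles as the acquisition-style
    ground truth; ``clean`` is the noiseless oracle."""

    members: list[ImageStack]
    clean: ImageStack

    @property
    def ground_truth_index(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# phantom rasterization helpers


def _splat_points(canvas: np.ndarray, ys: np.ndarray, xs: np.ndarray, amp: float) -> None:
    """Accumulate bilinear (anti-aliased) point masses onto a 2D canvas."""
    h, w = canvas.shape
    ys = np.clip(ys, 0.0, h - 1.001)
    xs = np.clip(xs, 0.0, w - 1.001)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    np.add.at(canvas, (y0, x0), amp * (1 - fy) * (1 - fx))
    np.add.at(canvas, (y0 + 1, x0), amp * fy * (1 - fx))
    np.add.at(canvas, (y0, x0 + 1), amp * (1 - fy) * fx)
    np.add.at(canvas, (y0 + 1, x0 + 1), amp * fy * fx)


def _smooth_walk(rng: np.random.Generator, n_pts: int, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """A smoothed 2D random-walk polyline densely resampled to ~4 pts/px."""
    y = rng.uniform(0.15 * h, 0.85 * h)
    x = rng.uniform(0.15 * w, 0.85 * w)
    ang = rng.uniform(0, 2 * np.pi)
    step = 1.0
    ys, xs = [y], [x]
    for _ in range(n_pts):
        ang += rng.normal(0.0, 0.35)
        y = np.clip(y + step * np.sin(ang), 1.0, h - 2.0)
        x = np.clip(x + step * np.cos(ang), 1.0, w - 2.0)
        ys.append(y)
        xs.append(x)
    ys, xs = np.array(ys), np.array(xs)
    # moving-average smoothing then dense resampling for sub-pixel coverage
    kern = np.ones(5) / 5.0
    ys = np.convolve(ys, kern, mode="valid")
    xs = np.convolve(xs, kern, mode="valid")
    t = np.linspace(0, 1, len(ys))
    td = np.linspace(0, 1, 4 * n_pts)
    return np.interp(td, t, ys), np.interp(td, t, xs)


def _raster_filaments(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    f, h, w = spec.shape
    lo, hi = spec.intensity_range
    vol = np.zeros((f, h, w))
    for _ in range(spec.density):
        ys, xs = _smooth_walk(rng, max(h, w), h, w)
        amp = rng.uniform(lo, hi)
        # slow per-structure drift across frames
        vy, vx = rng.normal(0.0, 0.4, size=2)
        for fi in range(f):
            _splat_points(vol[fi], ys + vy * fi, xs + vx * fi, amp / 4.0)
    return vol


def _raster_blobs(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    f, h, w = spec.shape
    lo, hi = spec.intensity_range
    vol = np.zeros((f, h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.density):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        sig = rng.uniform(1.5, max(2.5, 0.04 * min(h, w)))
        amp = rng.uniform(lo, hi)
        for fi in range(f):
            jy = cy + rng.normal(0.0, 0.3)
            jx = cx + rng.normal(0.0, 0.3)
            vol[fi] += amp * np.exp(-((yy - jy) ** 2 + (xx - jx) ** 2) / (2 * sig**2))
    return vol


def _raster_tubes(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    f, h, w = spec.shape
    lo, hi = spec.intensity_range
    frame = np.zeros((h, w))
    for _ in range(spec.density):
        ys, xs = _smooth_walk(rng, max(h, w), h, w)
        amp = rng.uniform(lo, hi)
        _splat_points(frame, ys, xs, amp / 4.0)
        # spawn up to two branches off the trunk
        for _ in range(rng.integers(0, 3)):
            start = rng.integers(0, len(ys))
            bys, bxs = _smooth_walk(rng, max(h, w) // 2, h, w)
            bys = bys - bys[0] + ys[start]
            bxs = bxs - bxs[0] + xs[start]
            _splat_points(frame, np.clip(bys, 0, h - 1.001), np.clip(bxs, 0, w - 1.001), amp / 4.0)
    return np.broadcast_to(frame, (f, h, w)).copy()


def make_clean_stack(spec: PhantomSpec) -> ImageStack:
    """Deterministic-in-seed clean phantom: structures, PSF blur,
    constant background, clipped to [0, 1]."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    raster = {"filaments": _raster_filaments, "blobs": _raster_blobs, "tubes": _raster_tubes}
    vol = raster[spec.kind](spec, rng)
    if spec.psf_sigma > 0:
        for fi in range(vol.shape[0]):
            vol[fi] = gaussian_filter(vol[fi], spec.psf_sigma)
    vol = np.clip(vol + spec.background, 0.0, 1.0)
    return ImageStack(voxels=vol[np.newaxis], axis_label="Z", dtype_origin="float32")


# ---------------------------------------------------------------------------
# noise


def degrade(clean: ImageStack, noise: NoiseParams, seed) -> ImageStack:
    """Poisson(alpha * clean) + N(0, read_sigma^2) per voxel, averaged over
    ``n_average`` independent repeats, returned on the [~0, 1] scale."""
    noise.validate()
    v = clean.voxels
    if v.min() < 0.0 or v.max() > 1.0:
        raise ConfigError("degrade expects a clean stack in [0, 1]")
    rng = np.random.default_rng(seed)
    alpha = noise.photon_level
    acc = np.zeros_like(v)
    for _ in range(noise.n_average):
        shot = rng.poisson(alpha * v).astype(np.float64)
        if noise.read_sigma > 0:
            shot = shot + rng.normal(0.0, noise.read_sigma, size=v.shape)
        acc += shot
    out = acc / (noise.n_average * alpha)
    return ImageStack(voxels=out, axis_label=clean.axis_label, dtype_origin="float32")


def effective_photons(noise: NoiseParams) -> float:
    return noise.photon_level * noise.n_average


def make_pair_dataset(
    n_pairs: int,
    spec_template: PhantomSpec,
    low_noise: "NoiseParams | list[NoiseParams]",
    high_noise: NoiseParams,
    out_dir,
    seed: int,
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    write_clean: bool = True,
) -> Manifest:
    """Generate ``n_pairs`` independent phantoms, degrade each twice from
    the same clean stack (low: few effective photons; high: many), write
    TIFFs and return a deterministic manifest.

    ``low_noise`` may be a list of one NoiseParams per pair, giving a
    dataset whose low members span several acquisition speeds (useful to
    fine-tune models that stay robust across input SNR levels).
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    if isinstance(low_noise, NoiseParams):
        low_list = [low_noise] * n_pairs
    else:
        low_list = list(low_noise)
        if len(low_list) != n_pairs:
            raise ConfigError(f"need one low_noise per pair ({n_pairs}), got {len(low_list)}")
    for ln in low_list:
        if effective_photons(ln) >= effective_photons(high_noise):
            raise ConfigError(
                "low_noise must be strictly noisier than high_noise "
                f"(alpha*n_average {effective_photons(ln)} >= {effective_photons(high_noise)})"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = int(np.ceil(split_fractions[0] * n_pairs))
    n_val = int(np.ceil(split_fractions[1] * n_pairs))
    entries = []
    for i in range(n_pairs):
        import dataclasses

        spec = dataclasses.replace(spec_template, seed=int(np.random.default_rng([seed, i]).integers(2**31)))
        clean = make_clean_stack(spec)
        low = degrade(clean, low_list[i], [seed, i, 0])
        high = degrade(clean, high_noise, [seed, i, 1])
        pid = f"pair_{i:04d}"
        low_rel = f"low/{pid}.tif"
        high_rel = f"high/{pid}.tif"
        write_stack(low, out_dir / low_rel, "float32")
        write_stack(high, out_dir / high_rel, "float32")
        tags = [spec_template.kind, f"low_n_average={low_list[i].n_average}"]
        if write_clean:
            clean_rel = f"clean/{pid}.tif"
            write_stack(clean, out_dir / clean_rel, "float32")
            tags.append(f"clean={clean_rel}")
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        entries.append(ManifestEntry(pair_id=pid, low_path=low_rel, high_path=high_rel,
                                     split=split, tags=tags))
    manifest = Manifest(entries=entries, root=out_dir)
    save_manifest(manifest, out_dir / "manifest.yaml")
    return manifest


def make_average_series(spec: PhantomSpec, noise: NoiseParams, n: int = 64, seed: int = 0) -> AverageSeries:
    """N single-shot degradations of one clean phantom; member n is the
    running mean of repeats 1..n; member N is the designated ground truth."""
    if n < 2:
        raise ConfigError("average series needs N >= 2")
    if noise.n_average != 1:
        raise ConfigError("series repeats are single shots; pass n_average=1")
    clean = make_clean_stack(spec)
    members = []
    run = np.zeros_like(clean.voxels)
    for i in range(n):
        rep = degrade(clean, noise, [seed, i])
        run = run + rep.voxels
        members.append(ImageStack(voxels=run / (i + 1), axis_label=clean.axis_label,
                                  dtype_origin="float32"))
    return AverageSeries(members=members, clean=clean)
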