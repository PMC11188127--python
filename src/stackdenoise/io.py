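"""Image-stack and manifest I/O, intensity normalization, config/log plumbing.

Conventions shared by every module:

* voxel arrays are ``[C, F, H, W]`` — channel, frame (Z or T), row, column;
* pixel coordinates are 0-based, H before W;
* the Z and T interpretations of the frame axis are treated identically.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import ConfigError, DegenerateInputError, FormatError, ResolutionError

logger = logging.getLogger("stackdenoise")

#: default robust percentile window, chosen to shrug off hot pixels
DEFAULT_P_LOW_Q = 0.5
DEFAULT_P_HIGH_Q = 99.8

_ALLOWED_AXIS = ("Z", "T")
_ALLOWED_SPLITS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImageStack:
    """One sample: ``voxels[C, F, H, W]`` plus acquisition metadata."""

    voxels: np.ndarray
    axis_label: str = "Z"
    dtype_origin: str = "float32"
    pixel_size: float | None = None

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 4:
            raise FormatError(f"ImageStack voxels must be 4-axis [C,F,H,W], got shape {v.shape}")
        if min(v.shape) < 1:
            raise FormatError(f"ImageStack axes must all be >= 1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FormatError("ImageStack voxels must be finite")
        if self.axis_label not in _ALLOWED_AXIS:
            raise ConfigError(f"axis_label must be one of {_ALLOWED_AXIS}, got {self.axis_label!r}")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape


@dataclass
class StackPair:
    """A pixel-registered low/high SNR pair."""

    low: ImageStack
    high: ImageStack
    pair_id: str

    def __post_init__(self):
        if self.low.shape != self.high.shape:
            raise FormatError(
                f"pair {self.pair_id!r}: low shape {self.low.shape} != high shape {self.high.shape}"
            )
        if self.low.axis_label != self.high.axis_label:
            raise FormatError(f"pair {self.pair_id!r}: axis labels differ")


@dataclass
class ManifestEntry:
    pair_id: str
    low_path: str
    high_path: str
    split: str = "train"
    tags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.split not in _ALLOWED_SPLITS:
            raise FormatError(f"split must be one of {_ALLOWED_SPLITS}, got {self.split!r}")


@dataclass
class Manifest:
    """Dataset listing; paths are resolved relative to ``root``."""

    entries: list[ManifestEntry] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self):
        ids = [e.pair_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate pair_id(s) in manifest: {dupes}")

    def split(self, name: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == name]

    def resolve(self, rel: str) -> Path:
        return (Path(self.root) / rel).resolve()

    def load_pair(self, entry: ManifestEntry, axis_label: str = "Z") -> StackPair:
        low = read_stack(self.resolve(entry.low_path), axis_label)
        high = read_stack(self.resolve(entry.high_path), axis_label)
        return StackPair(low=low, high=high, pair_id=entry.pair_id)


@dataclass(frozen=True)
class NormParams:
    """Affine intensity map recorded by :func:`normalize_stack`."""

    p_low_value: float
    p_high_value: float
    p_low_q: float
    p_high_q: float

    def __post_init__(self):
        if not self.p_high_value > self.p_low_value:
            raise DegenerateInputError(
                f"degenerate normalization window: v_low={self.p_low_value} >= v_high={self.p_high_value}"
            )


# ---------------------------------------------------------------------------
# stack I/O


def read_stack(path, axis_label: str = "Z") -> ImageStack:
    """Read a single- or multi-page TIFF into an ImageStack.

    Pages map to the frame axis; an explicit channel axis (sample axis of
    the TIFF) maps to C; grayscale pages give C=1.  Values are converted to
    float without rescaling and the original dtype is recorded.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    origin = str(arr.dtype)
    if origin not in ("uint8", "uint16", "float32", "float64"):
        raise FormatError(f"{path}: unsupported TIFF dtype {origin}")
    if arr.ndim == 2:
        vox = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        vox = arr[np.newaxis]  # (F, H, W) -> C=1
    elif arr.ndim == 4:
        # written by write_stack as (F, C, H, W); move C first
        vox = np.moveaxis(arr, 1, 0)
    else:
        raise FormatError(f"{path}: cannot interpret TIFF of shape {arr.shape}")
    return ImageStack(
        voxels=vox.astype(np.float64),
        axis_label=axis_label,
        dtype_origin="float64" if origin == "float64" else origin,
    )


def write_stack(stack: ImageStack, path, dtype: str = "float32") -> None:
    """Write a multi-page TIFF, one page per frame (channel axis preserved).

    ``uint16`` output requires values in [0, 1]; they are scaled to the full
    integer range.  Out-of-range values raise rather than silently clip.
    """
    path = Path(path)
    v = stack.voxels
    if dtype == "float32":
        out = v.astype(np.float32)
    elif dtype == "uint16":
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError(
                f"uint16 output requires values in [0,1]; got [{v.min():.4g}, {v.max():.4g}]"
            )
        out = np.round(v * 65535.0).astype(np.uint16)
    else:
        raise ConfigError(f"write_stack dtype must be 'uint16' or 'float32', got {dtype!r}")
    c = out.shape[0]
    if c == 1:
        pages = out[0]  # (F, H, W)
    else:
        pages = np.moveaxis(out, 0, 1)  # (F, C, H, W)
    path.parent.mkdir(parents=True, exist_ok=True)
    # explicit photometric: stops tifffile guessing RGB for 3-4 frame stacks
    tifffile.imwrite(path, pages, photometric="minisblack")


# ---------------------------------------------------------------------------
# normalization


def normalize_stack(
    stack: ImageStack,
    p_low_q: float = DEFAULT_P_LOW_Q,
    p_high_q: float = DEFAULT_P_HIGH_Q,
    params: NormParams | None = None,
    clip: bool = True,
) -> tuple[ImageStack, NormParams]:
    """Percentile-window normalize to [0, 1] (clipped by default).

    When ``params`` is given the stored window is applied instead of
    computing percentiles — used to apply the LOW member's statistics to
    both members of a pair.  ``clip=False`` keeps out-of-window voxels on
    the affine map (used by inference so restoration never destroys them).
    """
    if params is None:
        if not (0.0 <= p_low_q < p_high_q <= 100.0):
            raise ConfigError(f"percentiles must satisfy 0 <= low < high <= 100, got {p_low_q}, {p_high_q}")
        v_low = float(np.percentile(stack.voxels, p_low_q))
        v_high = float(np.percentile(stack.voxels, p_high_q))
        if v_high <= v_low:
            raise DegenerateInputError(
                f"constant or near-constant stack: percentile window [{v_low}, {v_high}] is empty"
            )
        params = NormParams(v_low, v_high, p_low_q, p_high_q)
    scaled = (stack.voxels - params.p_low_value) / (params.p_high_value - params.p_low_value)
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    out = dataclasses.replace(stack, voxels=scaled)
    return out, params


def denormalize_stack(stack: ImageStack, params: NormParams) -> ImageStack:
    """Exact affine inverse of :func:`normalize_stack` (clipping not undone)."""
    v = stack.voxels * (params.p_high_value - params.p_low_value) + params.p_low_value
    return dataclasses.replace(stack, voxels=v)


def normalize_pair(pair: StackPair, p_low_q: float = DEFAULT_P_LOW_Q,
                   p_high_q: float = DEFAULT_P_HIGH_Q) -> tuple[StackPair, NormParams]:
    """Normalize both members using the LOW member's statistics, so input
    statistics at inference (no high member available) match training."""
    low_n, params = normalize_stack(pair.low, p_low_q, p_high_q)
    high_n, _ = normalize_stack(pair.high, params=params)
    return StackPair(low=low_n, high=high_n, pair_id=pair.pair_id), params


# ---------------------------------------------------------------------------
# manifests


def load_manifest(path, check_paths: bool = True) -> Manifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {"entries": []}
    if not isinstance(doc, dict) or "entries" not in doc:
        raise FormatError(f"{path}: manifest must be a mapping with an 'entries' list")
    entries = []
    for raw in doc["entries"] or []:
        try:
            entries.append(
                ManifestEntry(
                    pair_id=str(raw["pair_id"]),
                    low_path=str(raw["low_path"]),
                    high_path=str(raw["high_path"]),
                    split=str(raw.get("split", "train")),
                    tags=[str(t) for t in raw.get("tags", [])],
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: manifest entry missing field {exc}") from exc
    manifest = Manifest(entries=entries, root=path.parent)
    if check_paths:
        missing = []
        for e in manifest.entries:
            for rel in (e.low_path, e.high_path):
                if not manifest.resolve(rel).exists():
                    missing.append(rel)
        if missing:
            raise ResolutionError(f"{path}: missing file(s): {sorted(set(missing))}")
    return manifest


def save_manifest(manifest: Manifest, path) -> None:
    path = Path(path)
    doc = {
        "entries": [
            {
                "pair_id": e.pair_id,
                "low_path": e.low_path,
                "high_path": e.high_path,
                "split": e.split,
                "tags": list(e.tags),
            }
            for e in manifest.entries
        ]
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# config / logging plumbing


def load_config_file(path) -> dict:
    """Load a structured-text (YAML) configuration file into a dict."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config file must be a mapping")
    return doc


def save_config_file(config: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("stackdenoise")
    root.setLevel(getattr(logging, level.upper()))
    root.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)
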