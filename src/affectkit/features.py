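"""Face-patch extraction and gradient-orientation descriptors.

Turns an annotated frame (grayscale image + face box) into a fixed-length
histogram-of-oriented-gradients (HOG) descriptor:

1. crop the face box and bilinearly resample to a square patch;
2. normalize illumination (per-patch standardization followed by a logistic
   squash), which makes the downstream descriptor invariant to global
   gain/offset changes in lighting;
3. pool gradient-orientation histograms over cells, normalize over
   overlapping blocks (L2-hys).

Two training-time augmentation operators are provided: horizontal mirroring
and Gaussian jitter of the face box, emulating face-tracker inaccuracy.

Face *detection* is out of scope: boxes are inputs, so any upstream tracker
can be plugged in behind the :class:`FaceBox` contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .labels import canonical

__all__ = [
    "FaceBox",
    "FaceFrame",
    "HogConfig",
    "NoFaceError",
    "extract_patch",
    "normalize_illumination",
    "compute_hog",
    "mirror_frame",
    "jitter_box",
    "hog_dim",
    "frame_features",
    "HogDescriptor",
    "read_frames_csv",
    "write_frames_csv",
    "write_features_csv",
    "read_features_csv",
    "to_grayscale",
]

#: ITU-R BT.601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class NoFaceError(Exception):
    """The face box lies entirely outside the image (distinct from malformed input)."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W) or (H, W, 3) array in [0, 1] to grayscale (BT.601)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3] @ _LUMA
    raise ValueError(f"expected 2-D or (H, W, 3) image, got shape {arr.shape}")


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box, 0-based, (x, y, width, height), half-open."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"box sides must be positive, got {self.width}x{self.height}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2)."""
        return (self.x, self.y, self.x + self.width, self.y + self.height)

    def clip(self, image_shape: tuple[int, int]) -> "FaceBox":
        """Intersect with the image; raise :class:`NoFaceError` if empty."""
        h, w = image_shape[:2]
        x1 = max(self.x, 0.0)
        y1 = max(self.y, 0.0)
        x2 = min(self.x + self.width, float(w))
        y2 = min(self.y + self.height, float(h))
        if x2 <= x1 or y2 <= y1:
            raise NoFaceError(f"box {self} lies outside a {w}x{h} image")
        return FaceBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class FaceFrame:
    """One timestamped grayscale frame with its face box and optional true label."""

    image: np.ndarray
    timestamp: float
    box: FaceBox
    label: str | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("image must be a non-empty 2-D grayscale array")
        if self.timestamp < 0:
            raise ValueError(f"timestamp must be >= 0, got {self.timestamp}")
        object.__setattr__(self, "image", img)
        if self.label is not None:
            object.__setattr__(self, "label", canonical(self.label))


@dataclass(frozen=True)
class HogConfig:
    """Parameters of the gradient-orientation descriptor.

    Defaults follow the canonical published HOG configuration: 64x64 patch,
    8-px cells, 2x2-cell blocks with single-cell stride, 9 unsigned
    orientation bins, L2-hys block normalization.
    """

    patch_size: int = 64
    cell_size: int = 8
    block_size: int = 2
    n_orientations: int = 9
    block_norm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.patch_size % self.cell_size != 0:
            raise ValueError("patch_size must be divisible by cell_size")
        if self.n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        if self.block_size < 1 or self.block_size > self.patch_size // self.cell_size:
            raise ValueError("block_size out of range")

    @property
    def cells_per_side(self) -> int:
        return self.patch_size // self.cell_size

    @property
    def blocks_per_side(self) -> int:
        return self.cells_per_side - self.block_size + 1

    @property
    def dim(self) -> int:
        """Descriptor length — a pure function of the configuration."""
        return self.blocks_per_side**2 * self.block_size**2 * self.n_orientations


def hog_dim(config: HogConfig) -> int:
    return config.dim


def extract_patch(frame: FaceFrame, size: int) -> np.ndarray:
    """Crop the face box and bilinearly resample to a ``size`` x ``size`` patch.

    Pixel-center aligned: output pixel i samples source coordinate
    ``box_edge + (i + 0.5) * box_side / size - 0.5``, with nearest-edge clamp.
    Intensities stay in [0, 1]. Raises :class:`NoFaceError` if the box lies
    entirely outside the image.
    """
    if size <= 0:
        raise ValueError("patch size must be positive")
    box = frame.box.clip(frame.image.shape)
    ys = box.y + (np.arange(size) + 0.5) * box.height / size - 0.5
    xs = box.x + (np.arange(size) + 0.5) * box.width / size - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    patch = map_coordinates(frame.image, [yy, xx], order=1, mode="nearest")
    return np.clip(patch, 0.0, 1.0)


def normalize_illumination(patch: np.ndarray) -> np.ndarray:
    """Per-patch standardize then logistically squash back to [0, 1].

    Invariant to affine intensity rescaling a*p + c (a > 0) when no clipping
    occurred upstream. A zero-variance patch maps to the all-0.5 patch by
    convention (no exception).
    """
    p = np.asarray(patch, dtype=float)
    sd = p.std()
    if p.max() - p.min() == 0.0 or not np.isfinite(sd):
        return np.full_like(p, 0.5)
    return expit((p - p.mean()) / sd)


def compute_hog(patch: np.ndarray, config: HogConfig | None = None) -> np.ndarray:
    """Block-normalized gradient-orientation descriptor of a square patch.

    Scheme: central-difference gradients (one-sided at borders), unsigned
    orientation in [0, pi) with magnitude-weighted *circular linear*
    interpolation between the two nearest bin centers, per-cell pooling,
    overlapping block_size x block_size blocks at single-cell stride, L2-hys
    normalization (L2, clip at 0.2, re-L2). All entries are >= 0 and each
    block sub-vector has norm <= 1 (up to eps).
    """
    config = config or HogConfig()
    p = np.asarray(patch, dtype=float)
    if p.shape != (config.patch_size, config.patch_size):
        raise ValueError(
            f"patch shape {p.shape} does not match configured size {config.patch_size}"
        )
    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), np.pi)

    nb = config.n_orientations
    delta = np.pi / nb
    pos = theta / delta - 0.5
    k0 = np.floor(pos).astype(int)
    w1 = pos - k0
    b0 = np.mod(k0, nb)
    b1 = np.mod(k0 + 1, nb)

    nc = config.cells_per_side
    cs = config.cell_size
    cell_hist = np.zeros((nc, nc, nb))
    cy = np.repeat(np.arange(nc), cs)  # row index -> cell row
    flat_cell = (cy[:, None] * nc + cy[None, :]).ravel()
    np.add.at(
        cell_hist.reshape(-1, nb)[:, :],
        (flat_cell, b0.ravel()),
        (mag * (1.0 - w1)).ravel(),
    )
    np.add.at(cell_hist.reshape(-1, nb)[:, :], (flat_cell, b1.ravel()), (mag * w1).ravel())

    bs = config.block_size
    nbl = config.blocks_per_side
    eps = config.block_norm_eps
    out = np.empty((nbl, nbl, bs * bs * nb))
    for by in range(nbl):
        for bx in range(nbl):
            v = cell_hist[by : by + bs, bx : bx + bs, :].ravel()
            v = v / np.sqrt(v @ v + eps**2)
            v = np.minimum(v, 0.2)
            v = v / np.sqrt(v @ v + eps**2)
            out[by, bx] = v
    return out.ravel()


def frame_features(frame: FaceFrame, config: HogConfig | None = None) -> np.ndarray:
    """Full frame -> descriptor map: crop/resample, illumination-normalize, HOG."""
    config = config or HogConfig()
    patch = extract_patch(frame, config.patch_size)
    return compute_hog(normalize_illumination(patch), config)


def mirror_frame(frame: FaceFrame) -> FaceFrame:
    """Horizontally mirror image and box; label and timestamp preserved.

    An involution: ``mirror_frame(mirror_frame(f))`` reproduces ``f`` exactly.
    """
    w = frame.image.shape[1]
    box = FaceBox(w - frame.box.x - frame.box.width, frame.box.y, frame.box.width, frame.box.height)
    return FaceFrame(frame.image[:, ::-1].copy(), frame.timestamp, box, frame.label)


def jitter_box(
    box: FaceBox,
    sigma: float,
    rng: np.random.Generator | int,
    image_shape: tuple[int, int],
    min_side: float = 8.0,
    max_retries: int = 10,
) -> FaceBox:
    """Perturb the box corners with i.i.d. N(0, sigma^2) noise (tracker-error model).

    Corners are clipped to the image; a draw that collapses a side below
    ``min_side`` is redrawn up to ``max_retries`` times, then raises.
    Deterministic for a given seed/generator state; sigma = 0 returns the
    input box unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return box
    gen = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    h, w = image_shape[:2]
    x1, y1, x2, y2 = box.corners
    for _ in range(max_retries):
        dx1, dy1, dx2, dy2 = gen.normal(0.0, sigma, size=4)
        nx1 = np.clip(x1 + dx1, 0.0, float(w))
        ny1 = np.clip(y1 + dy1, 0.0, float(h))
        nx2 = np.clip(x2 + dx2, 0.0, float(w))
        ny2 = np.clip(y2 + dy2, 0.0, float(h))
        if nx2 - nx1 >= min_side and ny2 - ny1 >= min_side:
            return FaceBox(float(nx1), float(ny1), float(nx2 - nx1), float(ny2 - ny1))
    raise ValueError(
        f"jittered box collapsed below min side {min_side} in {max_retries} retries"
    )


class HogDescriptor(TransformerMixin, BaseEstimator):
    """sklearn transformer: FaceFrames (or raw square patches) -> HOG features.

    Stateless; ``fit`` only records the output dimensionality.
    """

    def __init__(
        self,
        patch_size: int = 64,
        cell_size: int = 8,
        block_size: int = 2,
        n_orientations: int = 9,
        block_norm_eps: float = 1e-5,
        normalize: bool = True,
    ) -> None:
        self.patch_size = patch_size
        self.cell_size = cell_size
        self.block_size = block_size
        self.n_orientations = n_orientations
        self.block_norm_eps = block_norm_eps
        self.normalize = normalize

    @property
    def config(self) -> HogConfig:
        return HogConfig(
            patch_size=self.patch_size,
            cell_size=self.cell_size,
            block_size=self.block_size,
            n_orientations=self.n_orientations,
            block_norm_eps=self.block_norm_eps,
        )

    def fit(self, X, y=None):
        self.n_features_out_ = self.config.dim
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self.config
        rows = []
        for item in X:
            if isinstance(item, FaceFrame):
                patch = extract_patch(item, cfg.patch_size)
            else:
                patch = np.asarray(item, dtype=float)
            if self.normalize:
                patch = normalize_illumination(patch)
            rows.append(compute_hog(patch, cfg))
        return np.asarray(rows)


# ---------------------------------------------------------------------------
# frame / feature table IO


def write_frames_csv(frames: Sequence[FaceFrame], path, images_dir=None) -> None:
    """Write a frames.csv sidecar (and PNGs, if ``images_dir`` is given)."""
    from PIL import Image

    path = Path(path)
    rows = []
    for i, f in enumerate(frames):
        frame_path = ""
        if images_dir is not None:
            images_dir = Path(images_dir)
            images_dir.mkdir(parents=True, exist_ok=True)
            frame_path = f"frame_{i:06d}.png"
            img = (np.clip(f.image, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(img, mode="L").save(images_dir / frame_path)
        rows.append(
            {
                "frame_path": frame_path,
                "timestamp_s": f.timestamp,
                "box_x": f.box.x,
                "box_y": f.box.y,
                "box_w": f.box.width,
                "box_h": f.box.height,
                "label": f.label or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frames_csv(path, images_dir=None) -> list[FaceFrame]:
    """Load frames.csv (columns frame_path,timestamp_s,box_x,box_y,box_w,box_h,label)."""
    from PIL import Image

    path = Path(path)
    images_dir = Path(images_dir) if images_dir is not None else path.parent
    df = pd.read_csv(path, keep_default_na=False)
    required = {"frame_path", "timestamp_s", "box_x", "box_y", "box_w", "box_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frames csv missing columns: {sorted(missing)}")
    frames = []
    for row in df.itertuples(index=False):
        img = np.asarray(Image.open(images_dir / row.frame_path).convert("L"), dtype=float) / 255.0
        label = getattr(row, "label", "") or None
        frames.append(
            FaceFrame(
                image=img,
                timestamp=float(row.timestamp_s),
                box=FaceBox(float(row.box_x), float(row.box_y), float(row.box_w), float(row.box_h)),
                label=label,
            )
        )
    return frames


def write_features_csv(X: np.ndarray, labels: Sequence[str] | None, path) -> None:
    """Feature table with header f0..f{d-1},label (label column may be empty)."""
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = ["" if l is None else canonical(l) for l in labels] if labels is not None else ""
    df.to_csv(path, index=False)


def read_features_csv(path) -> tuple[np.ndarray, list[str | None]]:
    df = pd.read_csv(path, keep_default_na=False)
    if "label" not in df.columns:
        raise ValueError("features csv missing 'label' column")
    feat_cols = [c for c in df.columns if c != "label"]
    X = df[feat_cols].to_numpy(dtype=float)
    labels = [canonical(l) if l else None for l in df["label"]]
    return X, labels
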