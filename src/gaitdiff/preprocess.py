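"""Silhouette extraction and normalization.

Raw grayscale frames are turned into binary silhouettes by per-pixel
Gaussian background subtraction, and every silhouette is brought onto a
common canvas: cropped to its bounding box, rescaled (bicubic) so the
bounding-box height equals ``target_height`` with aspect ratio preserved,
and translated so its centroid sits at the canvas center.  Two silhouettes
prepared this way are mutually aligned, which makes the frame-differencing
step a plain per-pixel comparison.

Coordinates follow image convention: ``x`` is the column, ``y`` the row,
0-based with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.transform import resize

__all__ = [
    "RawFrame",
    "BackgroundModel",
    "BinarySilhouette",
    "fit_background",
    "segment",
    "compute_centroid",
    "normalize_and_align",
]

DEFAULT_CANVAS = (240, 320)
DEFAULT_TARGET_HEIGHT = 200


@dataclass(frozen=True)
class RawFrame:
    """A single grayscale frame (rows x cols, row-major)."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite intensities")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel Gaussian background: mean intensity and spread (std)."""

    mean: np.ndarray
    spread: np.ndarray
    threshold_k: float = 2.5

    def __post_init__(self) -> None:
        if self.mean.shape != self.spread.shape:
            raise ValueError("mean and spread shapes differ")
        if np.any(self.spread < 0):
            raise ValueError("spread must be non-negative")


@dataclass(frozen=True)
class BinarySilhouette:
    """One binary silhouette on a fixed canvas.

    ``centroid`` is (x_c, y_c): the mean of foreground column and row
    coordinates, real-valued.
    """

    mask: np.ndarray
    frame_index: int = 0
    centroid: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        vals = np.unique(m)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must contain only 0/1")
        m = m.astype(np.uint8)
        object.__setattr__(self, "mask", m)
        if self.centroid is None:
            object.__setattr__(self, "centroid", compute_centroid(m))

    @property
    def canvas_height(self) -> int:
        return self.mask.shape[0]

    @property
    def canvas_width(self) -> int:
        return self.mask.shape[1]

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def fit_background(frames: list[RawFrame | np.ndarray]) -> BackgroundModel:
    """Fit a per-pixel Gaussian background model over static frames.

    Returns the element-wise mean and standard deviation (population,
    ``ddof=0``) of the input stack.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to fit a background model")
    arrays = [f.pixels if isinstance(f, RawFrame) else np.asarray(f, float) for f in frames]
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(
                f"frame {i} has shape {a.shape}, expected {shape} (dimension mismatch)"
            )
    stack = np.stack(arrays)
    return BackgroundModel(mean=stack.mean(axis=0), spread=stack.std(axis=0))


def segment(
    frame: RawFrame | np.ndarray,
    bg: BackgroundModel,
    blur_sigma: float = 1.0,
    *,
    spread_floor: float = 1.0,
    keep_largest: bool = True,
) -> BinarySilhouette:
    """Extract the walking subject from a frame by background subtraction.

    The frame is Gaussian-blurred with ``blur_sigma`` (0 disables the blur),
    and a pixel is foreground iff::

        |blurred - mean| > threshold_k * max(spread, spread_floor)

    ``spread_floor`` guards pixels whose background never varied.  With
    ``keep_largest`` the largest 8-connected foreground component is kept,
    which discards isolated noise speckles.
    """
    px = frame.pixels if isinstance(frame, RawFrame) else np.asarray(frame, float)
    idx = frame.frame_index if isinstance(frame, RawFrame) else 0
    if px.shape != bg.mean.shape:
        raise ValueError(f"frame shape {px.shape} does not match background {bg.mean.shape}")
    blurred = ndimage.gaussian_filter(px, blur_sigma) if blur_sigma > 0 else px
    thresh = bg.threshold_k * np.maximum(bg.spread, spread_floor)
    mask = (np.abs(blurred - bg.mean) > thresh).astype(np.uint8)
    if keep_largest and mask.any():
        labels, n = label(mask, connectivity=2, return_num=True)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = (labels == sizes.argmax()).astype(np.uint8)
    if not mask.any():
        raise ValueError("no subject detected: segmentation produced an empty foreground")
    return BinarySilhouette(mask=mask, frame_index=idx)


def compute_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (x_c, y_c) of the foreground: the mean of pixel coordinates.

    x is the column index, y the row index; the result is real-valued.
    """
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("cannot compute centroid of an empty mask")
    return float(xs.mean()), float(ys.mean())


def _round_half_down(v: float) -> int:
    # Fixed tie rule (ties toward -inf) so placement is reproducible
    # across platforms.
    return int(np.ceil(v - 0.5))


def normalize_and_align(
    mask: np.ndarray | BinarySilhouette,
    target_height: int = DEFAULT_TARGET_HEIGHT,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    *,
    frame_index: int | None = None,
) -> BinarySilhouette:
    """Height-normalize a silhouette and center it on a fixed canvas.

    The mask is cropped to its bounding box, rescaled by bicubic
    interpolation so the box height equals ``target_height`` (aspect ratio
    preserved), re-binarized at 0.5, and pasted onto an ``H x W`` zero
    canvas so that its centroid lands on the canvas center pixel (nearest
    integer, ties toward negative infinity).
    """
    if isinstance(mask, BinarySilhouette):
        if frame_index is None:
            frame_index = mask.frame_index
        mask = mask.mask
    mask = np.asarray(mask)
    H, W = canvas
    if target_height > H:
        raise ValueError(f"target_height {target_height} exceeds canvas height {H}")
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("cannot normalize an empty mask")
    crop = mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1].astype(float)
    bh, bw = crop.shape
    scale = target_height / bh
    new_w = max(1, int(round(bw * scale)))
    if new_w > W:
        raise ValueError(
            f"rescaled silhouette width {new_w} exceeds canvas width {W}; use a larger canvas"
        )
    if (target_height, new_w) == crop.shape:
        scaled = crop >= 0.5
    else:
        scaled = resize(crop, (target_height, new_w), order=3, anti_aliasing=False) >= 0.5
    scaled = scaled.astype(np.uint8)
    if not scaled.any():  # pragma: no cover - only hit for pathological masks
        raise ValueError("silhouette vanished after rescaling")

    x_c, y_c = compute_centroid(scaled)
    out = np.zeros((H, W), dtype=np.uint8)
    # top-left corner that puts the centroid on the canvas center pixel
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    x0 = _round_half_down(cx - x_c)
    y0 = _round_half_down(cy - y_c)
    sh, sw = scaled.shape
    # clip to canvas (a silhouette taller/wider than the canvas was rejected above)
    ys0, ys1 = max(0, y0), min(H, y0 + sh)
    xs0, xs1 = max(0, x0), min(W, x0 + sw)
    out[ys0:ys1, xs0:xs1] = scaled[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
    if not out.any():
        raise ValueError("silhouette fell entirely outside the canvas")
    return BinarySilhouette(mask=out, frame_index=frame_index or 0)
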