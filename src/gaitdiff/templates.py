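"""Motion templates: the average gait differential image (AGDI) and the
gait energy image (GEI).

Both templates compress an aligned binary silhouette sequence
``I_1 .. I_N`` into a single real-valued image on the same canvas:

* AGDI averages the frame-to-frame differential images
  ``D_j(x, y) = [I_j(x, y) != I_{j+1}(x, y)]`` over the ``N - 1`` adjacent
  pairs, so it highlights the moving parts (limbs) while static regions
  (torso interior) go to zero.
* GEI averages the silhouettes themselves, so every pixel holds the
  fraction of frames in which it was foreground.

Templates are built over a caller-specified frame window (the whole
sequence by default); a simple autocorrelation-based gait-cycle estimator
is provided as a convenience for choosing window lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BinarySilhouette

__all__ = [
    "SilhouetteSequence",
    "GaitTemplate",
    "differential_image",
    "build_agdi",
    "build_gei",
    "build_template",
    "estimate_cycle_length",
]


@dataclass(frozen=True)
class SilhouetteSequence:
    """An ordered, aligned silhouette sequence for one walk."""

    frames: tuple[BinarySilhouette, ...]
    subject_id: str = ""
    sequence_id: str = ""
    view_angle: float = 90.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise ValueError("a silhouette sequence needs at least 2 frames")
        shape = frames[0].mask.shape
        for i, f in enumerate(frames):
            if f.mask.shape != shape:
                raise ValueError(
                    f"frame {i} has canvas {f.mask.shape}, expected {shape}"
                )
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def canvas(self) -> tuple[int, int]:
        return self.frames[0].mask.shape

    def masks(self) -> np.ndarray:
        """Stack of frame masks, shape (N, H, W)."""
        return np.stack([f.mask for f in self.frames])

    def window(self, start: int, stop: int | None = None) -> "SilhouetteSequence":
        frames = self.frames[start:stop]
        return SilhouetteSequence(
            frames=frames,
            subject_id=self.subject_id,
            sequence_id=self.sequence_id,
            view_angle=self.view_angle,
        )


@dataclass(frozen=True)
class GaitTemplate:
    """A per-pixel average image summarizing one sequence."""

    values: np.ndarray
    kind: str = "agdi"
    n_frames_used: int = 0
    subject_id: str = ""
    sequence_id: str = ""
    view_angle: float = 90.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("template values must be 2-D")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("template values must lie in [0, 1]")
        if self.kind not in ("agdi", "gei"):
            raise ValueError(f"unknown template kind {self.kind!r}")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def differential_image(
    a: BinarySilhouette | np.ndarray, b: BinarySilhouette | np.ndarray
) -> np.ndarray:
    """Per-pixel inequality indicator of two aligned binary frames.

    For binary inputs this is the XOR of the two masks; the result is
    symmetric in its arguments.
    """
    ma = a.mask if isinstance(a, BinarySilhouette) else np.asarray(a)
    mb = b.mask if isinstance(b, BinarySilhouette) else np.asarray(b)
    if ma.shape != mb.shape:
        raise ValueError(f"canvas mismatch: {ma.shape} vs {mb.shape}")
    return (ma != mb).astype(np.uint8)


def build_agdi(seq: SilhouetteSequence) -> GaitTemplate:
    """Average gait differential image: mean of the N-1 adjacent XOR images."""
    masks = seq.masks().astype(np.int16)
    n = masks.shape[0]
    if n < 2:
        raise ValueError("AGDI needs at least 2 frames")
    diffs = (masks[1:] != masks[:-1]).astype(float)
    return GaitTemplate(
        values=diffs.mean(axis=0),
        kind="agdi",
        n_frames_used=n,
        subject_id=seq.subject_id,
        sequence_id=seq.sequence_id,
        view_angle=seq.view_angle,
    )


def build_gei(seq: SilhouetteSequence) -> GaitTemplate:
    """Gait energy image: per-pixel mean of the binary frames themselves."""
    masks = seq.masks().astype(float)
    return GaitTemplate(
        values=masks.mean(axis=0),
        kind="gei",
        n_frames_used=masks.shape[0],
        subject_id=seq.subject_id,
        sequence_id=seq.sequence_id,
        view_angle=seq.view_angle,
    )


def build_template(seq: SilhouetteSequence, kind: str = "agdi") -> GaitTemplate:
    if kind == "agdi":
        return build_agdi(seq)
    if kind == "gei":
        return build_gei(seq)
    raise ValueError(f"unknown template kind {kind!r}")


def estimate_cycle_length(
    seq: SilhouetteSequence, min_period: int = 6, max_period: int | None = None
) -> int:
    """Estimate the gait-cycle period (frames) from the silhouette-width signal.

    The per-frame foreground bounding-box width oscillates with the stride;
    the lag maximizing the autocorrelation of the mean-centered width signal
    over ``[min_period, max_period]`` is returned.  This is a convenience —
    template construction itself never requires cycle detection.
    """
    widths = []
    for f in seq.frames:
        xs = np.nonzero(f.mask.any(axis=0))[0]
        widths.append(xs.max() - xs.min() + 1 if xs.size else 0)
    w = np.asarray(widths, float)
    w = w - w.mean()
    n = len(w)
    if max_period is None:
        max_period = n // 2
    if max_period < min_period:
        raise ValueError("sequence too short for cycle estimation")
    ac = np.correlate(w, w, mode="full")[n - 1 :]
    lags = np.arange(min_period, max_period + 1)
    return int(lags[np.argmax(ac[min_period : max_period + 1])])
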