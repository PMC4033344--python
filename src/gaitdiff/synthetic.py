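"""Parametric side-view walking-silhouette generator.

Real gait datasets are bulky; this module renders deterministic binary
silhouettes of a stick-and-ellipse walker so the whole template /
feature / recognition pipeline can be exercised end to end.  A walker is
a circle head, an ellipse torso and two-segment legs and arms drawn as
thick line segments; joint angles vary sinusoidally with the frame index
over a subject-specific gait cycle.  Subjects differ in limb proportions,
stride and arm-swing amplitude and cycle length; sequences of the same
subject share those parameters and differ only in phase offset and pixel
noise, so same-subject templates are near and different-subject templates
are far — the property the recognition tests rely on.

The renderer emulates shape and articulation only: no clothing, shadows,
self-occlusion ordering, perspective or view change, and its pixel noise
is independent salt-and-pepper rather than the structured segmentation
errors of real silhouettes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import draw

from .preprocess import BinarySilhouette, normalize_and_align
from .templates import SilhouetteSequence

__all__ = ["WalkerParams", "render_walker", "generate_population"]

DEFAULT_CANVAS = (120, 96)
DEFAULT_TARGET_HEIGHT = 100


@dataclass(frozen=True)
class WalkerParams:
    """Subject-level shape and motion parameters.

    Ratios are fractions of the figure height; amplitudes are half-ranges
    of the sinusoidal joint angles in degrees.
    """

    torso_height_ratio: float = 0.32
    torso_width_ratio: float = 0.16
    head_radius_ratio: float = 0.07
    leg_length_ratio: float = 0.48
    arm_length_ratio: float = 0.36
    stride_amplitude_deg: float = 28.0
    arm_amplitude_deg: float = 22.0
    cycle_length: int = 22
    phase_offset: float = 0.0
    shape_jitter: float = 0.02
    flip_probability: float = 0.002
    figure_height: int = 96

    def __post_init__(self) -> None:
        if not 0.0 <= self.stride_amplitude_deg <= 60.0:
            raise ValueError("stride amplitude must be in [0, 60] degrees")
        if not 0.0 <= self.arm_amplitude_deg <= 60.0:
            raise ValueError("arm-swing amplitude must be in [0, 60] degrees")
        if self.cycle_length < 6:
            raise ValueError("cycle length must be at least 6 frames")
        if not 0.0 <= self.flip_probability <= 0.2:
            raise ValueError("flip probability must be in [0, 0.2]")
        for name in ("torso_height_ratio", "torso_width_ratio", "head_radius_ratio",
                     "leg_length_ratio", "arm_length_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _thick_segment(mask: np.ndarray, p0, p1, width: float) -> None:
    """Draw a line segment of the given thickness (rounded caps), in place."""
    H, W = mask.shape
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    length = float(np.hypot(dx, dy))
    half = width / 2.0
    if length > 1e-9:
        px, py = -dy / length * half, dx / length * half
        rr, cc = draw.polygon(
            [y0 - py, y0 + py, y1 + py, y1 - py],
            [x0 - px, x0 + px, x1 + px, x1 - px],
            shape=(H, W),
        )
        mask[rr, cc] = 1
    for x, y in ((x0, y0), (x1, y1)):
        rr, cc = draw.disk((y, x), max(half, 0.5), shape=(H, W))
        mask[rr, cc] = 1


def render_walker(
    params: WalkerParams,
    frame_index: int,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> BinarySilhouette:
    """Render one frame of the walker as a binary silhouette.

    Deterministic in ``(params, frame_index, canvas)``.  Joint angles are
    sinusoidal in ``frame_index / cycle_length`` (plus the phase offset);
    left and right limbs move in antiphase and arms oppose the legs.
    Raises if the figure would extend beyond the canvas.
    """
    H, W = canvas
    fh = params.figure_height
    # exact periodicity: integer cycle length, frame index reduced first
    cyc = params.cycle_length
    phase = ((frame_index % cyc) / cyc + params.phase_offset) % 1.0
    omega = 2.0 * np.pi * phase

    r_head = params.head_radius_ratio * fh
    torso_h = params.torso_height_ratio * fh
    torso_w = params.torso_width_ratio * fh
    leg_len = params.leg_length_ratio * fh
    arm_len = params.arm_length_ratio * fh
    a_leg = np.deg2rad(params.stride_amplitude_deg)
    a_arm = np.deg2rad(params.arm_amplitude_deg)

    cx = W / 2.0
    top = (H - fh) / 2.0
    # slight vertical bob at twice the stride frequency, vanishing with amplitude
    bob = 0.01 * fh * (params.stride_amplitude_deg / 30.0) * np.cos(2 * omega)
    head_c = (cx, top + r_head + bob)
    neck_y = top + 2 * r_head + bob
    hip = (cx, neck_y + torso_h)
    shoulder = (cx, neck_y + 0.12 * torso_h)

    def limb(origin, L, theta, bend, seg_split=0.5):
        """Two-segment limb from origin; theta from straight down, +x forward."""
        ox, oy = origin
        l1, l2 = L * seg_split, L * (1 - seg_split)
        joint = (ox + l1 * np.sin(theta), oy + l1 * np.cos(theta))
        theta2 = theta + bend
        end = (joint[0] + l2 * np.sin(theta2), joint[1] + l2 * np.cos(theta2))
        return joint, end

    theta_l = a_leg * np.sin(omega)
    theta_r = a_leg * np.sin(omega + np.pi)
    # knee flexes while the leg swings forward, straightens in stance
    knee_l = -0.3 * a_leg * max(0.0, np.cos(omega))
    knee_r = -0.3 * a_leg * max(0.0, np.cos(omega + np.pi))
    alpha_l = a_arm * np.sin(omega + np.pi)
    alpha_r = a_arm * np.sin(omega)
    elbow = np.deg2rad(12.0)

    leg_w = 0.055 * fh
    arm_w = 0.04 * fh

    # near/far limbs attach laterally apart (legs clear of each other, arms
    # at the torso edges) so silhouette area varies smoothly through the
    # stride crossing instead of limbs vanishing into the body
    leg_side = 0.55 * leg_w
    arm_side = torso_w / 2 + 0.25 * arm_w
    segments = []
    for theta, knee, dx in ((theta_l, knee_l, -leg_side), (theta_r, knee_r, leg_side)):
        origin = (hip[0] + dx, hip[1])
        k, f = limb(origin, leg_len, theta, knee)
        segments.append((origin, k, leg_w))
        segments.append((k, f, leg_w))
    for alpha, dx in ((alpha_l, -arm_side), (alpha_r, arm_side)):
        origin = (shoulder[0] + dx, shoulder[1])
        e, hand = limb(origin, arm_len, alpha, elbow)
        segments.append((origin, e, arm_w))
        segments.append((e, hand, arm_w))

    # bounds check before drawing (clipping would silently distort the figure)
    xs = [head_c[0] - r_head, head_c[0] + r_head, hip[0] - torso_w / 2, hip[0] + torso_w / 2]
    ys = [head_c[1] - r_head, head_c[1] + r_head]
    for p0, p1, w in segments:
        for (x, y) in (p0, p1):
            xs.extend([x - w, x + w])
            ys.extend([y - w, y + w])
    if min(xs) < 0 or max(xs) > W - 1 or min(ys) < 0 or max(ys) > H - 1:
        raise ValueError(
            f"walker figure exceeds the {H}x{W} canvas; reduce figure_height or amplitudes"
        )

    mask = np.zeros((H, W), dtype=np.uint8)
    rr, cc = draw.disk((head_c[1], head_c[0]), r_head, shape=(H, W))
    mask[rr, cc] = 1
    rr, cc = draw.ellipse(neck_y + torso_h / 2, cx, torso_h / 2, torso_w / 2, shape=(H, W))
    mask[rr, cc] = 1
    _thick_segment(mask, (cx, neck_y), hip, torso_w * 0.6)  # fill neck-hip line
    for p0, p1, w in segments:
        _thick_segment(mask, p0, p1, w)
    return BinarySilhouette(mask=mask, frame_index=frame_index)


# parameter ranges subjects are drawn from (uniform); motion parameters get
# the widest ranges because the differential template is articulation-driven
_SUBJECT_RANGES = {
    "torso_height_ratio": (0.28, 0.36),
    "torso_width_ratio": (0.12, 0.20),
    "head_radius_ratio": (0.055, 0.085),
    "leg_length_ratio": (0.44, 0.52),
    "arm_length_ratio": (0.30, 0.40),
    "stride_amplitude_deg": (14.0, 40.0),
    "arm_amplitude_deg": (8.0, 34.0),
}
# frames per gait cycle, inclusive; brackets the ~13 frames/cycle typical of
# 25 fps walking video with inter-subject variation
_CYCLE_RANGE = (12, 20)


def generate_population(
    n_subjects: int,
    seqs_per_subject: int = 2,
    frames_per_seq: int = 40,
    seed: int = 0,
    *,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    target_height: int = DEFAULT_TARGET_HEIGHT,
    flip_probability: float = 0.002,
    align: bool = True,
) -> list[SilhouetteSequence]:
    """Generate a reproducible population of walking sequences.

    Each subject's shape/motion parameters are drawn once from the
    documented ranges using a single generator seeded with ``seed``;
    sequences of the same subject reuse them with a fresh phase offset and
    noise realization.  With ``align`` each frame is height-normalized and
    centroid-centered (the same operation applied to real silhouettes)
    before per-pixel flip noise is added.
    """
    if n_subjects < 2:
        raise ValueError("a population needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    sequences: list[SilhouetteSequence] = []
    for s in range(n_subjects):
        draws = {k: rng.uniform(*v) for k, v in _SUBJECT_RANGES.items()}
        params = WalkerParams(
            **draws,
            cycle_length=int(rng.integers(_CYCLE_RANGE[0], _CYCLE_RANGE[1] + 1)),
            flip_probability=flip_probability,
        )
        for q in range(seqs_per_subject):
            # a walker with an integer frame period only ever shows its
            # cycle_length discrete poses, so recordings of the same subject
            # differ by a whole-frame shift of the cycle, not an arbitrary
            # sub-frame phase
            shift = int(rng.integers(0, params.cycle_length))
            seq_params = replace(params, phase_offset=shift / params.cycle_length)
            frames = []
            for j in range(frames_per_seq):
                sil = render_walker(seq_params, j, canvas)
                if align:
                    sil = normalize_and_align(
                        sil, target_height=target_height, canvas=canvas, frame_index=j
                    )
                m = sil.mask
                if flip_probability > 0:
                    flips = rng.random(m.shape) < flip_probability
                    m = np.where(flips, 1 - m, m).astype(np.uint8)
                frames.append(BinarySilhouette(mask=m, frame_index=j))
            sequences.append(
                SilhouetteSequence(
                    frames=tuple(frames),
                    subject_id=f"s{s:03d}",
                    sequence_id=f"seq{q:02d}",
                    view_angle=90.0,
                )
            )
    return sequences
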