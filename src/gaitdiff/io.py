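"""Readers and writers for sequences, templates and projection bases.

Silhouette sequences live as directories of PNG/PGM frames, one file per
frame, time order given by zero-padded numeric filenames (non-numeric
names fall back to lexicographic order with a warning).  A CASIA-B-style
nested layout ``subject/sequence/angle/frame.png`` is parsed into labels
by :func:`parse_casia_layout`.

Templates persist as 16-bit grayscale PNG (value x 65535) with a sidecar
``.meta`` text header carrying kind/frame-count/provenance; bases as a
portable container with a JSON text header followed by flat little-endian
float64 arrays.  Both round-trips are bit-exact.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .features import ProjectionBasis
from .preprocess import BinarySilhouette
from .templates import GaitTemplate, SilhouetteSequence

__all__ = [
    "read_sequence",
    "write_sequence",
    "parse_casia_layout",
    "save_template",
    "load_template",
    "save_basis",
    "load_basis",
    "RunConfig",
]

_FRAME_EXTS = (".png", ".pgm")


def _frame_sort_key(path: Path):
    m = re.search(r"(\d+)", path.stem)
    if m is None:
        return None
    return int(m.group(1))


def _sorted_frame_paths(directory: Path) -> list[Path]:
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in _FRAME_EXTS)
    if not paths:
        raise FileNotFoundError(f"no frame images (*.png, *.pgm) in {directory}")
    keys = [_frame_sort_key(p) for p in paths]
    if any(k is None for k in keys):
        warnings.warn(
            f"non-numeric frame names in {directory}; using lexicographic order",
            stacklevel=2,
        )
        return paths
    return [p for _, p in sorted(zip(keys, paths), key=lambda kv: kv[0])]


def parse_casia_layout(directory: Path) -> dict[str, str]:
    """Labels from a ``subject/sequence/angle`` path tail (best effort)."""
    parts = Path(directory).parts
    out = {"subject_id": "", "sequence_id": "", "view_angle": "90"}
    if len(parts) >= 3:
        out = {"subject_id": parts[-3], "sequence_id": parts[-2], "view_angle": parts[-1]}
    elif len(parts) == 2:
        out = {"subject_id": parts[-2], "sequence_id": parts[-1], "view_angle": "90"}
    elif len(parts) == 1:
        out["sequence_id"] = parts[-1]
    return out


def read_sequence(directory: str | Path, *, labels: dict | None = None) -> SilhouetteSequence:
    """Read a directory of binary frame images as a silhouette sequence."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"sequence directory not found: {directory}")
    if labels is None:
        labels = parse_casia_layout(directory)
    frames = []
    for i, path in enumerate(_sorted_frame_paths(directory)):
        try:
            img = iio.imread(path)
        except Exception as exc:
            raise IOError(f"unreadable frame file {path}: {exc}") from exc
        if img.ndim == 3:
            img = img[..., 0]
        mask = (img > (img.max() / 2 if img.max() > 1 else 0)).astype(np.uint8)
        frames.append(BinarySilhouette(mask=mask, frame_index=i))
    angle = labels.get("view_angle", "90")
    angle = float(re.sub(r"[^\d.]", "", str(angle)) or 90)
    return SilhouetteSequence(
        frames=tuple(frames),
        subject_id=str(labels.get("subject_id", "")),
        sequence_id=str(labels.get("sequence_id", "")),
        view_angle=angle,
    )


def write_sequence(seq: SilhouetteSequence, directory: str | Path) -> None:
    """Write each frame as an 8-bit PNG (0/255), zero-padded filenames."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(seq.frames):
        iio.imwrite(directory / f"{i:04d}.png", (f.mask * 255).astype(np.uint8))


def save_template(template: GaitTemplate, path: str | Path) -> None:
    """Persist a template as 16-bit PNG plus a ``.meta`` sidecar."""
    path = Path(path)
    quantized = np.round(template.values * 65535.0).astype(np.uint16)
    iio.imwrite(path, quantized)
    meta = {
        "kind": template.kind,
        "n_frames_used": template.n_frames_used,
        "subject_id": template.subject_id,
        "sequence_id": template.sequence_id,
        "view_angle": template.view_angle,
        "scale": 65535,
    }
    path.with_suffix(path.suffix + ".meta").write_text(json.dumps(meta, indent=1))


def load_template(path: str | Path) -> GaitTemplate:
    path = Path(path)
    img = iio.imread(path).astype(float)
    meta_path = path.with_suffix(path.suffix + ".meta")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    scale = float(meta.get("scale", 65535))
    return GaitTemplate(
        values=img / scale,
        kind=meta.get("kind", "agdi"),
        n_frames_used=int(meta.get("n_frames_used", 0)),
        subject_id=str(meta.get("subject_id", "")),
        sequence_id=str(meta.get("sequence_id", "")),
        view_angle=float(meta.get("view_angle", 90.0)),
    )


_BASIS_MAGIC = b"GAITDIFF-BASIS-1\n"


def save_basis(basis: ProjectionBasis, path: str | Path) -> None:
    """Write a basis: magic line, JSON header with shapes, then the arrays
    (mean, covariance, eigenvalues, components) as flat little-endian float64."""
    arrays = {
        "mean_template": basis.mean_template,
        "covariance": basis.covariance,
        "eigenvalues": basis.eigenvalues,
        "components": basis.components,
    }
    header = {
        "n_components": basis.n_components,
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
        "dtype": "<f8",
    }
    blob = json.dumps(header).encode() + b"\n"
    with open(path, "wb") as fh:
        fh.write(_BASIS_MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for arr in arrays.values():
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def load_basis(path: str | Path) -> ProjectionBasis:
    with open(path, "rb") as fh:
        magic = fh.read(len(_BASIS_MAGIC))
        if magic != _BASIS_MAGIC:
            raise IOError(f"{path} is not a gaitdiff basis file")
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        arrays = {}
        for name, shape in header["shapes"].items():
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(count * 8)
            arrays[name] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
    return ProjectionBasis(n_components=int(header["n_components"]), **arrays)


@dataclass
class RunConfig:
    """Flat pipeline configuration; round-trips losslessly as ``key = value`` text."""

    canvas_height: int = 240
    canvas_width: int = 320
    target_height: int = 200
    blur_sigma: float = 1.0
    threshold_k: float = 2.5
    spread_floor: float = 1.0
    template_kind: str = "agdi"
    feature_method: str = "2dpca"
    n_components: int = 20
    protocol: str = "plain"
    seed: int = 0
    gallery_dir: str = ""
    probe_dir: str = ""

    def to_text(self) -> str:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno} is not 'key = value': {raw!r}")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"unknown config key {key!r} (line {lineno})")
            current = getattr(defaults, key)
            kwargs[key] = type(current)(value)
        return cls(**kwargs)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]
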