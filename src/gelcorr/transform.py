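"""Similarity transforms for gel-image alignment.

Gels are aligned to a reference with a 4-parameter similarity transform —
rotation, uniform scale, translation — and nothing more: no warping or other
non-rigid deformation, so the analysis cannot fabricate spot shapes.

Convention (fixed and serialized with every alignment file): a point
``p = (x, y)`` (x = column, rightwards; y = row, downwards) maps forward as

    F(p) = s * R(theta) * (p - c) + c + t

where ``c = ((W-1)/2, (H-1)/2)`` is the image center, ``theta`` is the
rotation in degrees counter-clockwise on screen, ``s`` the uniform scale and
``t = (tx, ty)`` the translation in pixels.  Resampling is by inverse
mapping; output pixels whose source coordinate falls outside the input
footprint become *missing data* (masked), never zeros fed to statistics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import SimilarityTransform as _SkSimilarity

from .errors import EstimationError, ParameterError
from .io import GelStack

logger = logging.getLogger(__name__)

_EDGE_EPS = 1e-9  # tolerance for "on the border" source coordinates
_ORDER = {"nearest": 0, "bilinear": 1}


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation (deg CCW about image center) + uniform scale + translation."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        params = (self.rotation_deg, self.scale, self.tx, self.ty)
        if not all(math.isfinite(p) for p in params):
            raise ParameterError(f"non-finite transform parameters {params}")
        if self.scale <= 0:
            raise ParameterError(f"scale must be > 0, got {self.scale}")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(0.0, 1.0, 0.0, 0.0)

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            abs(self.rotation_deg) <= tol
            and abs(self.scale - 1.0) <= tol
            and abs(self.tx) <= tol
            and abs(self.ty) <= tol
        )

    # -- linear-algebra helpers -------------------------------------------

    def _rot(self) -> np.ndarray:
        """Rotation matrix acting on (x, y) with y pointing down.

        Counter-clockwise on screen means clockwise in the y-down frame,
        hence the transposed sign pattern.
        """
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), math.sin(th)],
                         [-math.sin(th), math.cos(th)]])

    def apply_to_points(self, pts: np.ndarray, center=(0.0, 0.0)) -> np.ndarray:
        """Forward-map an (N, 2) array of (x, y) points."""
        pts = np.asarray(pts, dtype=float)
        c = np.asarray(center, dtype=float)
        t = np.array([self.tx, self.ty])
        return (self.scale * (self._rot() @ (pts - c).T)).T + c + t

    def invert(self) -> "SimilarityTransform":
        """The transform undoing this one (same center convention)."""
        rot_inv = SimilarityTransform(-self.rotation_deg, 1.0, 0.0, 0.0)._rot()
        t_inv = -(rot_inv @ np.array([self.tx, self.ty])) / self.scale
        return SimilarityTransform(
            -self.rotation_deg, 1.0 / self.scale, float(t_inv[0]), float(t_inv[1])
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
            "tx": self.tx,
            "ty": self.ty,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "SimilarityTransform":
        return cls(
            float(d.get("rotation_deg", 0.0)),
            float(d.get("scale", 1.0)),
            float(d.get("tx", 0.0)),
            float(d.get("ty", 0.0)),
        )


def invert(t: SimilarityTransform) -> SimilarityTransform:
    return t.invert()


def compose(t2: SimilarityTransform, t1: SimilarityTransform) -> SimilarityTransform:
    """The single transform equivalent to applying ``t1`` first, then ``t2``."""
    r2 = t2._rot()
    t1v = np.array([t1.tx, t1.ty])
    t2v = np.array([t2.tx, t2.ty])
    tv = t2.scale * (r2 @ t1v) + t2v
    return SimilarityTransform(
        t1.rotation_deg + t2.rotation_deg,
        t1.scale * t2.scale,
        float(tv[0]),
        float(tv[1]),
    )


def _image_center(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def apply_transform(
    image: np.ndarray,
    t: SimilarityTransform,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` under ``t``; returns (output, valid_mask).

    Output pixels are filled by inverse mapping with the chosen interpolation
    ("nearest" or "bilinear").  ``valid_mask`` is True exactly where the
    inverse-mapped source coordinate lies within [0, W-1] x [0, H-1]; other
    pixels are set to 0 and flagged invalid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError(f"expected 2D image, got shape {image.shape}")
    if interpolation not in _ORDER:
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    h, w = image.shape
    c = _image_center(image.shape)
    inv = t.invert()

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    src = inv.apply_to_points(pts, center=c)
    src_x = src[:, 0].reshape(h, w)
    src_y = src[:, 1].reshape(h, w)

    valid = (
        (src_x >= -_EDGE_EPS)
        & (src_x <= w - 1 + _EDGE_EPS)
        & (src_y >= -_EDGE_EPS)
        & (src_y <= h - 1 + _EDGE_EPS)
    )
    out = ndimage.map_coordinates(
        image, [src_y, src_x], order=_ORDER[interpolation], mode="constant", cval=0.0
    )
    out[~valid] = 0.0
    return out, valid


@dataclass
class AlignmentSet:
    """Per-sample transforms mapping each image onto the reference image."""

    reference_id: str
    transforms: dict[str, SimilarityTransform]

    def __post_init__(self) -> None:
        ref = self.transforms.get(self.reference_id)
        if ref is not None and not ref.is_identity(tol=1e-12):
            raise ParameterError(
                f"reference {self.reference_id!r} must carry the identity transform"
            )

    def completed(self, sample_ids: Iterable[str]) -> "AlignmentSet":
        """A copy with identity transforms filled in for unlisted samples."""
        tr = dict(self.transforms)
        for sid in sample_ids:
            tr.setdefault(sid, SimilarityTransform.identity())
        return AlignmentSet(self.reference_id, tr)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "reference_id": self.reference_id,
            "transforms": {sid: t.to_dict() for sid, t in self.transforms.items()},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignmentSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            reference_id=payload["reference_id"],
            transforms={
                sid: SimilarityTransform.from_dict(d)
                for sid, d in payload["transforms"].items()
            },
        )

    @classmethod
    def from_csv(cls, path: str | Path, reference_id: str) -> "AlignmentSet":
        df = pd.read_csv(path)
        needed = {"sample_id", "rotation_deg", "scale", "tx", "ty"}
        missing = needed - set(df.columns)
        if missing:
            raise ParameterError(f"alignment CSV missing columns {sorted(missing)}")
        transforms = {
            str(r.sample_id): SimilarityTransform(
                float(r.rotation_deg), float(r.scale), float(r.tx), float(r.ty)
            )
            for r in df.itertuples()
        }
        return cls(reference_id=reference_id, transforms=transforms)


def estimate_from_landmarks(
    src_points: Sequence[tuple[float, float]],
    dst_points: Sequence[tuple[float, float]],
    center: tuple[float, float] = (0.0, 0.0),
) -> SimilarityTransform:
    """Least-squares similarity transform mapping src landmarks onto dst.

    ``center`` is the rotation pivot used by this library's parameterization
    (pass the image center ``((W-1)/2, (H-1)/2)`` when the landmarks come
    from an image pair).  Uses the closed-form (Umeyama) least-squares
    similarity fit; the RMS residual is logged.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise EstimationError("src and dst must be matching (N, 2) point lists")
    if src.shape[0] < 2:
        raise EstimationError("need at least 2 landmark pairs")
    if np.allclose(src, src[0]):
        raise EstimationError("all source landmarks coincide; fit is degenerate")

    if hasattr(_SkSimilarity, "from_estimate"):
        sk = _SkSimilarity.from_estimate(src, dst)
        if not sk:
            raise EstimationError("similarity estimation failed")
    else:  # scikit-image < 0.26
        sk = _SkSimilarity()
        if not sk.estimate(src, dst):
            raise EstimationError("similarity estimation failed")
    s = float(sk.scale)
    theta_deg = -math.degrees(float(sk.rotation))  # skimage rotates CCW in y-down frame
    A = sk.params[:2, :2]
    T = sk.params[:2, 2]
    c = np.asarray(center, dtype=float)
    t = T - c + A @ c
    est = SimilarityTransform(theta_deg, s, float(t[0]), float(t[1]))
    resid = est.apply_to_points(src, center=c) - dst
    logger.info("landmark fit RMS residual: %.6g px",
                float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))))
    return est


def align_stack(
    stack: GelStack,
    alignment: AlignmentSet,
    interpolation: str = "bilinear",
) -> GelStack:
    """Resample every image in the stack by its transform.

    Existing per-pixel validity travels with the image (resampled nearest);
    pixels drawn from outside an image's footprint become invalid.
    """
    missing = [sid for sid in stack.sample_ids if sid not in alignment.transforms]
    if missing:
        raise ParameterError(f"no transform for samples {missing}")

    data = np.empty_like(stack.data)
    valid = np.empty_like(stack.valid)
    for i, sid in enumerate(stack.sample_ids):
        t = alignment.transforms[sid]
        if t.is_identity():
            data[i], valid[i] = stack.data[i], stack.valid[i]
            continue
        out, footprint = apply_transform(stack.data[i], t, interpolation)
        old_valid, _ = apply_transform(
            stack.valid[i].astype(float), t, interpolation="nearest"
        )
        data[i] = out
        valid[i] = footprint & (old_valid > 0.5)
    return GelStack(data=data, valid=valid, sample_ids=list(stack.sample_ids))


def _minmax_scale(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(np.min(img)), float(np.max(img))
    if hi <= lo:  # constant image: bright maps to 1, blank to 0
        return np.full_like(img, 1.0 if hi > 0 else 0.0)
    return (img - lo) / (hi - lo)


def render_overlay(image_a: np.ndarray, image_b: np.ndarray, alpha: float) -> np.ndarray:
    """Blend two images for visual alignment QC: (1-alpha)*A + alpha*B.

    Each input is min-max scaled to [0, 1] first so differently exposed gels
    blend comparably; the result is suitable for export as an 8-bit PNG.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"overlay shape mismatch: {a.shape} vs {b.shape}")
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    return (1.0 - alpha) * _minmax_scale(a) + alpha * _minmax_scale(b)
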