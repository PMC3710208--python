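"""Synthetic 2D-gel image stacks with known ground truth.

Real immunoblot series are rarely shareable, so every stage of the pipeline
is exercised against simulated stacks that reproduce the phenomenology the
method targets: chains of Gaussian spots whose amplitudes follow an external
covariate, horizontal streaking/laddering, spots that appear or disappear
along the series, global per-image exposure jitter, additive noise, and
known per-image misalignments.

The generator is deterministic given its seed, and hands back a
:class:`GroundTruth` holding the misalignments actually applied plus masks
of covariate-responsive pixels, so tests can score localization instead of
eyeballing heat maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import stats as sps

from .errors import ParameterError
from .io import GelStack, SampleRecord, write_manifest
from .transform import AlignmentSet, SimilarityTransform, apply_transform


@dataclass
class SpotSpec:
    """One anisotropic Gaussian spot; amplitude = base + slope * covariate.

    ``appear_at`` / ``disappear_at`` gate the spot to a covariate window
    (inclusive), emulating spots that appear and later vanish along a time
    course.  Amplitude is clamped at 0.
    """

    cx: float
    cy: float
    sx: float
    sy: float
    base_amplitude: float = 0.0
    slope: float = 0.0
    appear_at: float | None = None
    disappear_at: float | None = None

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ParameterError("spot widths sx, sy must be > 0")
        if self.base_amplitude < 0:
            raise ParameterError("base_amplitude must be >= 0")

    def amplitude(self, v: float) -> float:
        if self.appear_at is not None and v < self.appear_at:
            return 0.0
        if self.disappear_at is not None and v > self.disappear_at:
            return 0.0
        return max(0.0, self.base_amplitude + self.slope * v)

    def field(self, H: int, W: int) -> np.ndarray:
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        return np.exp(
            -((xx - self.cx) ** 2 / (2 * self.sx**2)
              + (yy - self.cy) ** 2 / (2 * self.sy**2))
        )


@dataclass
class StreakSpec:
    """Horizontal streak on row ``y`` spanning columns x_start..x_end inclusive."""

    y: int
    x_start: int
    x_end: int
    amplitude: float = 0.0
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.x_start > self.x_end:
            raise ParameterError("x_start must be <= x_end")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")

    def value(self, v: float) -> float:
        return max(0.0, self.amplitude + self.slope * v)

    def field(self, H: int, W: int) -> np.ndarray:
        out = np.zeros((H, W))
        out[self.y, self.x_start:self.x_end + 1] = 1.0
        return out


@dataclass
class SyntheticStackSpec:
    """Full description of a synthetic stack; one image per covariate value."""

    H: int
    W: int
    covariate_values: list[float]
    spots: list[SpotSpec] = field(default_factory=list)
    streaks: list[StreakSpec] = field(default_factory=list)
    background_level: float = 0.0
    noise_sd: float = 0.0
    per_image_scale: list[float] | None = None
    misalignments: list[SimilarityTransform] | None = None
    seed: int = 0
    covariate_name: str = "covariate"

    def __post_init__(self) -> None:
        n = len(self.covariate_values)
        if self.per_image_scale is None:
            self.per_image_scale = [1.0] * n
        if self.misalignments is None:
            self.misalignments = [SimilarityTransform.identity()] * n
        if len(self.per_image_scale) != n or len(self.misalignments) != n:
            raise ParameterError("per-sample vectors must match covariate length")
        if any(s <= 0 for s in self.per_image_scale):
            raise ParameterError("per_image_scale entries must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n(self) -> int:
        return len(self.covariate_values)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "H": self.H, "W": self.W,
            "covariate_values": list(map(float, self.covariate_values)),
            "covariate_name": self.covariate_name,
            "spots": [vars(s).copy() for s in self.spots],
            "streaks": [vars(s).copy() for s in self.streaks],
            "background_level": self.background_level,
            "noise_sd": self.noise_sd,
            "per_image_scale": list(map(float, self.per_image_scale)),
            "misalignments": [t.to_dict() for t in self.misalignments],
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticStackSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            H=d["H"], W=d["W"],
            covariate_values=d["covariate_values"],
            spots=[SpotSpec(**s) for s in d.get("spots", [])],
            streaks=[StreakSpec(**s) for s in d.get("streaks", [])],
            background_level=d.get("background_level", 0.0),
            noise_sd=d.get("noise_sd", 0.0),
            per_image_scale=d.get("per_image_scale"),
            misalignments=[
                SimilarityTransform.from_dict(t) for t in d["misalignments"]
            ] if "misalignments" in d else None,
            seed=d.get("seed", 0),
            covariate_name=d.get("covariate_name", "covariate"),
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring pipeline output.

    ``responsive_mask``: pixels whose noise-free modulation depth (range of
    the clean signal across the covariate series, in true/aligned
    coordinates) is at least half the maximum depth anywhere — the analogue
    of thresholding a result map at half max.  ``rho_sign`` holds the sign
    of the clean signal's Spearman correlation with the covariate (0 where
    unmodulated).  ``core_mask``: within 1 sigma of a responsive
    (slope > 0) spot center.  ``background_mask``: modulation depth below 1%
    of the maximum.
    """

    misalignments: list[SimilarityTransform]
    correction: AlignmentSet
    responsive_mask: np.ndarray
    rho_sign: np.ndarray
    core_mask: np.ndarray
    background_mask: np.ndarray
    clean_stack: np.ndarray


def _clean_field(spec: SyntheticStackSpec, v: float) -> np.ndarray:
    """Noise-free, unit-scale, unaligned image for covariate value v."""
    img = np.full((spec.H, spec.W), float(spec.background_level))
    for spot in spec.spots:
        amp = spot.amplitude(v)
        if amp > 0:
            img += amp * spot.field(spec.H, spec.W)
    for streak in spec.streaks:
        val = streak.value(v)
        if val > 0:
            img += val * streak.field(spec.H, spec.W)
    return img


def render_image(spec: SyntheticStackSpec, sample_index: int) -> np.ndarray:
    """Render sample ``sample_index``: scale, noise, misalign, clamp at 0."""
    if not 0 <= sample_index < spec.n:
        raise ParameterError(f"sample index {sample_index} out of range 0..{spec.n - 1}")
    v = spec.covariate_values[sample_index]
    img = spec.per_image_scale[sample_index] * _clean_field(spec, v)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, sample_index])
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    t = spec.misalignments[sample_index]
    if not t.is_identity():
        img, _ = apply_transform(img, t, interpolation="bilinear")
    return np.clip(img, 0.0, None)


def _ground_truth(spec: SyntheticStackSpec) -> GroundTruth:
    clean = np.stack([_clean_field(spec, v) for v in spec.covariate_values])
    depth = clean.max(axis=0) - clean.min(axis=0)
    max_depth = float(depth.max())
    if max_depth > 0:
        responsive = depth >= 0.5 * max_depth
        background = depth < 0.01 * max_depth
    else:
        responsive = np.zeros_like(depth, dtype=bool)
        background = np.ones_like(depth, dtype=bool)

    v = np.asarray(spec.covariate_values, dtype=float)
    rv = sps.rankdata(v)
    rvc = rv - rv.mean()
    ranks = sps.rankdata(clean.reshape(spec.n, -1), axis=0)
    rc = ranks - ranks.mean(axis=0)
    num = rvc @ rc
    rho_sign = np.sign(np.where(np.abs(num) < 1e-12, 0.0, num))
    rho_sign = rho_sign.reshape(spec.H, spec.W)
    rho_sign[depth == 0] = 0

    yy, xx = np.mgrid[0:spec.H, 0:spec.W].astype(float)
    core = np.zeros((spec.H, spec.W), dtype=bool)
    for spot in spec.spots:
        if spot.slope > 0:
            core |= (
                (xx - spot.cx) ** 2 / spot.sx**2
                + (yy - spot.cy) ** 2 / spot.sy**2
            ) <= 1.0

    sample_ids = [f"s{i:02d}" for i in range(spec.n)]
    correction = AlignmentSet(
        reference_id=sample_ids[0],
        transforms={
            sid: t.invert() for sid, t in zip(sample_ids, spec.misalignments)
        },
    )
    return GroundTruth(
        misalignments=list(spec.misalignments),
        correction=correction,
        responsive_mask=responsive,
        rho_sign=rho_sign,
        core_mask=core,
        background_mask=background,
        clean_stack=clean,
    )


def generate_stack(spec: SyntheticStackSpec) -> tuple[GelStack, GroundTruth]:
    """Render the whole stack (as captured, i.e. misaligned) plus ground truth.

    The returned stack's valid mask is all-true, mirroring freshly loaded
    camera images; applying ``GroundTruth.correction`` with
    :func:`gelcorr.transform.align_stack` restores registration and masks
    border pixels that left the canvas.
    """
    data = np.stack([render_image(spec, i) for i in range(spec.n)])
    stack = GelStack(
        data=data,
        valid=np.ones_like(data, dtype=bool),
        sample_ids=[f"s{i:02d}" for i in range(spec.n)],
    )
    return stack, _ground_truth(spec)


def write_fixture(
    stack: GelStack, spec: SyntheticStackSpec, out_dir: str | Path
) -> Path:
    """Write the stack as 16-bit PNGs + manifest + alignment + truth JSON.

    Returns the manifest path; loading it with gelcorr.io reproduces the
    stack exactly up to 16-bit quantization (values are clipped to
    0..65535 and rounded).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = _ground_truth(spec)
    records: list[SampleRecord] = []
    for i, sid in enumerate(stack.sample_ids):
        png = out_dir / f"{sid}.png"
        q = np.clip(np.round(stack.data[i]), 0, 65535).astype(np.uint16)
        iio.imwrite(png, q)
        records.append(
            SampleRecord(
                sample_id=sid,
                signal_path=png,
                include=True,
                variables={spec.covariate_name: repr(float(spec.covariate_values[i]))},
            )
        )
    manifest = write_manifest(records, out_dir / "manifest.csv")
    gt.correction.to_json(out_dir / "alignment.json")
    truth = {
        "misalignments": [t.to_dict() for t in spec.misalignments],
        "covariate_values": list(map(float, spec.covariate_values)),
        "responsive_mask": gt.responsive_mask.astype(int).tolist(),
        "seed": spec.seed,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth) + "\n")
    spec.to_json(out_dir / "spec.json")
    return manifest
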