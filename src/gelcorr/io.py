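"""Manifest and gel-image stack input/output.

A study is described by a plain CSV *manifest* with one row per biological
sample.  Mandatory columns are ``sample_id``, ``signal_path`` and
``include``; an optional ``standard_path`` column points at the fluorescent
alignment-standard image of the same membrane; every remaining column is an
external variable (numeric, or an ordered category label).

Images are 8- or 16-bit grayscale PNGs.  Stored intensities are preserved on
load (an 8-bit image yields floats in 0..255, a 16-bit one 0..65535); any
intensity normalization is a separate, explicit step.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatchError,
    EncodingError,
    ImageLoadError,
    ManifestError,
)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("sample_id", "signal_path", "include")
_RESERVED_COLUMNS = set(MANDATORY_COLUMNS) | {"standard_path"}
_TRUE_FLAGS = {"true", "1"}
_FALSE_FLAGS = {"false", "0"}


@dataclass
class SampleRecord:
    """One manifest row: image paths, inclusion flag and raw variable values."""

    sample_id: str
    signal_path: Path
    include: bool = True
    standard_path: Path | None = None
    variables: dict[str, str] = field(default_factory=dict)


@dataclass
class GelStack:
    """An ordered, co-registered stack of equally sized 2D gel images.

    Attributes
    ----------
    data : float array, shape (n, H, W)
        Pixel intensities, one layer per included sample.
    valid : bool array, shape (n, H, W)
        True where a pixel carries observed data.  All-true on load; pixels
        resampled from outside an image's footprint during alignment become
        invalid and are excluded from all downstream statistics.
    sample_ids : list of str
        Sample identifiers, in manifest order.
    """

    data: np.ndarray
    valid: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 3:
            raise DimensionMismatchError("stack data must be (n, H, W)")
        if self.valid.shape != self.data.shape:
            raise DimensionMismatchError(
                f"valid mask shape {self.valid.shape} != data shape {self.data.shape}"
            )
        if len(self.sample_ids) != self.data.shape[0]:
            raise DimensionMismatchError("one sample_id required per image")
        if self.n < 2:
            raise DimensionMismatchError("a stack needs at least 2 images")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def H(self) -> int:
        return self.data.shape[1]

    @property
    def W(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "GelStack":
        return GelStack(self.data.copy(), self.valid.copy(), list(self.sample_ids))


@dataclass
class ExternalVariable:
    """Per-sample numeric covariate, possibly rank-encoded from ordered categories."""

    name: str
    values: np.ndarray
    source_kind: str = "numeric"  # "numeric" | "ordered_categorical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise EncodingError(f"variable {self.name!r} has non-finite values")
        if np.unique(self.values).size < 2:
            raise EncodingError(
                f"variable {self.name!r} has fewer than 2 distinct values; "
                "correlation is undefined"
            )


def _parse_include(raw: str, sample_id: str) -> bool:
    token = str(raw).strip().lower()
    if token in _TRUE_FLAGS:
        return True
    if token in _FALSE_FLAGS:
        return False
    raise ManifestError(
        f"sample {sample_id!r}: include flag {raw!r} not one of true/false/1/0"
    )


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Parse a CSV manifest into :class:`SampleRecord` rows.

    Raises :class:`ManifestError` when a mandatory column is missing, a
    ``sample_id`` repeats, or an ``include`` flag is unparseable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ManifestError(f"manifest {path} is missing mandatory column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ManifestError(f"duplicate sample_id in manifest: {sorted(set(dup))}")

    var_columns = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    base = path.parent
    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        std = None
        if "standard_path" in df.columns and str(row["standard_path"]).strip():
            std = base / str(row["standard_path"])
        records.append(
            SampleRecord(
                sample_id=sid,
                signal_path=base / str(row["signal_path"]),
                include=_parse_include(row["include"], sid),
                standard_path=std,
                variables={c: row[c] for c in var_columns},
            )
        )
    return records


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> Path:
    """Write records back to a canonical CSV manifest (roundtrips with read_manifest)."""
    path = Path(path)
    var_columns: list[str] = []
    for rec in records:
        for name in rec.variables:
            if name not in var_columns:
                var_columns.append(name)
    has_standard = any(r.standard_path is not None for r in records)
    header = ["sample_id", "signal_path"]
    if has_standard:
        header.append("standard_path")
    header.append("include")
    header.extend(var_columns)
    base = path.parent

    def _rel(p: Path | None) -> str:
        if p is None:
            return ""
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [rec.sample_id, _rel(rec.signal_path)]
            if has_standard:
                row.append(_rel(rec.standard_path))
            row.append("true" if rec.include else "false")
            row.extend(str(rec.variables.get(c, "")) for c in var_columns)
            writer.writerow(row)
    return path


def _load_image(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageLoadError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        # RGB(A) export of a grayscale signal: average color channels.
        logger.info("image %s has %d channels; converting to gray by channel mean",
                    path, arr.shape[2])
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise ImageLoadError(f"image {path} is not 2D (shape {arr.shape})")
    return arr.astype(float)


def load_stack(records: Sequence[SampleRecord], use_standard: bool = False) -> GelStack:
    """Load the included samples' images into a :class:`GelStack`.

    ``use_standard`` selects each record's alignment-standard image instead of
    the signal image.  Intensities are kept in their stored units; no
    rescaling between 8- and 16-bit inputs is performed.
    """
    included = [r for r in records if r.include]
    for rec in records:
        if not rec.include:
            logger.info("sample %s excluded from the stack", rec.sample_id)
    if len(included) < 2:
        raise DimensionMismatchError("fewer than 2 included samples")

    images, ids = [], []
    shape: tuple[int, int] | None = None
    ref_path: Path | None = None
    for rec in included:
        if use_standard:
            if rec.standard_path is None:
                raise ImageLoadError(
                    f"sample {rec.sample_id!r} has no standard image but "
                    "use_standard was requested"
                )
            p = rec.standard_path
        else:
            p = rec.signal_path
        img = _load_image(p)
        if shape is None:
            shape, ref_path = img.shape, p
        elif img.shape != shape:
            raise DimensionMismatchError(
                f"image {p} has shape {img.shape} but {ref_path} has shape {shape}"
            )
        images.append(img)
        ids.append(rec.sample_id)
    data = np.stack(images)
    return GelStack(data=data, valid=np.ones_like(data, dtype=bool), sample_ids=ids)


def encode_variable(
    records: Sequence[SampleRecord],
    name: str,
    category_order: Sequence[str] | None = None,
) -> ExternalVariable:
    """Encode one manifest variable column numerically over included samples.

    Numeric cells pass through unchanged.  When ``category_order`` is given,
    every cell is treated as a category label and mapped to its 0-based rank
    in that order (Spearman correlation is rank-based, so any monotone
    encoding of an ordered scale is equivalent).
    """
    included = [r for r in records if r.include]
    raw: list[str] = []
    for rec in included:
        if name not in rec.variables or str(rec.variables[name]).strip() == "":
            raise EncodingError(
                f"sample {rec.sample_id!r} has no value for variable {name!r}"
            )
        raw.append(str(rec.variables[name]).strip())

    if category_order is not None:
        order: Mapping[str, int] = {lbl: i for i, lbl in enumerate(category_order)}
        missing = sorted({v for v in raw if v not in order})
        if missing:
            raise EncodingError(
                f"labels {missing} of variable {name!r} absent from category_order"
            )
        values = [float(order[v]) for v in raw]
        return ExternalVariable(name, np.array(values), "ordered_categorical")

    values = []
    for rec, v in zip(included, raw):
        try:
            values.append(float(v))
        except ValueError as exc:
            raise EncodingError(
                f"variable {name!r} value {v!r} (sample {rec.sample_id!r}) is not "
                "numeric; pass category_order for ordered categories"
            ) from exc
    return ExternalVariable(name, np.array(values), "numeric")
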