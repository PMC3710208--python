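"""Regions of interest, text export and heat-map rendering of result maps.

All pixel coordinates are 0-based with the origin at the top-left corner
(x = column, y = row); every exported file states this in its header block.
Exports are tab-delimited UTF-8 text with "." decimals at full float
precision, so they re-import bit-for-bit and are readable from R, MATLAB,
pandas etc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .errors import RoiError, UnknownMapError
from .stats import ResultMaps

logger = logging.getLogger(__name__)

_FMT = "%.17g"  # full double precision, roundtrip-exact
NAN_COLOR = (128, 128, 128)  # neutral gray for missing pixels in heat maps


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle: top-left (x0, y0) inclusive, width x height pixels."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise RoiError(f"ROI must cover >= 1 pixel, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise RoiError(f"ROI origin must be non-negative, got {self}")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise RoiError(f"ROI {self} exceeds map bounds {h}x{w} (HxW)")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )

    @classmethod
    def parse(cls, text: str) -> "ROI":
        """Parse the compact "x0,y0,width,height" form."""
        try:
            x0, y0, w, h = (int(tok) for tok in text.split(","))
        except ValueError as exc:
            raise RoiError(f"cannot parse ROI {text!r}; expected x0,y0,width,height") from exc
        return cls(x0, y0, w, h)


@dataclass
class RoiSummary:
    """NaN-aware per-map statistics over one ROI."""

    roi: ROI
    stats: dict[str, dict[str, float]]  # map name -> {mean,min,max,count_valid}


def summarize_roi(maps: ResultMaps, roi: ROI) -> RoiSummary:
    """Mean/min/max/valid-count of every result map over the ROI.

    Statistics ignore invalid (NaN) pixels; an ROI with no valid pixel yields
    NaN statistics with count_valid = 0 and a logged warning.
    """
    roi.check_bounds(maps.rho.shape)
    sl = roi.slices()
    out: dict[str, dict[str, float]] = {}
    for name in maps.map_names():
        patch = maps.get(name)[sl]
        n_valid = int(np.sum(np.isfinite(patch)))
        if n_valid == 0:
            logger.warning("ROI %s contains no valid pixels for map %s", roi, name)
            out[name] = {"mean": float("nan"), "min": float("nan"),
                         "max": float("nan"), "count_valid": 0}
        else:
            out[name] = {
                "mean": float(np.nanmean(patch)),
                "min": float(np.nanmin(patch)),
                "max": float(np.nanmax(patch)),
                "count_valid": n_valid,
            }
    return RoiSummary(roi=roi, stats=out)


def _header_lines(maps: ResultMaps) -> list[str]:
    lines = ["# gelcorr export",
             "# coordinates: 0-based, origin top-left, x=column y=row"]
    for key in sorted(maps.meta):
        lines.append(f"# {key}: {maps.meta[key]}")
    return lines


def _fmt(v: float) -> str:
    return "NaN" if not np.isfinite(v) else _FMT % v


def export_roi_text(summary: RoiSummary, maps: ResultMaps, path: str | Path) -> Path:
    """Write per-pixel ROI values plus summary rows as tab-delimited text."""
    path = Path(path)
    roi = summary.roi
    names = maps.map_names()
    lines = _header_lines(maps)
    lines.append(f"# roi: x0={roi.x0} y0={roi.y0} width={roi.width} height={roi.height}")
    lines.append("\t".join(["x", "y", *names]))
    for y in range(roi.y0, roi.y0 + roi.height):
        for x in range(roi.x0, roi.x0 + roi.width):
            vals = [_fmt(float(maps.get(n)[y, x])) for n in names]
            lines.append("\t".join([str(x), str(y), *vals]))
    for stat in ("mean", "min", "max", "count_valid"):
        vals = [_fmt(summary.stats[n][stat]) for n in names]
        lines.append("\t".join([f"summary_{stat}", "", *vals]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def export_map_text(maps: ResultMaps, which: str, path: str | Path) -> Path:
    """Write one H x W map as a tab-delimited grid after a settings header."""
    path = Path(path)
    grid = maps.get(which)  # raises UnknownMapError for bad names
    lines = _header_lines(maps)
    lines.append(f"# map: {which}")
    lines.append(f"# shape: {grid.shape[0]} {grid.shape[1]}")
    for row in grid:
        lines.append("\t".join(_fmt(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_map_text(path: str | Path) -> np.ndarray:
    """Re-import a grid written by :func:`export_map_text`."""
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rows.append([float(tok) for tok in line.split("\t")])
    return np.array(rows)


def render_heatmap(map2d: np.ndarray, kind: str, path: str | Path) -> Path:
    """Render a result map to an 8-bit RGB PNG heat map.

    ``signed`` maps (rho, products) use a diverging colormap symmetric about
    0 (range [-max|v|, +max|v|]); ``unsigned`` maps (p, sigma_norm) use a
    sequential colormap over [0, max].  NaN pixels are painted a neutral
    gray distinct from both colormap extremes.  Purely a view: the stored
    map values are never modified.
    """
    path = Path(path)
    grid = np.asarray(map2d, dtype=float)
    if grid.ndim != 2:
        raise UnknownMapError(f"heat map input must be 2D, got shape {grid.shape}")
    nan_mask = ~np.isfinite(grid)
    finite = grid[~nan_mask]
    if kind == "signed":
        cmap = colormaps["RdBu_r"]
        vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
        vmax = vmax or 1.0
        normed = (grid + vmax) / (2 * vmax)
    elif kind == "unsigned":
        cmap = colormaps["viridis"]
        vmax = float(np.max(finite)) if finite.size else 1.0
        vmax = vmax or 1.0
        normed = grid / vmax
    else:
        raise UnknownMapError(f"heat map kind must be 'signed' or 'unsigned', got {kind!r}")
    normed = np.clip(np.where(nan_mask, 0.0, normed), 0.0, 1.0)
    rgb = (cmap(normed)[..., :3] * 255).round().astype(np.uint8)
    rgb[nan_mask] = NAN_COLOR
    iio.imwrite(path, rgb)
    return path
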