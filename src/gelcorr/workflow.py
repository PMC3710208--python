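"""End-to-end analysis workflow: manifest in, maps/exports/run-log out.

These functions are the programmatic equivalent of a batch run: load a
manifest, optionally align to a reference, run the per-pixel correlation
analysis, and write every artifact (map text files, heat-map PNGs, ROI
exports, a run log) into an output directory.  Given the same inputs, config
and seed, the text outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import scipy

import gelcorr

from .errors import GelCorrError, ParameterError, StageError
from .io import encode_variable, load_stack, read_manifest
from .normalization import SCHEMES
from .roi import ROI, export_map_text, export_roi_text, render_heatmap, summarize_roi
from .stats import ResultMaps, TestConfig, run_analysis
from .transform import AlignmentSet, align_stack, render_overlay

_SIGNED_MAPS = {"rho", "CS", "CV", "CSD"}


@dataclass
class RunConfig:
    """Everything one analysis run needs; serialized into the run log."""

    manifest: str | Path
    variable: str
    category_order: list[str] | None = None
    alignment: str | Path | None = None
    normalization: str = "median"
    test: TestConfig = field(default_factory=TestConfig)
    min_valid: int | None = None
    rois: list[ROI] = field(default_factory=list)
    out_dir: str | Path = "gelcorr_out"
    use_standard_for_overlay: bool = True

    def __post_init__(self) -> None:
        if self.normalization not in SCHEMES:
            raise ParameterError(f"unknown normalization {self.normalization!r}")

    def to_dict(self) -> dict:
        return {
            "manifest": str(self.manifest),
            "variable": self.variable,
            "category_order": self.category_order,
            "alignment": None if self.alignment is None else str(self.alignment),
            "normalization": self.normalization,
            "test": vars(self.test).copy(),
            "min_valid": self.min_valid,
            "rois": [vars(r).copy() for r in self.rois],
            "out_dir": str(self.out_dir),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free helper: re-raise stage failures with a stage tag."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, GelCorrError) and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def analyze(config: RunConfig) -> ResultMaps:
    """Run the full pipeline and write all artifacts under ``config.out_dir``.

    Artifacts: ``<map>.txt`` and ``<map>.png`` for rho, sigma_norm, p, CS,
    CV, CSD; ``roi_<k>.txt`` per configured ROI; ``run_log.json`` with input
    checksums, settings and library versions.  Raises :class:`StageError`
    tagged with the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("manifest"):
        records = read_manifest(config.manifest)
        var = encode_variable(records, config.variable, config.category_order)
    with _stage("load"):
        stack = load_stack(records)
    if config.alignment is not None:
        with _stage("align"):
            alignment = AlignmentSet.from_json(config.alignment)
            alignment = alignment.completed(stack.sample_ids)
            stack = align_stack(stack, alignment)
    with _stage("analysis"):
        maps = run_analysis(
            stack, var,
            scheme=config.normalization,
            cfg=config.test,
            min_valid=config.min_valid,
        )

    with _stage("export"):
        for name in maps.map_names():
            export_map_text(maps, name, out / f"{name}.txt")
            kind = "signed" if name in _SIGNED_MAPS else "unsigned"
            render_heatmap(maps.get(name), kind, out / f"{name}.png")
        for k, roi in enumerate(config.rois):
            summary = summarize_roi(maps, roi)
            export_roi_text(summary, maps, out / f"roi_{k}.txt")
        log = {
            "config": config.to_dict(),
            "manifest_sha256": _sha256(Path(config.manifest)),
            "image_sha256": {
                r.sample_id: _sha256(Path(r.signal_path))
                for r in records if r.include
            },
            "meta": maps.meta,
            "versions": {
                "gelcorr": gelcorr.__version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "python": platform.python_version(),
            },
        }
        (out / "run_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True) + "\n"
        )
    return maps


def align_check(
    manifest: str | Path,
    alignment: str | Path | AlignmentSet,
    out_dir: str | Path,
    alpha: float = 0.5,
    use_standard: bool = True,
) -> list[Path]:
    """Write per-sample overlay PNGs against the reference for alignment QC.

    Uses the alignment-standard images when present (and ``use_standard``),
    so the check is blind to the biological signal.  Returns the written
    paths, one per non-reference sample.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with _stage("manifest"):
        records = read_manifest(manifest)
    if not isinstance(alignment, AlignmentSet):
        with _stage("align"):
            alignment = AlignmentSet.from_json(alignment)
    included = [r for r in records if r.include]
    have_standard = all(r.standard_path is not None for r in included)
    with _stage("load"):
        stack = load_stack(records, use_standard=use_standard and have_standard)
    with _stage("align"):
        unknown = set(alignment.transforms) - set(stack.sample_ids)
        if unknown:
            raise ParameterError(f"alignment names unknown samples {sorted(unknown)}")
        if alignment.reference_id not in stack.sample_ids:
            raise ParameterError(
                f"reference {alignment.reference_id!r} not in manifest"
            )
        aligned = align_stack(stack, alignment.completed(stack.sample_ids))

    ref_idx = aligned.sample_ids.index(alignment.reference_id)
    written: list[Path] = []
    with _stage("export"):
        for i, sid in enumerate(aligned.sample_ids):
            if i == ref_idx:
                continue
            blend = render_overlay(aligned.data[i], aligned.data[ref_idx], alpha)
            path = out / f"overlay_{sid}_vs_{alignment.reference_id}.png"
            iio.imwrite(path, np.round(blend * 255).astype(np.uint8))
            written.append(path)
    return written
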