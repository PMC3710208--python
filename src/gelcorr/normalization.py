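"""Per-image intensity normalization.

Gel-to-gel exposure and handling introduce global intensity differences that
would otherwise masquerade as biology in a pixel-wise correlation.  Three
per-image schemes are supported:

- ``mean``:    divide by the image's mean valid-pixel intensity
- ``median``:  divide by the median valid-pixel intensity (default elsewhere
               in the pipeline; robust to a handful of saturated spots)
- ``zscore``:  subtract the mean and divide by the population standard
               deviation (divisor N) of valid pixels
- ``none``:    pass through unchanged

Statistics are computed over *valid* pixels only, so border pixels masked by
alignment cannot bias the scale.  Masked-out pixel values are left unchanged
(and stay masked).
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateImageError, ParameterError
from .io import GelStack

SCHEMES = ("none", "mean", "median", "zscore")


def normalize_image(
    image: np.ndarray, mask: np.ndarray | None, scheme: str
) -> np.ndarray:
    """Apply one normalization scheme to a single image.

    Raises :class:`DegenerateImageError` when the scale statistic is zero
    (mean/median schemes) or the image is constant (zscore).
    """
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown normalization scheme {scheme!r}")
    image = np.asarray(image, dtype=float)
    if scheme == "none":
        return image.copy()
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = image[mask]
    if vals.size == 0:
        raise DegenerateImageError("image has no valid pixels")

    out = image.copy()
    if scheme == "mean":
        mu = float(np.mean(vals))
        if mu == 0.0:
            raise DegenerateImageError("mean of valid pixels is zero")
        out[mask] = image[mask] / mu
    elif scheme == "median":
        med = float(np.median(vals))
        if med == 0.0:
            raise DegenerateImageError("median of valid pixels is zero")
        out[mask] = image[mask] / med
    else:  # zscore
        mu = float(np.mean(vals))
        sigma = float(np.std(vals))  # population sigma, divisor N
        if sigma == 0.0:
            raise DegenerateImageError("image is constant; z-score undefined")
        out[mask] = (image[mask] - mu) / sigma
    return out


def normalize_stack(stack: GelStack, scheme: str) -> GelStack:
    """Normalize every image in the stack independently; masks are preserved.

    Per-image degeneracies are aggregated into one error naming the samples.
    """
    if scheme == "none":
        return stack.copy()
    out = np.empty_like(stack.data)
    failures: list[str] = []
    for i, sid in enumerate(stack.sample_ids):
        try:
            out[i] = normalize_image(stack.data[i], stack.valid[i], scheme)
        except DegenerateImageError as exc:
            failures.append(f"{sid}: {exc}")
            out[i] = stack.data[i]
    if failures:
        raise DegenerateImageError(
            "normalization failed for sample(s): " + "; ".join(failures)
        )
    return GelStack(data=out, valid=stack.valid.copy(), sample_ids=list(stack.sample_ids))
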