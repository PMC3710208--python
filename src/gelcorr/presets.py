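"""Ready-made synthetic stack specifications.

``p53_timecourse`` emulates a five-point irradiation time course of a heavily
modified tumour-suppressor protein: a horizontal chain of five loosely
connected spots (the full-length isoform at its charge-train positions) whose
amplitudes grow with time after stimulation, a "long tail" streak extending
toward the high-pI end that develops early and keeps growing, a new spot that
only appears mid-series, and two weaker short-isoform spots below and to the
left.  Per-image exposure jitter, additive camera noise (5% of the peak
modulation depth) and small known misalignments complete the picture.
"""

from __future__ import annotations

from .errors import ParameterError
from .simulate import SpotSpec, StreakSpec, SyntheticStackSpec
from .transform import SimilarityTransform


def p53_timecourse(seed: int = 0, misaligned: bool = True) -> SyntheticStackSpec:
    """Synthetic five-image time course with covariate hours = 0, 2, 4, 6, 8.

    Peak spot amplitude runs 300 -> 1260 counts across the series (slope 120
    per hour), so the 5% noise level is sd = 48 counts.  Set
    ``misaligned=False`` for a perfectly registered stack.
    """
    chain_y = 40.0
    spots = [
        SpotSpec(cx=cx, cy=chain_y, sx=3.5, sy=3.0,
                 base_amplitude=300.0, slope=120.0)
        for cx in (27.0, 37.0, 47.0, 57.0, 67.0)
    ]
    # spot appearing mid-series at the low-pI tip
    spots.append(SpotSpec(cx=18.0, cy=chain_y, sx=3.0, sy=2.5,
                          base_amplitude=150.0, slope=110.0, appear_at=4.0))
    # weaker short-isoform spots, below and left of the chain
    spots.append(SpotSpec(cx=20.0, cy=56.0, sx=3.0, sy=2.5,
                          base_amplitude=80.0, slope=15.0))
    spots.append(SpotSpec(cx=29.0, cy=56.0, sx=3.0, sy=2.5,
                          base_amplitude=60.0, slope=12.0))
    # ubiquitination-ladder style streaks toward high pI, growing with time
    streaks = [
        StreakSpec(y=40, x_start=70, x_end=88, amplitude=60.0, slope=75.0),
        StreakSpec(y=39, x_start=70, x_end=84, amplitude=40.0, slope=60.0),
    ]
    misalignments = [
        SimilarityTransform.identity(),
        SimilarityTransform(1.2, 1.004, 2.0, -1.5),
        SimilarityTransform(-0.8, 0.997, -1.5, 2.0),
        SimilarityTransform(0.6, 1.006, 1.0, 1.0),
        SimilarityTransform(-1.4, 0.995, -2.0, -1.0),
    ] if misaligned else None
    return SyntheticStackSpec(
        H=96, W=96,
        covariate_values=[0.0, 2.0, 4.0, 6.0, 8.0],
        covariate_name="hours",
        spots=spots,
        streaks=streaks,
        background_level=20.0,
        noise_sd=48.0,  # 5% of the 960-count peak modulation depth
        per_image_scale=[1.0, 1.15, 0.92, 1.08, 0.97],
        misalignments=misalignments,
        seed=seed,
    )


_PRESETS = {"p53_timecourse": p53_timecourse}


def get_preset(name: str, seed: int = 0, **kwargs) -> SyntheticStackSpec:
    """Look up a preset spec by name."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return factory(seed=seed, **kwargs)
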