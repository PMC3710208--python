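"""Pixel-by-pixel correlation statistics.

The core of the package: for every pixel coordinate (x, y) the vector of
intensities across the aligned, normalized stack (the *pixel column*) is
correlated against a per-sample external variable using Spearman rank
correlation.  Alongside the correlation map the module computes a normalized
standard-deviation map, a per-pixel p-value map (correlation t-test or
permutation test), and composite product maps such as

    CSD = correlation * significance * variance

which highlight pixels that are strongly, significantly *and* substantially
modulated — the "biosignature" of the protein's response.

Spearman correlation is Pearson correlation of midranks, so it is invariant
to any strictly monotone transform of either side; ordered categories encoded
as consecutive integers therefore behave identically to any other monotone
encoding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    EncodingError,
    InsufficientSamplesError,
    ParameterError,
    UndefinedCorrelationError,
    UnknownMapError,
)
from .io import ExternalVariable, GelStack
from .normalization import SCHEMES, normalize_stack

_TINY = np.finfo(float).tiny
_TIE_EPS = 1e-12  # slack when counting |rho_perm| >= |rho_obs| (float ties)
PRODUCT_FORMULAS: dict[str, list[str]] = {
    "CS": ["rho", "significance"],
    "CV": ["rho", "sigma_norm"],
    "CSD": ["rho", "significance", "sigma_norm"],
}


@dataclass
class TestConfig:
    """Configuration of the per-pixel significance test.

    ``permutation`` enumerates all n! orderings of the external variable when
    ``n! <= exhaustive_limit`` (exact two-sided p = #{|rho_perm| >= |rho_obs|}/n!)
    and otherwise falls back to ``n_permutations`` seeded Monte-Carlo draws
    with the add-one estimator p = (b+1)/(m+1), which never returns 0.
    """

    __test__ = False  # not a pytest class, despite the name

    test: str = "permutation"  # "t_test" | "permutation"
    n_permutations: int = 999
    exhaustive_limit: int = 40320  # 8!
    seed: int = 0
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if self.test not in ("t_test", "permutation"):
            raise ParameterError(f"unknown test {self.test!r}")
        if self.n_permutations < 99:
            raise ParameterError("n_permutations must be >= 99")
        if self.exhaustive_limit < 2:
            raise ParameterError("exhaustive_limit must be >= 2")
        if self.sidedness != "two_sided":
            raise ParameterError("only two_sided tests are supported")


@dataclass
class ResultMaps:
    """Co-registered result maps from one correlation analysis.

    Invalid pixels (too few valid samples, constant pixel column) carry NaN
    in every map and False in ``validity``.
    """

    rho: np.ndarray
    sigma_norm: np.ndarray
    p: np.ndarray
    products: dict[str, np.ndarray]
    validity: np.ndarray
    meta: dict = field(default_factory=dict)

    def map_names(self) -> list[str]:
        return ["rho", "sigma_norm", "p", *self.products]

    def get(self, name: str) -> np.ndarray:
        if name == "rho":
            return self.rho
        if name == "sigma_norm":
            return self.sigma_norm
        if name == "p":
            return self.p
        if name in self.products:
            return self.products[name]
        raise UnknownMapError(f"no result map named {name!r}; have {self.map_names()}")


# ---------------------------------------------------------------------------
# scalar statistics


def _check_column(v: np.ndarray, label: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ParameterError(f"{label} must be 1-D")
    if not np.all(np.isfinite(v)):
        raise ParameterError(f"{label} contains non-finite values")
    if np.unique(v).size < 2:
        raise UndefinedCorrelationError(f"{label} is constant; correlation undefined")
    return v


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Ties receive average ranks, so with no ties this equals the classical
    1 - 6*sum(d^2)/(n*(n^2-1)).
    """
    x = _check_column(np.asarray(x), "x")
    y = _check_column(np.asarray(y), "y")
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientSamplesError("need at least 3 samples")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float(rxc @ ryc / math.sqrt((rxc @ rxc) * (ryc @ ryc)))


def p_ttest(rho: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Two-sided p for H0: rho = 0 via the correlation t-test.

    t = rho*sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom; |rho| = 1
    clamps to the smallest positive float so downstream products never hit
    exactly 1 by rounding.  Broadcasts over arrays.
    """
    rho_arr = np.asarray(rho, dtype=float)
    n_arr = np.asarray(n)
    if np.any(n_arr < 4):
        raise InsufficientSamplesError("correlation t-test requires n >= 4")
    if np.any(np.abs(rho_arr) > 1 + 1e-12):
        raise ParameterError("|rho| must be <= 1")
    rho_arr = np.clip(rho_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_arr * np.sqrt((n_arr - 2) / (1.0 - rho_arr**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=n_arr - 2)
    p = np.where(np.abs(rho_arr) >= 1.0, _TINY, p)
    p = np.clip(p, _TINY, 1.0)
    return float(p) if np.isscalar(rho) and np.isscalar(n) else p


def _rank_rows(X: np.ndarray) -> np.ndarray:
    """Midranks along axis 0 (one rank vector per column)."""
    return sps.rankdata(X, axis=0)


def _all_permutations(v: np.ndarray) -> np.ndarray:
    return np.array(list(itertools.permutations(v.tolist())), dtype=float)


def p_permutation(
    x: Sequence[float], y: Sequence[float], cfg: TestConfig | None = None
) -> float:
    """Two-sided permutation p-value for the Spearman correlation of x and y.

    The null is generated by permuting ``y``; midranks are recomputed per
    permutation (with average ranks this equals permuting the rank vector, so
    ties travel with their values).
    """
    cfg = cfg or TestConfig()
    x = _check_column(np.asarray(x), "x")
    y = _check_column(np.asarray(y), "y")
    n = x.size
    rho_obs = spearman_rho(x, y)

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rxc = rx - rx.mean()
    xnorm = math.sqrt(float(rxc @ rxc))
    ryc_ss = float(((ry - ry.mean()) ** 2).sum())
    ynorm = math.sqrt(ryc_ss)

    if math.factorial(n) <= cfg.exhaustive_limit:
        perms = _all_permutations(ry)
        denom = perms.shape[0]
        null = (perms - ry.mean()) @ rxc / (xnorm * ynorm)
        count = int(np.sum(np.abs(null) >= abs(rho_obs) - _TIE_EPS))
        return count / denom
    rng = np.random.default_rng(cfg.seed)
    b = 0
    m = cfg.n_permutations
    for _ in range(m):
        perm = rng.permutation(ry)
        r = float((perm - perm.mean()) @ rxc / (xnorm * ynorm))
        if abs(r) >= abs(rho_obs) - _TIE_EPS:
            b += 1
    return (b + 1) / (m + 1)


# ---------------------------------------------------------------------------
# map-level statistics


def _pearson_on_ranks(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of X (shape (m, P)) against y (shape (m,))."""
    Xr = _rank_rows(X)
    yr = sps.rankdata(y)
    Xc = Xr - Xr.mean(axis=0)
    yc = yr - yr.mean()
    ssx = np.einsum("ij,ij->j", Xc, Xc)
    ssy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (yc @ Xc) / np.sqrt(ssx * ssy)
    rho[ssx == 0.0] = np.nan  # constant pixel column
    return rho


def _validity_groups(stack: GelStack):
    """Yield (pixel_indices, sample_mask) for each distinct validity pattern."""
    n = stack.n
    V = stack.valid.reshape(n, -1)
    if V.all():
        yield np.arange(V.shape[1]), np.ones(n, dtype=bool)
        return
    patterns, inverse = np.unique(V.T, axis=0, return_inverse=True)
    for k in range(patterns.shape[0]):
        yield np.where(inverse == k)[0], patterns[k].astype(bool)


def correlation_map(
    stack: GelStack, var: ExternalVariable, min_valid: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Spearman rho of the stack against the external variable.

    ``min_valid`` is the minimum number of valid samples a pixel needs
    (default: all samples).  Pixels below it, or with a constant intensity
    column, are masked (NaN, validity False).
    """
    n = stack.n
    if var.values.size != n:
        raise ParameterError(
            f"variable has {var.values.size} values but stack has {n} samples"
        )
    if np.unique(var.values).size < 2:
        raise EncodingError("external variable has fewer than 2 distinct values")
    min_valid = n if min_valid is None else max(int(min_valid), 3)

    rho = np.full(stack.H * stack.W, np.nan)
    for pix_idx, samp_mask in _validity_groups(stack):
        m = int(samp_mask.sum())
        if m < max(min_valid, 3):
            continue
        ysub = var.values[samp_mask]
        if np.unique(ysub).size < 2:
            continue
        Xsub = stack.data.reshape(n, -1)[samp_mask][:, pix_idx]
        rho[pix_idx] = _pearson_on_ranks(Xsub, ysub)
    rho = rho.reshape(stack.H, stack.W)
    validity = np.isfinite(rho)
    return rho, validity


def sigma_norm_map(stack: GelStack) -> np.ndarray:
    """Per-pixel sample std of intensities, scaled into [0, 1] by its global max.

    Uses divisor n-1 over the valid samples at each pixel (>= 2 required,
    else NaN); the normalizer is the maximum std over all valid pixels, so
    the most variable pixel maps to exactly 1.
    """
    counts = stack.valid.sum(axis=0)
    if not np.any(counts >= 2):
        raise UndefinedCorrelationError("no pixel has >= 2 valid samples")
    data = np.where(stack.valid, stack.data, 0.0)
    s1 = data.sum(axis=0)
    s2 = (data**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1**2 / counts) / (counts - 1)
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    sd[counts < 2] = np.nan
    vmax = np.nanmax(sd)
    if vmax > 0:
        sd = sd / vmax
    return sd


def permutation_p_map(
    stack: GelStack,
    var: ExternalVariable,
    cfg: TestConfig | None = None,
    min_valid: int | None = None,
    block: int = 1024,
) -> np.ndarray:
    """Per-pixel two-sided permutation p-value map (vectorized over pixels).

    Pixels are processed in blocks so that exhaustive enumeration (n_perm up
    to ``exhaustive_limit``) stays within memory.
    """
    cfg = cfg or TestConfig()
    n = stack.n
    min_valid = n if min_valid is None else max(int(min_valid), 3)
    p = np.full(stack.H * stack.W, np.nan)
    rng = np.random.default_rng(cfg.seed)

    for pix_idx, samp_mask in _validity_groups(stack):
        m = int(samp_mask.sum())
        if m < max(min_valid, 3):
            continue
        ysub = var.values[samp_mask]
        if np.unique(ysub).size < 2:
            continue
        ry = sps.rankdata(ysub)
        exhaustive = math.factorial(m) <= cfg.exhaustive_limit
        if exhaustive:
            perms = _all_permutations(ry)
        else:
            perms = np.array(
                [rng.permutation(ry) for _ in range(cfg.n_permutations)]
            )
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        ynorm = np.sqrt(np.einsum("ij,ij->i", perms_c, perms_c))
        yc = ry - ry.mean()

        X = stack.data.reshape(n, -1)[samp_mask][:, pix_idx]
        for start in range(0, pix_idx.size, block):
            sl = slice(start, start + block)
            Xr = _rank_rows(X[:, sl])
            Xc = Xr - Xr.mean(axis=0)
            xnorm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
            with np.errstate(invalid="ignore", divide="ignore"):
                obs = np.abs(yc @ Xc) / (xnorm * math.sqrt(float(yc @ yc)))
                null = np.abs(perms_c @ Xc) / np.outer(ynorm, xnorm)
                counts = (null >= obs[None, :] - _TIE_EPS).sum(axis=0)
                if exhaustive:
                    pvals = counts / perms.shape[0]
                else:
                    pvals = (counts + 1) / (perms.shape[0] + 1)
            pvals = np.where(xnorm == 0.0, np.nan, pvals)
            p[pix_idx[sl]] = pvals
    return np.clip(p.reshape(stack.H, stack.W), _TINY, 1.0)


def _significance_from_p(p: np.ndarray, mapping: str) -> np.ndarray:
    if mapping == "one_minus_p":
        return 1.0 - p
    if mapping == "neg_log10_p":
        return -np.log10(p)
    raise ParameterError(f"unknown significance mapping {mapping!r}")


def product_map(
    maps: Mapping[str, np.ndarray],
    formula: Sequence[str],
    p_to_significance: str = "one_minus_p",
) -> np.ndarray:
    """Element-wise product of named result maps.

    The factor name ``"significance"`` is derived from the ``p`` map via the
    chosen mapping (default ``1 - p``, which keeps the factor in [0, 1]).
    NaN propagates.
    """
    out: np.ndarray | None = None
    for name in formula:
        if name == "significance":
            if "p" not in maps:
                raise UnknownMapError("formula needs 'significance' but no 'p' map given")
            factor = _significance_from_p(np.asarray(maps["p"], dtype=float),
                                          p_to_significance)
        elif name in maps:
            factor = np.asarray(maps[name], dtype=float)
        else:
            raise UnknownMapError(f"unknown factor {name!r}; have {sorted(maps)}")
        out = factor.copy() if out is None else out * factor
    if out is None:
        raise ParameterError("empty product formula")
    return out


def run_analysis(
    stack: GelStack,
    var: ExternalVariable,
    scheme: str = "median",
    cfg: TestConfig | None = None,
    min_valid: int | None = None,
    p_to_significance: str = "one_minus_p",
) -> ResultMaps:
    """Full per-pixel analysis: normalize, correlate, test, compose products.

    Pipeline: per-image normalization -> Spearman rho map + normalized-std
    map + p map (t-test or permutation per ``cfg``) -> products CS (rho x
    significance), CV (rho x sigma_norm) and CSD (rho x significance x
    sigma_norm).  The returned meta dict records every setting needed to
    reproduce the run.
    """
    cfg = cfg or TestConfig()
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown normalization scheme {scheme!r}")

    norm = normalize_stack(stack, scheme)
    rho, validity = correlation_map(norm, var, min_valid)
    sigma = sigma_norm_map(norm)

    if cfg.test == "t_test":
        counts = norm.valid.sum(axis=0)
        validity = validity & (counts >= 4)
        p = np.full_like(rho, np.nan)
        ok = validity
        p[ok] = np.atleast_1d(p_ttest(rho[ok], counts[ok]))
    else:
        p = permutation_p_map(norm, var, cfg, min_valid)
        validity = validity & np.isfinite(p)

    for m in (rho, sigma, p):
        m[~validity] = np.nan

    maps = {"rho": rho, "sigma_norm": sigma, "p": p}
    products = {
        name: product_map(maps, formula, p_to_significance)
        for name, formula in PRODUCT_FORMULAS.items()
    }
    meta = {
        "variable": var.name,
        "variable_kind": var.source_kind,
        "normalization": scheme,
        "test": cfg.test,
        "n": stack.n,
        "seed": cfg.seed,
        "n_permutations": cfg.n_permutations,
        "exhaustive_limit": cfg.exhaustive_limit,
        "min_valid": stack.n if min_valid is None else int(min_valid),
        "significance_mapping": p_to_significance,
    }
    return ResultMaps(rho=rho, sigma_norm=sigma, p=p, products=products,
                      validity=validity, meta=meta)
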