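"""Treatment statistics: NDSI heatmaps, per-band t-tests and ratio trends.

The three analyses compare reflectance samples of stressed and control
plants:

* all-pairs normalized difference spectral index,
  ``NDSI[i, j] = (band_i - band_j) / (band_i + band_j)``, summarized per
  band pair either as the sample mean or as the point-biserial correlation
  between per-pixel NDSI and treatment membership (the r-value heatmap);
* wavelength-by-wavelength Welch two-sample t-tests, reported as a
  log10(p) spectrum with a p = 0.05 significance line;
* two-band reflectance ratio maps (e.g. R782/R544 for drought,
  R676/R743 for salinity) and their per-day mean ± SD time trends.

Point-biserial r and the pooled two-sample t statistic on the same pair are
algebraically linked by ``r^2 = t^2 / (t^2 + df)`` with ``df = n - 2``; the
r-matrices carry the pooled t and df so the identity is checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ReflectanceCube
from .errors import DegenerateSpectrumError, EmptyInputError
from .segmentation import PixelSet, TreatmentSample, nearest_band

__all__ = [
    "NDSIMatrix",
    "PValueSpectrum",
    "RatioMap",
    "vector_normalize",
    "ndsi_all_pairs",
    "ndsi_treatment_r",
    "wavelength_ttests",
    "welch_ttest",
    "ratio_map",
    "trend_series",
]

_TINY_P = np.finfo(float).tiny


@dataclass
class NDSIMatrix:
    """bands x bands NDSI summary (mean, correlation r, or p-value)."""

    values: np.ndarray
    kind: str  # "mean" | "r" | "p"
    wavelengths: np.ndarray
    n_a: int
    n_b: int | None = None
    t: np.ndarray | None = None  # pooled two-sample t per pair (kind == "r")
    df: int | None = None
    flagged_zero_variance: np.ndarray | None = None


@dataclass
class PValueSpectrum:
    """Per-band Welch t-test p-values for one treatment comparison."""

    p: np.ndarray
    log10_p: np.ndarray
    t: np.ndarray
    df: np.ndarray
    wavelengths: np.ndarray
    pair: tuple[str, str]
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha


@dataclass
class RatioMap:
    """Per-pixel two-band reflectance ratio image with a plant-pixel summary."""

    values: np.ndarray  # 2-D, NaN outside plant pixels / masked pixels
    numerator_nm: float
    denominator_nm: float
    day: int
    treatment: str
    mean: float
    sd: float
    n_pixels: int
    n_masked: int


def vector_normalize(sample: TreatmentSample) -> TreatmentSample:
    """Scale every pixel spectrum to unit Euclidean norm over its bands."""
    norms = np.linalg.norm(sample.values, axis=1)
    if np.any(norms == 0):
        pix = int(np.flatnonzero(norms == 0)[0])
        raise DegenerateSpectrumError(f"pixel {pix} has an all-zero spectrum")
    return replace(sample, values=sample.values / norms[:, None])


def _pair_moments(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-band-pair sum and sum-of-squares of per-pixel NDSI.

    Returns (S, Q), each (bands x bands), accumulated one numerator band at
    a time to keep memory at O(n_pixels * bands).  Pairs with a zero
    denominator at a pixel contribute nothing (they are masked); in
    practice reflectance > 0 makes this a no-op.
    """
    x = values
    n, b = x.shape
    s = np.empty((b, b))
    q = np.empty((b, b))
    for i in range(b):
        den = x[:, i, None] + x
        with np.errstate(divide="ignore", invalid="ignore"):
            nd = np.where(den != 0, (x[:, i, None] - x) / den, 0.0)
        s[i] = nd.sum(axis=0)
        q[i] = (nd * nd).sum(axis=0)
    return s, q


def ndsi_all_pairs(
    sample: TreatmentSample, *, keep_pixel_ndsi: bool = False
) -> NDSIMatrix | tuple[NDSIMatrix, np.ndarray]:
    """Mean NDSI over pixels for every ordered band pair.

    The result is antisymmetric with a zero diagonal and, for non-negative
    reflectance, bounded in [-1, 1].  With ``keep_pixel_ndsi=True`` the full
    (pixels x bands x bands) stack is also returned (small inputs only).
    """
    if sample.n_pixels == 0:
        raise EmptyInputError("empty sample")
    s, _ = _pair_moments(sample.values)
    matrix = NDSIMatrix(values=s / sample.n_pixels, kind="mean",
                        wavelengths=sample.wavelengths, n_a=sample.n_pixels)
    if not keep_pixel_ndsi:
        return matrix
    x = sample.values
    den = x[:, :, None] + x[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        stack = np.where(den != 0, (x[:, :, None] - x[:, None, :]) / den, 0.0)
    return matrix, stack


def ndsi_treatment_r(sample_a: TreatmentSample, sample_b: TreatmentSample) -> NDSIMatrix:
    """Point-biserial correlation of per-pixel NDSI with group membership.

    For every band pair the per-pixel NDSI values of both groups are pooled
    and correlated against the binary indicator (A = 0, B = 1).  Pairs with
    zero pooled variance get r = 0 and are flagged.  The pooled-variance
    two-sample t and its df = n - 2 ride along for the r/t identity.
    """
    if not np.array_equal(sample_a.wavelengths, sample_b.wavelengths):
        raise ValueError("samples must share the band grid")
    na, nb = sample_a.n_pixels, sample_b.n_pixels
    n = na + nb
    if na < 2 or nb < 2:
        raise EmptyInputError("each group needs at least 2 pixels")
    sa, qa = _pair_moments(sample_a.values)
    sb, qb = _pair_moments(sample_b.values)
    ma, mb = sa / na, sb / nb
    mean = (sa + sb) / n
    # population variance of the pooled per-pixel NDSI
    var_pop = (qa + qb) / n - mean**2
    var_pop = np.maximum(var_pop, 0.0)
    zero = var_pop <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mb - ma) / np.sqrt(var_pop) * np.sqrt(na * nb) / n
    r[zero] = 0.0
    # pooled-variance two-sample t for the identity r^2 = t^2/(t^2 + df)
    ssa = qa - na * ma**2
    ssb = qb - nb * mb**2
    sp2 = np.maximum(ssa + ssb, 0.0) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[zero] = 0.0
    off_diag_zero = zero & ~np.eye(zero.shape[0], dtype=bool)
    if off_diag_zero.any():  # the diagonal is identically zero by construction
        warnings.warn(
            f"{int(off_diag_zero.sum())} off-diagonal band pair(s) had zero pooled "
            "NDSI variance", stacklevel=2)
    return NDSIMatrix(values=r, kind="r", wavelengths=sample_a.wavelengths,
                      n_a=na, n_b=nb, t=t, df=n - 2,
                      flagged_zero_variance=zero if zero.any() else None)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch (unequal-variance) two-sample t-test along axis 0.

    Returns (t, df, p) per column.  Degenerate columns — zero variance in
    both groups — give p = 1 when the means are equal and p -> 0 when they
    differ.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise EmptyInputError("each group needs at least 2 observations per band")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    degenerate = se2 == 0
    p = np.empty_like(diff)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = _TINY_P
    with np.errstate(invalid="ignore"):
        t[degenerate] = np.sign(diff[degenerate]) * np.inf
    t[degenerate & (diff == 0)] = 0.0
    df[degenerate] = na + nb - 2
    p = np.clip(p, _TINY_P, 1.0)
    return t, df, p


def wavelength_ttests(
    sample_a: TreatmentSample, sample_b: TreatmentSample, alpha: float = 0.05
) -> PValueSpectrum:
    """Per-band Welch t-test between two treatment samples.

    Returns the p-value spectrum and its log10; bands with p < alpha are
    flagged significant, mirroring a log10(p) plot with a dashed
    log10(0.05) line.
    """
    if not np.array_equal(sample_a.wavelengths, sample_b.wavelengths):
        raise ValueError("samples must share the band grid")
    t, df, p = welch_ttest(sample_a.values, sample_b.values)
    return PValueSpectrum(p=p, log10_p=np.log10(p), t=t, df=df,
                          wavelengths=sample_a.wavelengths,
                          pair=(sample_a.treatment, sample_b.treatment), alpha=alpha)


def ratio_map(
    cube: ReflectanceCube,
    plant_pixels: PixelSet,
    numerator_nm: float,
    denominator_nm: float,
    *,
    day: int = 0,
    treatment: str = "control",
) -> RatioMap:
    """Two-band reflectance ratio image over plant pixels.

    Each plant pixel gets R(nearest band to numerator) / R(nearest band to
    denominator); everything else is NaN.  Pixels with non-positive
    denominator reflectance are masked and counted.
    """
    ib_num = nearest_band(cube.wavelengths, numerator_nm)
    ib_den = nearest_band(cube.wavelengths, denominator_nm)
    values = np.full(cube.data.shape[:2], np.nan)
    n_masked = 0
    if len(plant_pixels):
        ll, ss = plant_pixels.coords[:, 0], plant_pixels.coords[:, 1]
        num = cube.data[ll, ss, ib_num]
        den = cube.data[ll, ss, ib_den]
        good = den > 0
        n_masked = int(np.count_nonzero(~good))
        values[ll[good], ss[good]] = num[good] / den[good]
    finite = values[np.isfinite(values)]
    mean = float(finite.mean()) if finite.size else float("nan")
    sd = float(finite.std(ddof=1)) if finite.size > 1 else float("nan")
    return RatioMap(values=values, numerator_nm=float(cube.wavelengths[ib_num]),
                    denominator_nm=float(cube.wavelengths[ib_den]), day=day,
                    treatment=treatment, mean=mean, sd=sd,
                    n_pixels=int(finite.size), n_masked=n_masked)


def trend_series(maps: list[RatioMap]) -> pd.DataFrame:
    """Tabulate per-day mean ± SD of ratio maps by treatment.

    Days whose map has no plant pixels appear with NaN mean/SD rather than
    failing.  Columns: treatment, day, mean, sd, n_pixels.
    """
    if not maps:
        raise EmptyInputError("no ratio maps given")
    pairs = {(m.numerator_nm, m.denominator_nm) for m in maps}
    if len(pairs) > 1:
        raise ValueError(f"maps mix ratio definitions: {sorted(pairs)}")
    rows = [
        {"treatment": m.treatment, "day": m.day, "mean": m.mean, "sd": m.sd,
         "n_pixels": m.n_pixels}
        for m in maps
    ]
    return (pd.DataFrame(rows)
            .sort_values(["treatment", "day"])
            .reset_index(drop=True))
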