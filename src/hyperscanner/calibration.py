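"""White-panel calibration, CV-based band selection and edge exclusion.

The processing chain mirrors how a spectralon panel embedded in every scan
is used: pick the along-track scan line over the panel with the maximum
median radiance, divide the whole cube by that line's per-band spectrum
(``Rfl[i,j,k] = DN[i,j,k] / DN_white[k]``, wavelength by wavelength), keep
only bands whose along-track coefficient of variation over the panel is
below a threshold, and crop spatial/spectral edges to dodge smile and
keystone artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi_io import RadianceCube
from .errors import CalibrationError, EmptyBandMaskError, GeometryError

__all__ = [
    "WhiteReference",
    "ReflectanceCube",
    "BandMask",
    "select_white_line",
    "to_reflectance",
    "along_track_cv",
    "select_bands",
    "exclude_edges",
]


@dataclass
class WhiteReference:
    """Per-band radiance of the selected white-panel scan line.

    ``spectrum[k]`` is the mean DN over the panel columns of the single
    selected line — the denominator of the reflectance conversion.
    """

    spectrum: np.ndarray
    line_index: int
    panel_columns: tuple[int, int]


@dataclass
class ReflectanceCube:
    """Relative reflectance cube (lines x samples x bands) with wavelengths."""

    data: np.ndarray
    wavelengths: np.ndarray
    band_mask_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError("reflectance cube must be (line, sample, band) with matching wavelengths")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class BandMask:
    """High-SNR band selection result.

    ``keep[k]`` is True where the along-track CV is at or below
    ``threshold``; ``wl_range`` is the contiguous first-to-last kept band
    wavelength span (an outcome of the data, not a constant).
    """

    keep: np.ndarray
    wl_range: tuple[float, float]
    cv: np.ndarray
    threshold: float

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))


def _check_panel(cube: RadianceCube, panel_columns: tuple[int, int]) -> tuple[int, int]:
    lo, hi = int(panel_columns[0]), int(panel_columns[1])
    if not (0 <= lo < hi <= cube.n_samples):
        raise GeometryError(f"panel columns {panel_columns} outside cube width {cube.n_samples}")
    return lo, hi


def select_white_line(cube: RadianceCube, panel_columns: tuple[int, int]) -> WhiteReference:
    """Pick the panel scan line with the maximum median radiance.

    For every along-track line the median is pooled over all its panel
    pixels and bands; the argmax line wins, ties going to the lowest line
    index.  The returned spectrum is that line's per-band mean over the
    panel columns.
    """
    lo, hi = _check_panel(cube, panel_columns)
    region = np.asarray(cube.data[:, lo:hi, :], dtype=float)
    medians = np.median(region.reshape(cube.n_lines, -1), axis=1)
    line = int(np.argmax(medians))  # argmax returns the first (lowest) index on ties
    spectrum = region[line].mean(axis=0)
    if np.any(spectrum <= 0):
        bad = np.flatnonzero(spectrum <= 0)
        raise CalibrationError(
            f"white spectrum non-positive at band(s) {bad.tolist()[:5]}; reflectance undefined"
        )
    return WhiteReference(spectrum=spectrum, line_index=line, panel_columns=(lo, hi))


def to_reflectance(cube: RadianceCube, white: WhiteReference) -> ReflectanceCube:
    """Divide every pixel spectrum by the white reference, band by band."""
    if len(white.spectrum) != cube.n_bands:
        raise ValueError(
            f"white spectrum has {len(white.spectrum)} bands, cube has {cube.n_bands}"
        )
    if np.any(white.spectrum <= 0):
        raise CalibrationError("white spectrum must be positive at every band")
    data = np.asarray(cube.data, dtype=float) / white.spectrum[None, None, :]
    return ReflectanceCube(data=data, wavelengths=cube.wavelengths.copy())


def along_track_cv(cube: RadianceCube, panel_columns: tuple[int, int]) -> np.ndarray:
    """Along-track coefficient of variation of the panel, per band.

    The panel DN are first averaged over the panel columns of each line,
    then CV_k = sd / mean is taken over lines (sample sd, n-1).  Low CV
    marks high-SNR bands.
    """
    lo, hi = _check_panel(cube, panel_columns)
    if cube.n_lines < 2:
        raise CalibrationError("along-track CV needs at least 2 lines")
    profile = np.asarray(cube.data[:, lo:hi, :], dtype=float).mean(axis=1)  # (lines, bands)
    mean = profile.mean(axis=0)
    if np.any(mean == 0):
        bad = np.flatnonzero(mean == 0)
        raise CalibrationError(f"zero mean panel radiance at band(s) {bad.tolist()[:5]}: CV undefined")
    return profile.std(axis=0, ddof=1) / mean


def select_bands(cv: np.ndarray, wavelengths: np.ndarray, threshold: float = 0.02) -> BandMask:
    """Keep bands with CV <= threshold; report the kept wavelength span."""
    if threshold <= 0:
        raise ValueError("CV threshold must be positive")
    cv = np.asarray(cv, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    keep = cv <= threshold
    if not keep.any():
        raise EmptyBandMaskError(f"no band has CV <= {threshold}")
    kept_wl = wavelengths[keep]
    return BandMask(keep=keep, wl_range=(float(kept_wl[0]), float(kept_wl[-1])),
                    cv=cv, threshold=float(threshold))


def exclude_edges(
    cube: ReflectanceCube, spatial_margin: int = 2, spectral_margin: int = 0
) -> ReflectanceCube:
    """Crop spatial and spectral edges (smile/keystone mitigation).

    ``spatial_margin`` pixels are removed from each side of both spatial
    axes and ``spectral_margin`` bands from each end of the spectrum.
    """
    if spatial_margin < 0 or spectral_margin < 0:
        raise GeometryError("margins must be non-negative")
    if 2 * spatial_margin >= min(cube.n_lines, cube.n_samples) or 2 * spectral_margin >= cube.n_bands:
        raise GeometryError("margin is at least half the cube extent")
    sp = slice(spatial_margin, cube.n_lines - spatial_margin)
    ss = slice(spatial_margin, cube.n_samples - spatial_margin)
    sb = slice(spectral_margin, cube.n_bands - spectral_margin)
    return ReflectanceCube(
        data=cube.data[sp, ss, sb].copy(),
        wavelengths=cube.wavelengths[sb].copy(),
        band_mask_applied=cube.band_mask_applied,
    )
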