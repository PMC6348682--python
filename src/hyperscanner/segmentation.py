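"""Plant-pixel extraction and fixed-size pixel sampling.

Replaces the manual region-of-interest step of an interactive viewer with a
reproducible rule: a pixel is "plant" when its normalized difference of NIR
(~800 nm) and red (~676 nm) reflectance exceeds a threshold.  Statistics
then operate on a fixed-size random sample of plant pixels (n = 2000 by
default) drawn without replacement under an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import BandMask, ReflectanceCube
from .errors import ConfigurationError, EmptyInputError

__all__ = [
    "PixelSet",
    "TreatmentSample",
    "nearest_band",
    "extract_plant_pixels",
    "sample_pixels",
    "restrict_to_columns",
    "load_roi",
    "save_roi",
]


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm`` (ties: lower wl)."""
    wl = np.asarray(wavelengths, dtype=float)
    return int(np.argmin(np.abs(wl - target_nm)))  # argmin -> first, i.e. lower wl


@dataclass
class PixelSet:
    """Unique (line, sample) coordinates of one pixel class in a cube."""

    coords: np.ndarray  # (n, 2) int
    label: str = "plant"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class TreatmentSample:
    """n pixels x retained bands reflectance matrix for one treatment/day."""

    values: np.ndarray
    wavelengths: np.ndarray
    treatment: str = "control"
    day: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape[1] != len(self.wavelengths):
            raise ValueError("sample band count must match wavelength grid")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def extract_plant_pixels(
    cube: ReflectanceCube,
    mask: BandMask | None = None,
    *,
    panel_columns: tuple[int, int] | None = None,
    threshold: float = 0.3,
    red_nm: float = 676.0,
    nir_nm: float = 800.0,
) -> PixelSet:
    """Vegetation-index segmentation of a reflectance cube.

    A pixel is kept when ``(R_nir - R_red) / (R_nir + R_red) > threshold``
    with the nearest bands to ``nir_nm`` / ``red_nm``.  Columns inside
    ``panel_columns`` are excluded.  Raises :class:`ConfigurationError` if
    the required bands were removed by the band mask; an empty result is a
    warning, not an error.
    """
    ib_red = nearest_band(cube.wavelengths, red_nm)
    ib_nir = nearest_band(cube.wavelengths, nir_nm)
    if mask is not None and not (mask.keep[ib_red] and mask.keep[ib_nir]):
        raise ConfigurationError(
            f"bands near {red_nm} and {nir_nm} nm must be retained for segmentation"
        )
    red = cube.data[:, :, ib_red]
    nir = cube.data[:, :, ib_nir]
    den = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(den > 0, (nir - red) / den, 0.0)
    keep = ndvi > threshold
    if panel_columns is not None:
        lo, hi = panel_columns
        keep[:, lo:hi] = False
    coords = np.argwhere(keep)
    if len(coords) == 0:
        warnings.warn("no plant pixels found", stacklevel=2)
    return PixelSet(coords=coords, label="plant")


def sample_pixels(
    pixels: PixelSet,
    cube: ReflectanceCube,
    n: int = 2000,
    seed: int = 0,
    *,
    mask: BandMask | None = None,
    treatment: str = "control",
    day: int = 0,
) -> TreatmentSample:
    """Draw ``n`` plant pixels uniformly without replacement.

    ``n`` is capped at the available pixel count.  If a band mask is given,
    only retained bands enter the sample matrix.  The draw is deterministic
    under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(pixels) == 0:
        raise EmptyInputError("cannot sample from an empty pixel set")
    rng = np.random.default_rng(seed)
    take = min(n, len(pixels))
    idx = rng.choice(len(pixels), size=take, replace=False)
    coords = pixels.coords[idx]
    values = cube.data[coords[:, 0], coords[:, 1], :]
    wl = cube.wavelengths
    if mask is not None:
        values = values[:, mask.keep]
        wl = wl[mask.keep]
    return TreatmentSample(values=values, wavelengths=wl, treatment=treatment,
                           day=day, seed=seed)


def restrict_to_columns(pixels: PixelSet, columns: tuple[int, int]) -> PixelSet:
    """Keep only pixels whose sample coordinate lies in [lo, hi).

    Used to split the plant pixels of a paired scan into its trays (the
    tray positions are known from the scanning route).
    """
    lo, hi = columns
    keep = (pixels.coords[:, 1] >= lo) & (pixels.coords[:, 1] < hi)
    return PixelSet(coords=pixels.coords[keep], label=pixels.label)


def load_roi(path) -> PixelSet:
    """Read a plain-text ROI file of ``line,sample`` pairs (0-based)."""
    coords = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return PixelSet(coords=coords)


def save_roi(pixels: PixelSet, path) -> None:
    """Write coordinates as ``line,sample`` text lines."""
    np.savetxt(path, pixels.coords, fmt="%d", delimiter=",")
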