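"""Reading and writing hyperspectral cubes in the ENVI header + flat-binary format.

A cube on disk is a pair of files: a plain-text ``.hdr`` with ``key = value``
lines (plus a ``wavelength = { ... }`` list of band centers in nm) and a flat
binary payload in one of the three standard interleaves:

* ``bsq`` — band sequential, stored as (bands, lines, samples)
* ``bil`` — band interleaved by line, stored as (lines, bands, samples)
* ``bip`` — band interleaved by pixel, stored as (lines, samples, bands)

In memory every cube is canonical ``(line, sample, band)`` regardless of the
stored interleave.  Pushbroom line scanners emit line-major data, so ``bil``
is the default on write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EnviFormatError, MetadataError

__all__ = [
    "SensorProfile",
    "RadianceCube",
    "NANO",
    "read_envi",
    "write_envi",
]

INTERLEAVES = ("bil", "bsq", "bip")

# ENVI numeric data-type codes -> numpy dtypes (little-endian).
_DTYPE_BY_CODE = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_CODE_BY_DTYPE = {np.dtype(v): k for k, v in _DTYPE_BY_CODE.items()}


@dataclass(frozen=True)
class SensorProfile:
    """Geometry of a pushbroom (line-scan) imaging spectrometer.

    ``n_spatial`` cross-track pixels per scan line and ``n_bands`` spectral
    bands covering ``[wl_start, wl_end]`` nm.  Band centers are placed at the
    midpoints of equal-width spectral bins, so the sampling interval is
    ``(wl_end - wl_start) / n_bands``.
    """

    name: str
    n_spatial: int
    n_bands: int
    wl_start: float
    wl_end: float

    def __post_init__(self) -> None:
        if self.n_spatial < 1 or self.n_bands < 2:
            raise ValueError("profile needs n_spatial >= 1 and n_bands >= 2")
        if not self.wl_end > self.wl_start:
            raise ValueError("wl_end must exceed wl_start")

    @property
    def sampling(self) -> float:
        """Spectral sampling interval in nm per band."""
        return (self.wl_end - self.wl_start) / self.n_bands

    def wavelengths(self) -> np.ndarray:
        """Band-center wavelengths (nm), ascending, length ``n_bands``."""
        k = np.arange(self.n_bands)
        return self.wl_start + (k + 0.5) * self.sampling


#: The 640-pixel, 270-band VNIR (400-1000 nm) line-scanner profile used
#: throughout: its sampling interval is 600/270 ~ 2.2 nm per band.
NANO = SensorProfile("nano", n_spatial=640, n_bands=270, wl_start=400.0, wl_end=1000.0)


@dataclass
class RadianceCube:
    """Raw scanner product: lines x samples x bands digital numbers (DN).

    ``data`` is canonical ``(line, sample, band)``; ``wavelengths`` holds the
    band centers in nm (strictly ascending, one per band).  DN are
    non-negative counts; the dtype may be integer (real sensor) or float
    (synthetic scenes).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bil"
    note: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-axis (line, sample, band)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise MetadataError(
                f"wavelength count {len(self.wavelengths)} != band axis {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise MetadataError("wavelengths must be strictly ascending")
        if self.interleave not in INTERLEAVES:
            raise ValueError(f"interleave must be one of {INTERLEAVES}")
        if self.data.size and float(np.min(self.data)) < 0:
            raise ValueError("digital numbers must be non-negative")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


_REQUIRED_FIELDS = ("samples", "lines", "bands", "interleave", "data type")


def _parse_header(text: str, path: Path) -> dict:
    """Parse ENVI ``key = value`` header text into a dict (keys lowercased)."""
    # Brace-delimited values may span lines; normalise them first.
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([A-Za-z][A-Za-z0-9 _]*?)\s*=\s*(\{[^}]*\}|[^\n{]*)",
                         text, flags=re.MULTILINE | re.DOTALL):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    missing = [f for f in _REQUIRED_FIELDS if f not in fields]
    if missing:
        raise EnviFormatError(f"{path}: missing required header field(s): {', '.join(missing)}")
    return fields


def _find_data_file(header_path: Path) -> Path:
    base = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    for cand in (base, base.with_suffix(".img"), base.with_suffix(".dat")):
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no data file found next to header {header_path}")


def read_envi(header_path: str | Path) -> RadianceCube:
    """Read an ENVI header/binary pair into a canonical-order cube.

    Raises :class:`EnviFormatError` for missing/contradictory header fields
    and :class:`MetadataError` when the wavelength list length does not match
    the band count.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise EnviFormatError(f"header file not found: {header_path}")
    fields = _parse_header(header_path.read_text(), header_path)

    def _int(key: str) -> int:
        try:
            return int(fields[key])
        except ValueError as exc:
            raise EnviFormatError(f"{header_path}: field '{key}' is not an integer") from exc

    samples, lines, bands = _int("samples"), _int("lines"), _int("bands")
    if min(samples, lines, bands) < 1:
        raise EnviFormatError(f"{header_path}: non-positive extent in header")
    interleave = fields["interleave"].lower()
    if interleave not in INTERLEAVES:
        raise EnviFormatError(f"{header_path}: unknown interleave '{interleave}'")
    code = _int("data type")
    if code not in _DTYPE_BY_CODE:
        raise EnviFormatError(f"{header_path}: unsupported data type code {code}")
    dtype = np.dtype(_DTYPE_BY_CODE[code])
    byte_order = int(fields.get("byte order", "0"))
    if byte_order not in (0, 1):
        raise EnviFormatError(f"{header_path}: byte order must be 0 or 1")
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", "0"))

    wl_field = fields.get("wavelength")
    if wl_field is None:
        raise EnviFormatError(f"{header_path}: missing required header field(s): wavelength")
    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[\s,]+", wl_field.strip("{} \n")) if tok],
        dtype=float,
    )
    if len(wavelengths) != bands:
        raise MetadataError(
            f"{header_path}: wavelength list has {len(wavelengths)} entries for {bands} bands"
        )

    data_path = _find_data_file(header_path)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise MetadataError(
            f"{data_path}: payload has {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)
    return RadianceCube(
        data=np.ascontiguousarray(cube),
        wavelengths=wavelengths,
        interleave=interleave,
        note=fields.get("description", "").strip("{}").strip(),
    )


def _storage_dtype(data: np.ndarray) -> np.dtype:
    """uint16 when every DN is an integer that fits; float64 otherwise.

    Integer storage matches real sensor output; float cubes (synthetic
    scenes) are kept at full double precision so a write/read cycle is
    bit-lossless.
    """
    if np.issubdtype(data.dtype, np.integer):
        if data.size == 0 or (data.min() >= 0 and data.max() <= np.iinfo(np.uint16).max):
            return np.dtype(np.uint16)
        return np.dtype(np.int32)
    if data.size and np.all(np.isfinite(data)) and np.all(data == np.floor(data)) \
            and data.min() >= 0 and data.max() <= np.iinfo(np.uint16).max:
        return np.dtype(np.uint16)
    return np.dtype(np.float64)


def write_envi(cube: RadianceCube, path: str | Path, interleave: str = "bil") -> Path:
    """Write ``cube`` as an ENVI header/binary pair; returns the header path.

    ``path`` may be the header path (``*.hdr``) or a bare stem; the payload
    goes to ``<stem>.img``.  Round-trip through :func:`read_envi` is
    lossless for any interleave.
    """
    if interleave not in INTERLEAVES:
        raise ValueError(f"interleave must be one of {INTERLEAVES}")
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".hdr" else path
    header_path, data_path = stem.with_suffix(".hdr"), stem.with_suffix(".img")

    dtype = _storage_dtype(cube.data)
    data = cube.data.astype(dtype.newbyteorder("<"), copy=False)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    lines, samples, bands = cube.data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{{cube.note or 'hyperscanner cube'}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_BY_DTYPE[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    try:
        header_path.write_text(header)
        np.ascontiguousarray(out).tofile(data_path)
    except OSError as exc:
        raise EnviFormatError(f"cannot write ENVI pair at {stem}: {exc}") from exc
    return header_path
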