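"""Synthetic pushbroom scenes with known ground truth.

The generator emulates what the gantry-mounted VNIR line scanner sees while
passing over plant trays in a lit growth room: *Arabidopsis* rosettes
(rendered as disks) on potting soil, with a near-Lambertian spectralon strip
along one image edge serving as the white reference.  Every downstream stage
— white-line selection, reflectance conversion, CV band filtering,
vegetation-index segmentation and the treatment statistics — can be tested
against the returned :class:`SceneTruth`.

Forward model per pixel and band::

    DN[l, s, k] = R[l, s, k] * illumination[k] * gain * drift(l) * (1 + eps)

where ``R`` is the noise-free absolute reflectance, ``drift`` a small smooth
along-track illumination modulation and ``eps`` zero-mean Gaussian
multiplicative noise (relative sd ``noise_sd``, inflated in the first/last
few bands to mimic the low-SNR spectral edges of a real VNIR detector).

Treatment effects are multiplicative reflectance shifts confined to stated
wavelength intervals, growing linearly with days since stress onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi_io import RadianceCube, SensorProfile, NANO
from .errors import GeometryError, ParameterError

__all__ = [
    "SpectrumModel",
    "StressEffect",
    "TrayLayout",
    "SceneTruth",
    "evaluate_spectrum",
    "generate_scene",
    "plant_model",
    "soil_model",
    "panel_model",
    "drought_effect",
    "saline_effect",
    "default_layout",
    "MINI",
    "mini_layout",
    "scene_preset",
    "PANEL_REFLECTANCE",
    "SOIL",
    "PLANT",
    "PANEL",
]

# Class codes in SceneTruth.class_map
SOIL, PLANT, PANEL = 0, 1, 2

#: Reflectance of the calibrated spectralon white panel (flat across VNIR).
PANEL_REFLECTANCE = 0.99

#: Stress onset: treatments were applied on day 19; scanning ran day 20-26.
STRESS_ONSET_DAY = 19


@dataclass(frozen=True)
class SpectrumModel:
    """Parametric reflectance spectrum: baseline − Gaussian dips + red edge.

    ``absorption`` lists (center nm, width nm, depth) Gaussian absorption
    features; ``red_edge`` is (inflection nm, steepness /nm, NIR plateau)
    for the logistic reflectance rise of green vegetation, or ``None``.
    """

    baseline: float
    absorption: tuple[tuple[float, float, float], ...] = ()
    red_edge: tuple[float, float, float] | None = None
    label: str = "plant"


def evaluate_spectrum(model: SpectrumModel, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate a :class:`SpectrumModel` on a wavelength grid (nm).

    Returns reflectance in (0, 1]; raises :class:`ParameterError` if the
    configured features drive reflectance non-positive anywhere on the grid.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size and (wl.min() < 350.0 or wl.max() > 1100.0):
        raise ParameterError("wavelengths must lie within 350-1100 nm")
    refl = np.full_like(wl, float(model.baseline))
    for center, width, depth in model.absorption:
        if width <= 0:
            raise ParameterError(f"absorption width must be positive (got {width})")
        refl -= depth * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    if model.red_edge is not None:
        inflection, steepness, plateau = model.red_edge
        refl += plateau / (1.0 + np.exp(-steepness * (wl - inflection)))
    if refl.size and refl.min() <= 0.0:
        k = int(np.argmin(refl))
        raise ParameterError(
            f"spectrum model '{model.label}' non-positive at {wl[k]:.1f} nm"
        )
    return np.minimum(refl, 1.0)


def panel_model() -> SpectrumModel:
    """Spectralon white panel: flat 0.99 at all bands."""
    return SpectrumModel(baseline=PANEL_REFLECTANCE, label="panel")


def plant_model() -> SpectrumModel:
    """Healthy rosette leaf: chlorophyll/carotenoid absorption + red edge.

    Blue (~450 nm) and red (~670 nm) chlorophyll absorption dips leave the
    familiar green peak near 550 nm; the logistic red edge (inflection
    ~715 nm) lifts reflectance to a ~0.5 NIR plateau.
    """
    return SpectrumModel(
        baseline=0.12,
        absorption=((450.0, 25.0, 0.06), (670.0, 35.0, 0.07)),
        red_edge=(715.0, 0.06, 0.38),
        label="plant",
    )


def soil_model() -> SpectrumModel:
    """Potting soil: dim, featureless, slowly brightening toward the NIR."""
    return SpectrumModel(
        baseline=0.16,
        red_edge=(700.0, 0.004, 0.14),
        label="soil",
    )


@dataclass(frozen=True)
class StressEffect:
    """Treatment-dependent spectral shift.

    Each entry of ``bands`` is ``(lo nm, hi nm, shift, per_day_growth)``: on
    day ``d > onset_day`` reflectance at band centers inside [lo, hi] is
    multiplied by ``1 + shift + per_day_growth * (d - onset_day - 1)``, i.e.
    the base ``shift`` applies on the first post-onset day and grows
    linearly after that.
    """

    treatment: str
    bands: tuple[tuple[float, float, float, float], ...]
    onset_day: int = STRESS_ONSET_DAY

    def multiplier(self, wavelengths: np.ndarray, day: int) -> np.ndarray:
        """Per-band reflectance multiplier on the given day."""
        wl = np.asarray(wavelengths, dtype=float)
        mult = np.ones_like(wl)
        if day <= self.onset_day:
            return mult
        elapsed = day - self.onset_day - 1
        for lo, hi, shift, growth in self.bands:
            sel = (wl >= lo) & (wl <= hi)
            mult[sel] = 1.0 + shift + growth * elapsed
        if mult.min() <= 0.0:
            raise ParameterError(f"effect '{self.treatment}' drives reflectance <= 0")
        return mult

    def affected(self, wavelengths: np.ndarray) -> np.ndarray:
        """Boolean mask of band centers inside any configured interval."""
        wl = np.asarray(wavelengths, dtype=float)
        mask = np.zeros(wl.shape, dtype=bool)
        for lo, hi, _, _ in self.bands:
            mask |= (wl >= lo) & (wl <= hi)
        return mask


def drought_effect() -> StressEffect:
    """Default drought response: red-edge/NIR interval 700-900 nm."""
    return StressEffect("drought", bands=((700.0, 900.0, 0.04, 0.02),))


def saline_effect() -> StressEffect:
    """Default saline response: 500-650, 700-720 and 800-900 nm intervals.

    The 700-720 and 800-900 nm shifts equal the drought shift so that a
    drought-vs-saline comparison has a true null on the shared intervals;
    500-650 nm (pigment region) is saline-only and 720-800 nm drought-only.
    """
    return StressEffect(
        "saline",
        bands=(
            (500.0, 650.0, -0.06, -0.02),
            (700.0, 720.0, 0.04, 0.02),
            (800.0, 900.0, 0.04, 0.02),
        ),
    )


@dataclass(frozen=True)
class TrayLayout:
    """Side-by-side trays of potted rosettes rendered as disks.

    Each of ``n_trays`` trays is an ``n_rows`` x ``n_cols`` pot grid with
    centers spaced ``pitch`` pixels, the first tray's upper-left plant
    center at (``origin_line``, ``origin_sample``); each rosette is a disk
    of ``radius`` pixels.  Trays sit in disjoint cross-track column blocks,
    so one scan can carry differently-treated trays next to the shared
    white panel — the paired design every treatment comparison uses.
    """

    n_trays: int = 2
    n_rows: int = 3
    n_cols: int = 6
    origin_line: int = 25
    origin_sample: int = 120
    pitch: int = 45
    radius: int = 7

    def tray_origin_sample(self, tray: int) -> int:
        return self.origin_sample + tray * self.n_cols * self.pitch

    def centers(self, tray: int) -> list[tuple[int, int]]:
        o = self.tray_origin_sample(tray)
        return [
            (self.origin_line + r * self.pitch, o + c * self.pitch)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def tray_sample_bounds(self, tray: int) -> tuple[int, int]:
        """Half-open sample interval containing every disk of one tray."""
        o = self.tray_origin_sample(tray)
        return o - self.radius, o + (self.n_cols - 1) * self.pitch + self.radius + 1

    @property
    def n_plants(self) -> int:
        return self.n_trays * self.n_rows * self.n_cols


def default_layout() -> TrayLayout:
    """Two side-by-side 18-pot trays (3 x 6 each): 36 plants total."""
    return TrayLayout()


#: Scaled-down 60-band profile (same 400-1000 nm span) for fast runs.
MINI = SensorProfile("mini", n_spatial=256, n_bands=60, wl_start=400.0, wl_end=1000.0)


def mini_layout() -> TrayLayout:
    """Two 9-pot trays sized for the mini profile."""
    return TrayLayout(n_trays=2, n_rows=3, n_cols=3, origin_line=18,
                      origin_sample=60, pitch=26, radius=6)


def scene_preset(name: str) -> dict:
    """Bundle of (profile, layout, n_lines, panel_columns) for a named preset."""
    if name == "nano":
        return {"profile": NANO, "layout": default_layout(), "n_lines": 160,
                "panel_columns": (8, 56)}
    if name == "mini":
        return {"profile": MINI, "layout": mini_layout(), "n_lines": 84,
                "panel_columns": (4, 36)}
    raise ValueError(f"unknown scene preset '{name}'")


@dataclass
class SceneTruth:
    """Ground truth for a generated scene.

    ``reflectance`` is the noise-free *relative* reflectance (absolute
    reflectance divided by the 0.99 panel reflectance) — exactly what an
    ideal white-panel calibration recovers.  ``class_map`` holds SOIL /
    PLANT / PANEL codes; ``treatment_map`` is the treatment string for plant
    pixels and '' elsewhere.
    """

    class_map: np.ndarray
    treatment_map: np.ndarray
    tray_map: np.ndarray
    reflectance: np.ndarray
    illumination: np.ndarray
    gain: float
    panel_columns: tuple[int, int]
    noisy_edge_bands: np.ndarray
    seed: int

    @property
    def plant_mask(self) -> np.ndarray:
        return self.class_map == PLANT

    def treatment_mask(self, treatment: str) -> np.ndarray:
        return (self.class_map == PLANT) & (self.treatment_map == treatment)


def generate_scene(
    profile: SensorProfile = NANO,
    layout: TrayLayout | None = None,
    effect: StressEffect | None = None,
    day: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    effects_by_tray: list[StressEffect | None] | None = None,
    n_lines: int = 160,
    panel_columns: tuple[int, int] = (8, 56),
    gain: float = 4000.0,
    flat_illumination: bool = False,
    drift_amplitude: float = 0.01,
    edge_noise_factor: float = 6.0,
    n_edge_bands: int = 10,
    jitter_sd: float = 0.02,
) -> tuple[RadianceCube, SceneTruth]:
    """Render one scan as a radiance cube plus its ground truth.

    Parameters mirror the acquisition geometry: ``panel_columns`` is the
    half-open sample interval occupied by the spectralon strip (full image
    height), ``n_lines`` the along-track extent, ``noise_sd`` the relative
    sd of the multiplicative sensor noise and ``jitter_sd`` the relative sd
    of static per-pixel reflectance variability of plants and soil.  With
    ``flat_illumination=True`` and ``noise_sd=0`` the forward model is
    exactly invertible by white-panel calibration.

    A single ``effect`` applies to every tray; ``effects_by_tray`` assigns
    one effect (or ``None`` for control) per tray, which is how a paired
    control-vs-stress scan sharing one white panel is produced.

    Identical arguments and seed produce a bitwise-identical cube.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    layout = layout or default_layout()
    if effects_by_tray is None:
        effects_by_tray = [effect] * layout.n_trays
    if len(effects_by_tray) != layout.n_trays:
        raise GeometryError(
            f"got {len(effects_by_tray)} tray effects for {layout.n_trays} trays"
        )
    lo, hi = panel_columns
    if not (0 <= lo < hi <= profile.n_spatial):
        raise GeometryError(f"panel columns {panel_columns} outside image width")

    wl = profile.wavelengths()
    n_l, n_s, n_b = n_lines, profile.n_spatial, profile.n_bands

    class_map = np.full((n_l, n_s), SOIL, dtype=np.int8)
    class_map[:, lo:hi] = PANEL
    tray_map = np.full((n_l, n_s), -1, dtype=np.int8)
    ll, ss = np.ogrid[:n_l, :n_s]
    for tray in range(layout.n_trays):
        for cl, cs in layout.centers(tray):
            if not (layout.radius <= cl < n_l - layout.radius
                    and layout.radius <= cs < n_s - layout.radius) or cs - layout.radius < hi:
                raise GeometryError(
                    f"plant at ({cl},{cs}) r={layout.radius} overflows the image or panel strip"
                )
            disk = (ll - cl) ** 2 + (ss - cs) ** 2 <= layout.radius**2
            class_map[disk] = PLANT
            tray_map[disk] = tray

    spectra = np.stack(
        [
            evaluate_spectrum(soil_model(), wl),
            evaluate_spectrum(plant_model(), wl),
            evaluate_spectrum(panel_model(), wl),
        ]
    )
    rng = np.random.default_rng(seed)

    refl = spectra[class_map]  # (L, S, B) absolute reflectance
    # Static per-pixel brightness jitter (leaf angle, soil texture); the
    # panel is uniform by construction.
    jitter = 1.0 + jitter_sd * rng.standard_normal((n_l, n_s))
    jitter[class_map == PANEL] = 1.0
    refl *= np.abs(jitter)[:, :, None]

    treatment_map = np.full((n_l, n_s), "", dtype=object)
    treatment_map[class_map == PLANT] = "control"
    for tray, tray_effect in enumerate(effects_by_tray):
        if tray_effect is None:
            continue
        mult = tray_effect.multiplier(wl, day)
        plants = (class_map == PLANT) & (tray_map == tray)
        refl[plants] = refl[plants] * mult[None, :]
        treatment_map[plants] = tray_effect.treatment
    np.clip(refl, None, 1.0, out=refl)

    if flat_illumination:
        illumination = np.ones(n_b)
        drift = np.ones(n_l)
    else:
        # Halogen-like lamp: brightening toward the NIR; smooth along-track
        # bump so the white-line argmax is non-trivial.
        illumination = 0.4 + 0.6 * (wl - wl[0]) / (wl[-1] - wl[0])
        drift = 1.0 + drift_amplitude * np.sin(np.pi * np.arange(n_l) / max(n_l - 1, 1))

    dn = refl * illumination[None, None, :] * gain
    dn *= drift[:, None, None]

    band_sd = np.full(n_b, noise_sd)
    if n_edge_bands > 0:
        band_sd[:n_edge_bands] *= edge_noise_factor
        band_sd[-n_edge_bands:] *= edge_noise_factor
    if noise_sd > 0:
        dn *= 1.0 + band_sd[None, None, :] * rng.standard_normal((n_l, n_s, n_b))
        np.clip(dn, 0.0, None, out=dn)

    treatments = sorted({e.treatment if e else "control" for e in effects_by_tray})
    cube = RadianceCube(
        data=dn,
        wavelengths=wl,
        interleave="bil",
        note=f"synthetic {profile.name} scene, day {day}, "
             f"treatments {'/'.join(treatments)}, seed {seed}",
    )
    noisy_edges = np.zeros(n_b, dtype=bool)
    if n_edge_bands > 0 and edge_noise_factor > 1:
        noisy_edges[:n_edge_bands] = True
        noisy_edges[-n_edge_bands:] = True
    truth = SceneTruth(
        class_map=class_map,
        treatment_map=treatment_map,
        tray_map=tray_map,
        reflectance=refl / PANEL_REFLECTANCE,
        illumination=illumination,
        gain=gain,
        panel_columns=(lo, hi),
        noisy_edge_bands=noisy_edges,
        seed=seed,
    )
    return cube, truth
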