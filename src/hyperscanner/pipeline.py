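"""End-to-end analysis pipeline with a reproducibility manifest.

``run_pipeline`` wires the stages together for a whole experiment:
simulate (or load) one scan per treatment and day, calibrate against the
in-scene white panel, CV-filter the bands, segment plants, draw the fixed
pixel samples and produce the NDSI r-value heatmaps, per-band t-test
spectra and ratio-trend tables, writing everything plus a JSON run
manifest into an output directory.  Re-running a manifest's configuration
reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (along_track_cv, exclude_edges, select_bands,
                          select_white_line, to_reflectance)
from .envi_io import NANO, RadianceCube, write_envi
from .errors import ConfigurationError
from .segmentation import extract_plant_pixels, restrict_to_columns, sample_pixels
from .stress_stats import (ndsi_treatment_r, ratio_map, trend_series,
                           vector_normalize, wavelength_ttests)
from .synthetic_scene import (default_layout, drought_effect, generate_scene,
                              saline_effect)

__all__ = ["RunManifest", "default_config", "run_pipeline"]

_EFFECTS = {"drought": drought_effect, "saline": saline_effect, "control": lambda: None}

#: Two-band ratios used for the per-stress time trends (nm).
DEFAULT_RATIOS = {"drought": (782.0, 544.0), "saline": (676.0, 743.0)}


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, outputs, version."""

    command: str
    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    version: str = __version__

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def default_config() -> dict:
    """Demo configuration: 3 treatments x 7 scan days on the nano profile."""
    return {
        "profile": "nano",
        "treatments": ["control", "drought", "saline"],
        "days": [20, 21, 22, 23, 24, 25, 26],
        "stats_day": 20,
        "n_lines": 160,
        "panel_columns": [8, 56],
        "noise_sd": 0.05,
        "n_pixels": 2000,
        "cv_threshold": 0.02,
        "spatial_margin": 2,
        "vegetation_threshold": 0.3,
        "normalize": True,
        "ttest_on_normalized": False,
        "ratios": DEFAULT_RATIOS,
        "write_cubes": False,
        "plots": False,
    }


def _calibrate(cube: RadianceCube, panel_columns, cv_threshold, spatial_margin):
    white = select_white_line(cube, panel_columns)
    cv = along_track_cv(cube, panel_columns)
    mask = select_bands(cv, cube.wavelengths, cv_threshold)
    refl = to_reflectance(cube, white)
    if spatial_margin:
        refl = exclude_edges(refl, spatial_margin=spatial_margin)
    return refl, mask, white


def run_pipeline(config: dict | None = None, out_dir: str | Path = "hyperscan_run",
                 seed: int = 0) -> RunManifest:
    """Run simulate -> calibrate -> segment -> analyze -> report.

    The configuration must name a panel-column interval: every scan is
    required to include the white panel, otherwise reflectance conversion
    is impossible.  Returns the saved :class:`RunManifest`.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    if not cfg.get("panel_columns"):
        raise ConfigurationError(
            "no panel columns configured: every scan must include the white panel"
        )
    panel = tuple(cfg["panel_columns"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="run_pipeline", config=cfg, seed=seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    profile = NANO if cfg["profile"] == "nano" else cfg["profile"]
    day0 = cfg["stats_day"]
    # Paired design: each scan carries the two compared trays next to the
    # shared white panel, so calibration error cancels between groups.
    pairs = [(a, b) for i, a in enumerate(cfg["treatments"])
             for b in cfg["treatments"][i + 1:]]
    ratio_days = {
        (a, b): cfg["days"] if ("control" in (a, b)
                                and ({a, b} - {"control"}).pop() in cfg["ratios"])
        else [day0]
        for a, b in pairs
    }
    ss = np.random.SeedSequence(seed)
    keys = [(a, b, d) for a, b in pairs for d in ratio_days[(a, b)]]
    scene_seeds = {k: int(s.generate_state(1)[0] % (2**31))
                   for k, s in zip(keys, ss.spawn(len(keys)))}

    samples: dict[tuple[str, str, int, str], object] = {}
    maps: dict[tuple[str, str], list] = {}
    spatial_margin = int(cfg["spatial_margin"])
    layout = default_layout()
    for a, b in pairs:
        for day in ratio_days[(a, b)]:
            s = scene_seeds[(a, b, day)]
            cube, truth = generate_scene(
                profile, layout, effects_by_tray=[_EFFECTS[a](), _EFFECTS[b]()],
                day=day, noise_sd=cfg["noise_sd"], seed=s,
                n_lines=cfg["n_lines"], panel_columns=panel,
            )
            refl, mask, _ = _calibrate(cube, panel, cfg["cv_threshold"], spatial_margin)
            shifted_panel = (max(panel[0] - spatial_margin, 0), panel[1] - spatial_margin)
            pixels = extract_plant_pixels(
                refl, mask, panel_columns=shifted_panel,
                threshold=cfg["vegetation_threshold"],
            )
            stress = ({a, b} - {"control"}) or {a}
            for tray, treatment in enumerate((a, b)):
                t_lo, t_hi = layout.tray_sample_bounds(tray)
                tray_pixels = restrict_to_columns(
                    pixels, (t_lo - spatial_margin, t_hi - spatial_margin))
                sample = sample_pixels(tray_pixels, refl, n=cfg["n_pixels"],
                                       seed=s + tray, mask=mask,
                                       treatment=treatment, day=day)
                samples[(a, b, day, treatment)] = sample
                for st in stress:
                    if st in cfg["ratios"] and "control" in (a, b):
                        num, den = cfg["ratios"][st]
                        maps.setdefault((st, treatment), []).append(
                            ratio_map(refl, tray_pixels, num, den,
                                      day=day, treatment=treatment))
            if cfg.get("write_cubes"):
                hdr = write_envi(cube, out / f"scene_{a}_vs_{b}_day{day}.hdr")
                manifest.outputs.append(str(hdr))

    # Day-`stats_day` treatment statistics (NDSI r heatmaps + t-test spectra)
    stats_rows = []
    for a, b in pairs:
        sa, sb = samples[(a, b, day0, a)], samples[(a, b, day0, b)]
        if cfg["normalize"]:
            sa_n, sb_n = vector_normalize(sa), vector_normalize(sb)
        else:
            sa_n, sb_n = sa, sb
        rmat = ndsi_treatment_r(sa_n, sb_n)
        spec = wavelength_ttests(
            sa_n if cfg["ttest_on_normalized"] else sa,
            sb_n if cfg["ttest_on_normalized"] else sb,
        )
        tag = f"{a}_vs_{b}_day{day0}"
        rpath = out / f"ndsi_r_{tag}.csv"
        pd.DataFrame(rmat.values, index=rmat.wavelengths,
                     columns=rmat.wavelengths).to_csv(rpath)
        ppath = out / f"ttest_{tag}.csv"
        pd.DataFrame({"wavelength_nm": spec.wavelengths, "t": spec.t, "df": spec.df,
                      "p": spec.p, "log10_p": spec.log10_p,
                      "significant": spec.significant}).to_csv(ppath, index=False)
        manifest.outputs += [str(rpath), str(ppath)]
        stats_rows.append({"pair": tag, "n_significant": int(spec.significant.sum()),
                           "n_bands": len(spec.p),
                           "max_abs_r": float(np.max(np.abs(rmat.values)))})
        if cfg.get("plots"):
            _plot_pair(out, tag, rmat, spec, manifest)

    trends = []
    for (stress, treatment), mlist in maps.items():
        table = trend_series(mlist)
        table.insert(0, "comparison", stress)
        trends.append(table)
    trend_path = out / "ratio_trends.csv"
    if trends:
        pd.concat(trends, ignore_index=True).to_csv(trend_path, index=False)
    else:
        pd.DataFrame(columns=["comparison", "treatment", "day", "mean", "sd",
                              "n_pixels"]).to_csv(trend_path, index=False)
    summary_path = out / "stats_summary.csv"
    pd.DataFrame(stats_rows).to_csv(summary_path, index=False)
    manifest.outputs += [str(trend_path), str(summary_path)]

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    mpath = out / "manifest.json"
    manifest.save(mpath)
    manifest.outputs.append(str(mpath))
    return manifest


def _plot_pair(out: Path, tag: str, rmat, spec, manifest: RunManifest) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.2))
    im = ax1.imshow(rmat.values, origin="lower", cmap="RdBu_r", vmin=-1, vmax=1,
                    extent=[rmat.wavelengths[0], rmat.wavelengths[-1]] * 2)
    ax1.set_xlabel("band j (nm)")
    ax1.set_ylabel("band i (nm)")
    ax1.set_title(f"NDSI r-value: {tag}")
    fig.colorbar(im, ax=ax1, shrink=0.85)
    ax2.plot(spec.wavelengths, spec.log10_p, lw=1)
    ax2.axhline(np.log10(spec.alpha), ls="--", color="k", label="p = 0.05")
    ax2.set_xlabel("wavelength (nm)")
    ax2.set_ylabel("log10 p")
    ax2.set_title(f"per-band Welch t-test: {tag}")
    ax2.legend()
    fig.tight_layout()
    png = out / f"fig_{tag}.png"
    fig.savefig(png, dpi=110)
    plt.close(fig)
    manifest.outputs.append(str(png))
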