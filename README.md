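# hyperscanner

Software for lab-scale hyperspectral plant-stress phenotyping with a
gantry-mounted pushbroom VNIR spectrometer, in two halves:

1. **Image analysis.** ENVI cube I/O, white-panel reflectance calibration,
   signal-to-noise band selection, rosette segmentation, and the treatment
   statistics used to detect drought and salinity stress in *Arabidopsis*:
   all-pairs normalized difference spectral indices (NDSI), per-wavelength
   Welch t-tests and two-band ratio time trends. A synthetic scene
   generator with complete ground truth stands in for the scanner, so every
   stage is testable end to end.
2. **Motion control.** A software twin of the CNC scanning gantry: the
   12-byte binary instruction set (three little-endian signed 32-bit
   integers per command), strict FIFO execution with travel-limit
   enforcement, serpentine route planning and scan-time simulation.

It is written for plant scientists and imaging engineers who want a
reproducible, scriptable replacement for the manual viewer-based processing
chain, or a safe place to develop scan routines before touching hardware.

## The core computations

A scan is a cube of digital numbers `DN[i, j, k]` (line, sample, band) from a
640-pixel x 270-band line scanner covering 400–1000 nm (2.2 nm sampling).
Each scan includes a 99%-reflectance spectralon strip. Calibration:

* **White reference** — the along-track line over the panel with the maximum
  pooled median radiance; its per-band mean spectrum is `DN_white[k]`.
* **Relative reflectance** — `Rfl[i, j, k] = DN[i, j, k] / DN_white[k]`,
  band by band.
* **Band selection** — keep bands whose along-track coefficient of variation
  (sd/mean over panel lines) is at or below a threshold (default 2%); the
  noisy spectral edges drop out.

Statistics on `n = 2000` plant pixels per treatment group:

* **NDSI** — `NDSI[i, j] = (R_i − R_j) / (R_i + R_j)` for every band pair,
  summarized as the point-biserial correlation `r` between per-pixel NDSI
  and group membership (with the pooled t and `df = n − 2` attached;
  `r² = t² / (t² + df)` exactly).
* **Per-band t-tests** — Welch two-sample tests per wavelength, plotted as
  `log10(p)` against the `p = 0.05` line.
* **Ratio trends** — per-pixel two-band ratios (R782/R544 for drought,
  R676/R743 for salinity) tracked as mean ± SD per day.

Compared treatment groups are always the two trays of a *single* scan
sharing one white panel, so calibration error cancels under the null — see
`docs/methods.md` for why this matters.

## Worked example

`python examples/02_stress_statistics.py` builds one paired scan (control
tray + drought tray), calibrates it, and runs the statistics:

```
20/40 bands significant at p < 0.05
significant range: 705-895 nm (drought effect was injected at 700-900 nm)
strongest band: 795 nm, log10 p = -39.3
strongest NDSI pair: (535, 765) nm, r = -0.346  (|r|=1 would mean perfect group separation)
```

The t-tests localise the injected drought response to exactly the red-edge /
NIR interval where it was simulated, and the strongest NDSI pair combines
one affected with one unaffected band — the same qualitative picture a
drought heatmap shows on real scans. The other examples cover calibration
(`01`), the 7-day ratio trend (`03`) and the gantry controller (`04`).

There is also a CLI for shell use:

```bash
hyperscan simulate --profile mini --treatment drought --out scan.hdr
hyperscan calibrate --in scan.hdr --panel-cols 4:36 --out refl.hdr
hyperscan demo --out report/        # full simulate->analyze pipeline
hyperscan gantry --route route.txt --speed 1 --z 30 --trace trace.csv
```

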