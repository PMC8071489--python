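# gmrspec

Simulation and quantification for a compact spectral detection platform:
a **gradient grating-period guided-mode-resonance (GGP-GMR) filter** mounted
on a linear CCD, used to read fluorescent and colorimetric liquid assays
without a spectrometer.

## The idea

A guided-mode-resonance filter is a bandstop element: at normal incidence it
reflects the one wavelength that phase-matches its guided mode, given by the
second-order Bragg condition

```
λ_R = n_eff(λ_R) · Λ
```

where `Λ` is the grating period and `n_eff` the effective index of the
fundamental TE mode. Chaining segments of linearly increasing period
(250–550 nm in 2-nm steps, 100 cycles each) makes the rejected wavelength
increase along the device, so a linear CCD underneath sees a transmission
*dip* whose position encodes the incident peak wavelength and whose depth
scales with its intensity. The readout is linear:

```
C = T · I
```

with `T_ij` the transmission at pixel `i` for wavelength `j` and `I` the
incident spectrum. The **minimum-intensity corresponding pixel (MICP)** of
`C`, mapped through a monochromatic-scan calibration curve, recovers the
peak wavelength; its intensity feeds dose-response curves. Assay figures of
merit follow the 3σ convention: noise = 3 × pooled replicate SD of
normalized intensity, sensitivity = dose-response slope (per 10 mg/L), and
LOD = noise / sensitivity.

The package provides, as library modules plus a thin CLI:

* `materials` / `waveguide` / `filter_model` — layer dispersion, the TE
  slab-mode effective index (with effective-medium homogenization of the
  grating layer), the Bragg fixed point, and the gradient layout;
* `instrument` — CCD geometry (anchored to the reported 2073 ↔ 500 nm /
  2361 ↔ 700 nm pixel numbering), Lorentzian resonance lineshape, the
  transmission matrix, and the noisy readout `C = TI`;
* `calibration` — monochromatic scans, sub-pixel MICP location, and the
  monotone wavelength ↔ pixel curve;
* `assay_sim` — synthetic fluorescent (rhodamine-like dye, albumin-blue
  580) and colorimetric (Jaffe creatinine kinetics, bromocresol-green
  albumin) experiments with replicate structure and a full seed ledger;
* `quantify` — MICP extraction, per-run normalization, OLS dose-response
  fits, noise/LOD statistics, and cross-instrument comparison against the
  simulated reference spectrometer channel.

## Worked example

Run the whole chain on the simulated albumin fluorescence assay (7
concentrations 6.25–200 mg/L plus a blank, 3 runs):

```bash
gmrspec run-all --preset hsa-fluorescent --seed 1 --out out/
```

This writes `layout.csv`, `calibration.csv`, a dataset of paired CCD
traces/spectra, dose-response tables for both channels, `report.json` and
`comparison.json`. With the default (low-noise) instrument settings the
report contains:

```
ggp-gmr:       slope 0.0365 per 10 mg/L, R² 1.000, noise 0.00023, LOD 0.06 mg/L
spectrometer:  slope 0.0369 per 10 mg/L, R² 1.000, noise 0.00407, LOD 1.10 mg/L
comparison:    slope 0.988, R² 1.000 (24 paired measurements)
```

Reading: both channels see the same linear dose response (slope ≈ 0.037
normalized units per 10 mg/L — the blank intercept ≈ 0.27 is free-dye
fluorescence), and the cross-instrument regression slope/R² near 1 shows the
compact filter/CCD readout reproduces the spectrometer channel. The LODs
here reflect the configured detector noise; with experimentally measured
noise levels (normalized 3σ of 0.1517 and 0.0730) the same arithmetic gives

```python
>>> from gmrspec import lod_from_noise_sensitivity
>>> lod_from_noise_sensitivity(0.1517, 0.037).lod
41.0
>>> lod_from_noise_sensitivity(0.0730, 0.042).lod
17.38
```

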