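# Methods

## Device model

The filter is a three-layer stack: a PET substrate, a UV-cured adhesive
(NOA 68) grating replica, and a sputtered TiO2 waveguiding film, with air
above. The grating period increases along the device from 250 to 550 nm in
2-nm steps, 100 cycles per period, so the device is a concatenation of 151
constant-period segments (total 6.04 mm; the 500–700 nm band uses ~2.0 mm).

Resonance is modeled by the second-order Bragg condition `λ_R = n_eff(λ_R)·Λ`
solved as a damped fixed point (damping 0.7, tolerance 1e-6 nm, at most 100
iterations, accepted on 400–1100 nm). Two effective-index models are
provided:

* **weighted-average** — thickness-weighted mean of the coating index and
  the duty-weighted grating-layer index. Fast, dispersion-poor; kept as the
  simple mental model.
* **slab-mode** (default) — the 85-nm grating layer is homogenized with
  zeroth-order TE effective-medium theory, `n² = f·n_ridge² + (1−f)·n_groove²`
  (ridges NOA 68, grooves filled by sputtered TiO2, duty f = 0.5), and the
  fundamental TE mode of the asymmetric four-region stack (NOA 68 substrate /
  homogenized grating 85 nm / TiO2 130 nm / air) is found by bracketing the
  real transfer-matrix characteristic function on a dense n_eff grid and
  refining with Brent's method. The solver is validated against the textbook
  single-slab transcendental dispersion relation.

Rigorous coupled-wave electromagnetics (RCWA/FDTD), TM polarization, and
off-normal incidence are out of scope; the resonance *position* comes from
the Bragg condition and the dip *shape* from a phenomenological lineshape.

### Material dispersion

PET 1.57 and NOA 68 1.54 (manufacturers' nominal visible values,
dispersionless); TiO2 as a two-term Cauchy `n(λ) = 2.13 + 2.5e4/λ²`
(n ≈ 2.21 at 550 nm), within the literature range for sputtered films. The
Cauchy coefficients are anchored to the device's reported operating window:
with them, the 250-nm period resonates at 497.9 nm and the 550-nm period at
954.5 nm, so the reported 500–700 nm band and the >400-nm bandwidth claim are
both covered by the reported period span. Dispersion models carry a validity
window (default 380–1150 nm) and refuse evaluation outside it; accuracy is
only claimed over the visible band where the anchor data live.

## Instrument model

Each CCD pixel is assigned the length-weighted mean resonance of the
segment(s) its footprint overlaps, and the transmission matrix is
`T_ij = 1 − d·L(λ_j − λ_R(i))` with a symmetric Lorentzian dip, depth
d = 0.9 and FWHM 3 nm by default (GMR dips are near-total and a few nm wide;
the true, possibly Fano-asymmetric lineshape of the hardware is not
reported). The wavelength grid is 200 one-nm bins, λ_j = 500…699 nm: the
half-open convention keeps the reported square 200×200 matrix shape while
naming the span 500–700. `square_mode=True` additionally selects one pixel
row per grid wavelength (strictly increasing), reproducing the square
indexing; the full matrix keeps every pixel under the device (~292 rows).

CCD geometry is fixed by two anchors: the positions resonating at 500 and
700 nm are placed on pixels 2073 and 2361, which yields a pitch of ~6.94 µm
and reproduces the reported pixel numbering (e.g. the brightest dye
concentration reads MICP 2201). Optical magnification is 1 (contact
configuration).

Readout is `C = T·I` exactly, plus optional seeded noise in the order dark
offset → shot (Gaussian, SD = scale·√signal) → read (Gaussian), clipped at
zero; an optional 16-bit quantization flag exists for realism. Identical
`NoiseParams` (including seed) give bit-identical traces.

## Calibration

Monochromatic Gaussian sources (FWHM 2.5 nm, amplitude 1 — MICP location is
amplitude-invariant, so source brightness is irrelevant) are scanned 500–699
nm in 1-nm steps. Each trace is smoothed with a 5-pixel moving average, the
argmin refined parabolically on its three neighbours, and a dip shallower
than 5% of the baseline (median of the smoothed trace) is rejected as a dark
frame. Raw MICPs are projected to a monotone sequence by isotonic regression
(pool-adjacent-violators); inversions beyond 2 pixels abort calibration.
The curve interpolates linearly in both directions and never extrapolates.
Noiseless end-to-end recovery is within 1 nm over 505–695 nm; the first knot
lands on pixel 2072 (reported: 2073) because the 500-nm scan point sits
just below the first modeled segment resonance (501.2 nm) — within the
±2-pixel scatter the reported pixel numbers themselves show.

## Synthetic assays

The generator emulates the replicate structure of the reported experiments
(3 runs, 7 concentrations + blank) with per-measurement seeds derived from
the plan seed and the (run, concentration, replicate, timepoint, channel)
coordinates, so any single trace can be regenerated bit-for-bit.

* **tamra** — Gaussian emission (FWHM 35 nm) whose peak follows
  `600 + (34/3)·log10(c/1e-3)` nm, anchored to the two reported points
  (600 nm at 1e-3 M, 566 nm at 1e-6 M); brightness saturates as
  `c/(c+1e-4 M)`. The shift law is logarithmic because only the two anchors
  are reported, not a mechanism.
* **hsa-fluorescent** — fixed 610-nm peak (centre of the reported 608–612
  band), amplitude `3.7·c + 260` arbitrary units over 6.25–200 mg/L, i.e. a
  normalized dose response `0.0037·c + 0.26` matching the reported slope
  convention; the intercept is blank/free-dye fluorescence, so blanks are
  measurable. (A blank emits the amplitude law's intercept; zero-intercept
  models emit background only.)
* **creatinine-jaffe** — Beer–Lambert chromogen, absorbance band 510 nm
  (FWHM 90 nm) under a 535-nm LED; color develops as `c·(1 − e^(−k t))`
  with k = 0.24 /min (≈70% of the asymptote at the 5-min read; no rate is
  reported), read at 0 and 5 min. The 0-vs-5-min intensity difference at
  the LED centre is strictly increasing over the seven reported
  concentrations.
* **albumin-bcg** — 620-nm absorbance band (FWHM 60 nm) under a 625-nm LED
  with saturating binding `c·K/(c+K)`, K = 15 mg/mL, reproducing the
  reported nonlinear response; LOD for such assays uses the local slope of
  the lowest three concentrations.

The spectrometer channel is the true spectrum plus per-bin additive Gaussian
noise and a run-level multiplicative gain jitter. What the generator does
*not* emulate: excitation leakage and blocking-filter edges, photobleaching,
matrix effects of artificial urine, environmental-light drift, and CCD
quantum-efficiency structure — so passing recovery tests demonstrates the
correctness of the pipeline's inference under the stated noise model, not
hardware-level performance.

## Quantification conventions

* Dip threshold for assay traces is 0.5% (vs 5% for calibration scans): a
  broadband emission tens of nm wide driven through a 3-nm resonance yields
  dips only a few percent deep.
* Normalization is per run, to the mean intensity at the highest
  concentration; kinetic assays difference the fixed-pixel intensities
  (t = 0 minus t = 5 min) before normalizing.
* Sensitivity is the OLS slope of normalized intensity versus concentration
  in **tens of mg/L**. This convention is forced by the reported
  noise/sensitivity/LOD triplets, which satisfy LOD = noise/slope only per
  10 mg/L (10 × 0.1517/0.037 = 41.0; 10 × 0.0730/0.042 = 17.38); it is
  configurable (`conc_scale`).
* Noise is 3 × the pooled within-concentration SD of normalized intensities
  ("standard deviation from all measurements" read as pooled; `global` and
  `blank` readings are selectable, since the reported wording does not
  disambiguate). Pooling requires ≥2 measurements per level.
* OLS is the hand-written two-pass closed form (tested to 1e-10 against an
  independent reference implementation); R² of a constant response is
  reported as 0 and flagged degenerate rather than undefined.

## Numerical choices and degenerate inputs

Mode search: 1500-point n_eff grid between the largest cladding index and
the largest layer index, largest-root bracket refined to 1e-12; absence of a
sign change raises a no-guided-mode error. Ties in the smoothed trace argmin
take the lowest pixel and set a flag. Parabolic refinements are clamped to
±0.5 pixel/bin. CSVs are written with 17 significant digits and parsed with
correctly-rounded `float()`, so round trips are bit-exact. Test problem
sizes (e.g. 100-seed MICP stability, 200-seed LOD recovery at 3 runs × 8
levels) were chosen so the whole suite runs in well under a minute while
keeping Monte-Carlo margins comfortable.

## Known limitations

The effective-index model is a homogenized slab, not the reported
reference's exact formulation, and neither shipped model is certified
against the fabricated device; dip depth/width defaults are illustrative;
whether the sample liquid contacts the grating (changing the superstrate) is
unknown and assumed not to; and the reported experimental LODs depend on
laboratory noise levels that the default configuration deliberately does not
assert — they are reproduced arithmetically from the reported noise and
sensitivity values instead.
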