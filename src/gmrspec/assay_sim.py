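"""Synthetic assay data: fluorescent emission, colorimetric transmission,
kinetics, and replicated serial-dilution experiments.

Three assay classes are emulated, each with a named preset:

* ``tamra`` — a rhodamine-like fluorophore whose emission peak red-shifts
  with concentration (600 nm at 1e-3 M down to 566 nm at 1e-6 M), used to
  exercise simultaneous wavelength + intensity recovery.
* ``hsa-fluorescent`` — an albumin-blue-580-style albumin assay: emission
  fixed near 610 nm, amplitude linear in concentration over 6.25-200 mg/L.
* ``creatinine-jaffe`` — alkaline-picrate colorimetry read kinetically at
  0 and 5 min under a 535-nm LED.
* ``albumin-bcg`` — bromocresol-green albumin colorimetry: a 620-nm
  absorbance band under a 625-nm LED, with saturating (nonlinear) binding.

Every generated trace/spectrum is reproducible from the plan seed plus its
(run, concentration, replicate, timepoint, channel) coordinates, and the
dataset retains the noiseless ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .instrument import NoiseParams, TransmissionMatrix, forward_readout
from .signals import CCDTrace, SpectrumSample, gaussian_profile


@dataclass(frozen=True)
class FluorophoreModel:
    """Concentration-dependent Gaussian emission.

    The peak obeys peak(c) = base_peak + peak_shift_per_decade *
    log10(c / reference_concentration); the amplitude law is either
    ``linear`` (scale * c + intercept) or ``saturating``
    (scale * c / (c + saturation_constant)).
    """

    base_peak: float
    peak_shift_per_decade: float
    reference_concentration: float
    emission_fwhm: float
    amplitude_law: str = "linear"
    amplitude_scale: float = 1.0
    amplitude_intercept: float = 0.0
    saturation_constant: float | None = None
    background: float = 0.0

    def __post_init__(self):
        if self.emission_fwhm <= 0:
            raise ValidationError("emission_fwhm must be positive")
        if self.amplitude_law not in ("linear", "saturating"):
            raise ValidationError("amplitude_law must be 'linear' or 'saturating'")
        if self.amplitude_law == "saturating" and not self.saturation_constant:
            raise ValidationError("saturating law needs saturation_constant")
        if self.amplitude_scale < 0 or self.amplitude_intercept < 0:
            raise ValidationError("amplitude coefficients must be >= 0")

    def amplitude(self, concentration: float) -> float:
        if concentration < 0:
            raise ValidationError("concentration must be >= 0")
        if self.amplitude_law == "linear":
            return self.amplitude_scale * concentration + self.amplitude_intercept
        return self.amplitude_scale * concentration / (concentration + self.saturation_constant)

    def peak_wavelength(self, concentration: float) -> float:
        if concentration <= 0:
            return self.base_peak
        return self.base_peak + self.peak_shift_per_decade * np.log10(
            concentration / self.reference_concentration)


def fluorescence_spectrum(model: FluorophoreModel, concentration: float,
                          grid) -> SpectrumSample:
    """Emission spectrum at one concentration.

    A blank (c = 0) emits only the amplitude law's intercept — the residual
    fluorescence of unbound dye — on top of the flat background; models with
    zero intercept (e.g. a plain dye dilution) give background only.
    """
    grid = np.asarray(grid, dtype=float)
    amp = model.amplitude(concentration)
    intensity = np.full(grid.shape, float(model.background))
    if amp > 0:
        peak = float(np.clip(model.peak_wavelength(concentration), grid[0], grid[-1]))
        intensity = intensity + gaussian_profile(grid, peak, model.emission_fwhm, amp)
    return SpectrumSample(grid, intensity)


@dataclass(frozen=True)
class ChromogenModel:
    """Beer-Lambert chromogen under Gaussian LED illumination.

    Absorbance A(lambda) = molar_absorptivity_scale * path_length * c_eff *
    G(lambda) with G a unit-peak Gaussian band at ``absorbance_peak``;
    transmittance is 10**(-A).
    """

    absorbance_peak: float
    absorbance_fwhm: float
    molar_absorptivity_scale: float
    path_length: float = 1.0
    led_center: float = 535.0
    led_fwhm: float = 30.0
    led_amplitude: float = 1000.0

    def __post_init__(self):
        for name in ("absorbance_fwhm", "molar_absorptivity_scale",
                     "path_length", "led_fwhm", "led_amplitude"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def led_spectrum(self, grid) -> SpectrumSample:
        grid = np.asarray(grid, dtype=float)
        return SpectrumSample(grid, gaussian_profile(grid, self.led_center,
                                                     self.led_fwhm,
                                                     self.led_amplitude))

    def absorbance(self, effective_concentration: float, grid) -> np.ndarray:
        band = gaussian_profile(grid, self.absorbance_peak, self.absorbance_fwhm)
        return (self.molar_absorptivity_scale * self.path_length
                * effective_concentration * band)


def transmitted_spectrum(model: ChromogenModel, effective_concentration: float,
                         grid) -> SpectrumSample:
    """LED spectrum attenuated by the Beer-Lambert chromogen band."""
    if effective_concentration < 0:
        raise ValidationError("effective concentration must be >= 0")
    grid = np.asarray(grid, dtype=float)
    led = model.led_spectrum(grid)
    t = 10.0 ** (-model.absorbance(effective_concentration, grid))
    return SpectrumSample(grid, led.intensity * t)


@dataclass(frozen=True)
class KineticModel:
    """First-order color development: c_eff(t) = c * (1 - exp(-k t))."""

    rate_constant: float = 0.24
    read_times: tuple[float, ...] = (0.0, 5.0)

    def __post_init__(self):
        if self.rate_constant < 0:
            raise ValidationError("rate_constant must be >= 0")
        if any(b < a for a, b in zip(self.read_times, self.read_times[1:])):
            raise ValidationError("read_times must be non-decreasing")

    def conversion(self, t_minutes: float) -> float:
        return 1.0 - float(np.exp(-self.rate_constant * t_minutes))


def kinetic_pair(chromogen: ChromogenModel, kinetics: KineticModel,
                 concentration: float, grid) -> tuple[SpectrumSample, SpectrumSample]:
    """Transmitted spectra at the two read times (typically 0 and 5 min)."""
    if len(kinetics.read_times) < 2:
        raise ValidationError("kinetic_pair needs two read times")
    t0, t1 = kinetics.read_times[0], kinetics.read_times[-1]
    return (transmitted_spectrum(chromogen, concentration * kinetics.conversion(t0), grid),
            transmitted_spectrum(chromogen, concentration * kinetics.conversion(t1), grid))


@dataclass(frozen=True)
class FluorescentAssay:
    """Fluorescent assay: the observed spectrum is the dye emission."""

    fluorophore: FluorophoreModel
    kind: str = "fluorescent"

    @property
    def read_times(self):
        return (None,)

    def true_spectrum(self, concentration, grid, timepoint=None):
        spec = fluorescence_spectrum(self.fluorophore, concentration, grid)
        return spec, {
            "true_peak_nm": self.fluorophore.peak_wavelength(concentration),
            "true_amplitude": self.fluorophore.amplitude(concentration),
        }


@dataclass(frozen=True)
class ColorimetricAssay:
    """Colorimetric assay: the observed spectrum is LED transmission.

    ``binding_constant`` (same units as concentration) makes the effective
    chromophore concentration saturate as c * K / (c + K), modeling
    stoichiometric binding (the bromocresol-green nonlinearity); ``kinetics``
    adds two-timepoint color development (the Jaffe readout).
    """

    chromogen: ChromogenModel
    kinetics: KineticModel | None = None
    binding_constant: float | None = None
    kind: str = "colorimetric"

    @property
    def read_times(self):
        return self.kinetics.read_times if self.kinetics is not None else (None,)

    def effective_concentration(self, concentration: float,
                                timepoint: float | None) -> float:
        c_eff = concentration
        if self.binding_constant is not None:
            c_eff = concentration * self.binding_constant / (concentration + self.binding_constant) \
                if concentration > 0 else 0.0
        if self.kinetics is not None and timepoint is not None:
            c_eff *= self.kinetics.conversion(timepoint)
        return c_eff

    def true_spectrum(self, concentration, grid, timepoint=None):
        c_eff = self.effective_concentration(concentration, timepoint)
        spec = transmitted_spectrum(self.chromogen, c_eff, grid)
        i = int(np.argmax(spec.intensity))
        return spec, {
            "true_peak_nm": float(np.asarray(grid, dtype=float)[i]),
            "true_amplitude": float(spec.intensity[i]),
            "effective_concentration": c_eff,
        }


AssayModel = FluorescentAssay | ColorimetricAssay


@dataclass(frozen=True)
class SamplePlan:
    """Replicated serial-dilution plan (the reference experiments use 3 runs)."""

    concentrations: tuple[float, ...]
    unit: str = "mg/L"
    include_blank: bool = True
    replicates_per_run: int = 1
    n_runs: int = 3
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        if np.unique(c).size != c.size:
            raise ValidationError("concentrations must be distinct")
        if self.n_runs < 1 or self.replicates_per_run < 1:
            raise ValidationError("n_runs and replicates_per_run must be >= 1")

    def levels(self) -> tuple[float, ...]:
        """All measured concentrations, blank (0) included when requested."""
        levels = tuple(sorted(self.concentrations, reverse=True))
        if self.include_blank and 0.0 not in levels:
            levels = levels + (0.0,)
        return levels


@dataclass
class MeasurementRecord:
    """One measurement: paired CCD trace and spectrometer spectrum."""

    run: int
    concentration: float
    replicate: int
    timepoint: float | None
    trace: CCDTrace
    spectrum: SpectrumSample
    truth: dict
    seeds: dict


def _child_seed(root: int, *coords: int) -> int:
    """Deterministic per-measurement seed below 2**31."""
    return int(np.random.SeedSequence([root, *coords]).generate_state(1)[0] % (2**31))


def _spectrometer_channel(true_spec: SpectrumSample, noise: NoiseParams | None,
                          gain: float, seed: int) -> SpectrumSample:
    intensity = true_spec.intensity * gain
    if noise is not None and noise.read_noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise.read_noise_sd, intensity.size)
    return SpectrumSample(true_spec.wavelength_nm.copy(), np.maximum(intensity, 0.0))


@dataclass
class AssayDataset:
    """All measurements of one plan plus the ground-truth/seed ledger."""

    plan: SamplePlan
    assay: AssayModel
    records: list[MeasurementRecord]

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"run": r.run, "concentration": r.concentration,
                   "replicate": r.replicate, "timepoint": r.timepoint}
            row.update(r.truth)
            rows.append(row)
        return pd.DataFrame(rows)

    def select(self, **kv) -> list[MeasurementRecord]:
        out = self.records
        for key, val in kv.items():
            out = [r for r in out if getattr(r, key) == val]
        return out


def generate_dataset(plan: SamplePlan, assay: AssayModel,
                     tmatrix: TransmissionMatrix,
                     detector_noise: NoiseParams | None = None,
                     spectrometer_noise: NoiseParams | None = None) -> AssayDataset:
    """Simulate every (run, concentration, replicate, timepoint) measurement.

    The CCD channel is ``forward_readout`` of the true spectrum with seeded
    detector noise; the spectrometer channel is the true spectrum with a
    run-level multiplicative gain jitter and per-bin additive noise.  All
    seeds derive deterministically from ``plan.seed`` and the measurement
    coordinates, so any single record can be regenerated bit-for-bit.
    """
    grid = tmatrix.column_wavelengths
    levels = plan.levels()
    records: list[MeasurementRecord] = []
    for run in range(plan.n_runs):
        gain = 1.0
        if spectrometer_noise is not None and spectrometer_noise.gain_jitter_sd > 0:
            gain_rng = np.random.default_rng(
                _child_seed(plan.seed, 9999, run))
            gain = float(max(1.0 + gain_rng.normal(0.0, spectrometer_noise.gain_jitter_sd), 0.0))
        for ci, conc in enumerate(levels):
            for rep in range(plan.replicates_per_run):
                for ti, tp in enumerate(assay.read_times):
                    true_spec, truth = assay.true_spectrum(conc, grid, tp)
                    seeds = {
                        "trace": _child_seed(plan.seed, run, ci, rep, ti, 0),
                        "spectrum": _child_seed(plan.seed, run, ci, rep, ti, 1),
                    }
                    det = None
                    if detector_noise is not None and detector_noise.enabled:
                        det = replace(detector_noise, seed=seeds["trace"])
                    trace = forward_readout(tmatrix, true_spec, det)
                    spec = _spectrometer_channel(true_spec, spectrometer_noise,
                                                 gain, seeds["spectrum"])
                    truth = dict(truth)
                    truth["spectrometer_gain"] = gain
                    records.append(MeasurementRecord(
                        run=run, concentration=conc, replicate=rep,
                        timepoint=tp, trace=trace, spectrum=spec,
                        truth=truth, seeds=seeds))
    return AssayDataset(plan=plan, assay=assay, records=records)


# ---------------------------------------------------------------------------
# Presets

def tamra_model() -> FluorophoreModel:
    """Rhodamine-like dye: peak 600 nm at 1e-3 M shifting -34 nm over three
    decades of dilution; saturating brightness."""
    return FluorophoreModel(
        base_peak=600.0, peak_shift_per_decade=34.0 / 3.0,
        reference_concentration=1e-3, emission_fwhm=35.0,
        amplitude_law="saturating", amplitude_scale=1000.0,
        saturation_constant=1e-4, background=1.0)


def hsa_fluorescent_model() -> FluorophoreModel:
    """Albumin-blue-580 albumin assay: fixed ~610-nm peak, amplitude linear
    in concentration with a free-dye blank offset."""
    return FluorophoreModel(
        base_peak=610.0, peak_shift_per_decade=0.0,
        reference_concentration=200.0, emission_fwhm=30.0,
        amplitude_law="linear", amplitude_scale=3.7, amplitude_intercept=260.0,
        background=2.0)


def jaffe_assay() -> ColorimetricAssay:
    """Picrate-creatinine kinetic colorimetry under a 535-nm LED."""
    return ColorimetricAssay(
        chromogen=ChromogenModel(
            absorbance_peak=510.0, absorbance_fwhm=90.0,
            molar_absorptivity_scale=1.7e-3, path_length=1.0,
            led_center=535.0, led_fwhm=30.0, led_amplitude=1000.0),
        kinetics=KineticModel(rate_constant=0.24, read_times=(0.0, 5.0)))


def bcg_assay() -> ColorimetricAssay:
    """Bromocresol-green albumin colorimetry: 620-nm band, 625-nm LED,
    saturating binding (nonlinear dose response)."""
    return ColorimetricAssay(
        chromogen=ChromogenModel(
            absorbance_peak=620.0, absorbance_fwhm=60.0,
            molar_absorptivity_scale=0.12, path_length=1.0,
            led_center=625.0, led_fwhm=25.0, led_amplitude=1000.0),
        binding_constant=15.0)


def preset_assay(name: str) -> tuple[AssayModel, SamplePlan]:
    """Named assay model plus its reference serial-dilution plan."""
    if name == "tamra":
        return (FluorescentAssay(tamra_model()),
                SamplePlan(concentrations=(1e-3, 1e-4, 1e-5, 1e-6, 1e-7),
                           unit="M", include_blank=False))
    if name == "hsa-fluorescent":
        return (FluorescentAssay(hsa_fluorescent_model()),
                SamplePlan(concentrations=(200.0, 150.0, 100.0, 50.0, 25.0,
                                           12.5, 6.25), unit="mg/L"))
    if name == "creatinine-jaffe":
        return (jaffe_assay(),
                SamplePlan(concentrations=(500.0, 400.0, 300.0, 200.0, 150.0,
                                           100.0, 50.0), unit="mg/L"))
    if name == "albumin-bcg":
        return (bcg_assay(),
                SamplePlan(concentrations=(50.0, 40.0, 30.0, 20.0, 10.0, 5.0),
                           unit="mg/mL"))
    raise ValidationError(f"unknown assay preset {name!r}")


PRESETS = ("tamra", "hsa-fluorescent", "creatinine-jaffe", "albumin-bcg")
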