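"""Run configuration: YAML -> validated domain objects.

A config file has five sections (device, instrument, calibration, assay,
output); every field defaults to the fabricated device / reported experiment
values, so a minimal config naming only an assay preset is complete.
Unknown keys are rejected, and invariant violations are reported with the
offending key name.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict

from .assay_sim import PRESETS, SamplePlan, preset_assay
from .errors import ConfigError, GmrSpecError
from .filter_model import GratingDesign
from .instrument import CCDGeometry, NoiseParams, ResonanceLineshape
from .materials import CauchyIndex, ConstantIndex, MaterialSet


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MaterialConfig(_Section):
    model: Literal["constant", "cauchy"] = "constant"
    n: float = 1.5
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0

    def build(self, label: str):
        if self.model == "constant":
            return ConstantIndex(self.n, label=label)
        return CauchyIndex(self.a, self.b, self.c, label=label)


class MaterialsConfig(_Section):
    substrate: MaterialConfig = MaterialConfig(n=1.57)
    adhesive: MaterialConfig = MaterialConfig(n=1.54)
    coating: MaterialConfig = MaterialConfig(model="cauchy", a=2.13, b=2.5e4)
    superstrate: MaterialConfig = MaterialConfig(n=1.0)

    def build(self) -> MaterialSet:
        ms = MaterialSet(substrate=self.substrate.build("substrate"),
                         adhesive=self.adhesive.build("adhesive"),
                         coating=self.coating.build("coating"),
                         superstrate=self.superstrate.build("superstrate"))
        ms.validate()
        return ms


class DesignConfig(_Section):
    period_start: float = 250.0
    period_end: float = 550.0
    period_step: float = 2.0
    cycles_per_period: int = 100
    duty_cycle: float = 0.5
    grating_depth: float = 85.0
    coating_thickness: float = 130.0
    band: Optional[tuple[float, float]] = (500.0, 700.0)
    neff_model: Literal["slab-mode", "weighted-average"] = "slab-mode"

    def build(self) -> GratingDesign:
        return GratingDesign(period_start=self.period_start,
                             period_end=self.period_end,
                             period_step=self.period_step,
                             cycles_per_period=self.cycles_per_period,
                             duty_cycle=self.duty_cycle,
                             grating_depth=self.grating_depth,
                             coating_thickness=self.coating_thickness)


class DeviceConfig(_Section):
    design: DesignConfig = DesignConfig()
    materials: MaterialsConfig = MaterialsConfig()


class CCDConfig(_Section):
    n_pixels: int = 3000
    pixel_pitch: Optional[float] = None
    position_offset: Optional[float] = None
    anchor_a: tuple[int, float] = (2073, 500.0)
    anchor_b: tuple[int, float] = (2361, 700.0)

    def build(self, layout) -> CCDGeometry:
        if self.pixel_pitch is not None:
            return CCDGeometry(pixel_pitch=self.pixel_pitch,
                               n_pixels=self.n_pixels,
                               position_offset=self.position_offset or 0.0)
        return CCDGeometry.from_anchors(layout, self.anchor_a, self.anchor_b,
                                        n_pixels=self.n_pixels)


class LineshapeConfig(_Section):
    depth: float = 0.9
    fwhm: float = 3.0
    shape: Literal["lorentzian", "gaussian"] = "lorentzian"

    def build(self) -> ResonanceLineshape:
        return ResonanceLineshape(depth=self.depth, fwhm=self.fwhm,
                                  shape=self.shape)


class NoiseConfig(_Section):
    read_noise_sd: float = 0.0
    shot_noise_scale: float = 0.0
    dark_offset: float = 0.0
    gain_jitter_sd: float = 0.0

    def build(self, seed: int = 0) -> NoiseParams:
        return NoiseParams(read_noise_sd=self.read_noise_sd,
                           shot_noise_scale=self.shot_noise_scale,
                           dark_offset=self.dark_offset,
                           gain_jitter_sd=self.gain_jitter_sd, seed=seed)


class InstrumentConfig(_Section):
    ccd: CCDConfig = CCDConfig()
    lineshape: LineshapeConfig = LineshapeConfig()
    detector_noise: NoiseConfig = NoiseConfig(read_noise_sd=2.0)
    spectrometer_noise: NoiseConfig = NoiseConfig(read_noise_sd=1.0,
                                                  gain_jitter_sd=0.01)


class CalibrationSection(_Section):
    scan_start: float = 500.0
    scan_stop: float = 700.0
    scan_step: float = 1.0
    linewidth: float = 2.5
    smoothing_window: int = 5
    min_dip_depth: float = 0.05


class AssaySection(_Section):
    preset: Literal["tamra", "hsa-fluorescent", "creatinine-jaffe",
                    "albumin-bcg"] = "hsa-fluorescent"
    concentrations: Optional[list[float]] = None
    unit: Optional[str] = None
    include_blank: Optional[bool] = None
    replicates_per_run: int = 1
    n_runs: int = 3

    def build(self, seed: int):
        assay, plan = preset_assay(self.preset)
        kwargs = dict(concentrations=plan.concentrations, unit=plan.unit,
                      include_blank=plan.include_blank,
                      replicates_per_run=self.replicates_per_run,
                      n_runs=self.n_runs, seed=seed)
        if self.concentrations is not None:
            kwargs["concentrations"] = tuple(self.concentrations)
        if self.unit is not None:
            kwargs["unit"] = self.unit
        if self.include_blank is not None:
            kwargs["include_blank"] = self.include_blank
        return assay, SamplePlan(**kwargs)


class RunConfig(_Section):
    device: DeviceConfig = DeviceConfig()
    instrument: InstrumentConfig = InstrumentConfig()
    calibration: CalibrationSection = CalibrationSection()
    assay: AssaySection = AssaySection()
    output_dir: str = "gmrspec-out"
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending key on parse errors,
    unknown keys, or invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error ({exc})") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>"
                         for err in exc.errors())
        raise ConfigError(f"{path}: invalid config key(s): {keys}") from exc
    # eager domain validation so geometry errors surface at load time
    try:
        cfg.device.design.build()
        cfg.device.materials.build()
        cfg.instrument.lineshape.build()
    except GmrSpecError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return cfg
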