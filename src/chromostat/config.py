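"""Validated run configuration.

A single human-editable YAML file configures every component: spectral
parameter sets, vesicle preparation, plant calibration, GDH kinetics,
controller gains, electrode constants, scenario settings, and the global
seed. Every omitted field falls back to the packaged default (an empty file
is a complete, valid configuration); unknown keys are rejected with the
offending key path in the message. ``RunConfig.build_*`` methods turn the
validated configuration into the runtime objects of the other modules.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import plant as _plant
from . import spectra as _spectra
from .controller import ControllerConfig as _CtrlRuntime
from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "default_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SpectraConfig(_Section):
    """Gaussian parameter sets for the two pigments and two LEDs (nm)."""

    br_center_nm: float = Field(_spectra.BR_PEAK_NM, gt=0)
    br_fwhm_nm: float = Field(_spectra.BR_FWHM_NM, gt=0)
    bpr_center_nm: float = Field(_spectra.BPR_PEAK_NM, gt=0)
    bpr_fwhm_nm: float = Field(_spectra.BPR_FWHM_NM, gt=0)
    blue_center_nm: float = Field(_spectra.BLUE_PEAK_NM, gt=0)
    blue_fwhm_nm: float = Field(_spectra.BLUE_FWHM_NM, gt=0)
    red_center_nm: float = Field(_spectra.RED_PEAK_NM, gt=0)
    red_fwhm_nm: float = Field(_spectra.RED_FWHM_NM, gt=0)
    grid_min_nm: float = Field(350.0, ge=200.0)
    grid_max_nm: float = Field(750.0, le=900.0)
    grid_step_nm: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _check_grid(self) -> "SpectraConfig":
        if self.grid_min_nm >= self.grid_max_nm:
            raise ValueError("grid_min_nm must be < grid_max_nm")
        return self


class PrepConfig(_Section):
    particle_conc_nm: float = Field(20.0, gt=0)
    diameter_logmu: float = math.log(130.0) - 0.5 * 0.35**2
    diameter_logsigma: float = Field(0.35, ge=0)
    mass_ratio_bpr_to_br: float = Field(2.0, gt=0)
    br_out_fraction: float = Field(2.0 / 3.0, ge=0, le=1)
    bpr_in_fraction: float = Field(1.0, ge=0, le=1)
    counter_pumping: bool = True


class PumpConfig(_Section):
    jmax: float = Field(0.01, ge=0)
    dph_max: float = Field(2.8, gt=0)
    ph_lo: float = 5.0
    ph_hi: float = 10.2
    logistic_width: float = Field(0.15, gt=0)

    @model_validator(mode="after")
    def _check_window(self) -> "PumpConfig":
        if self.ph_lo >= self.ph_hi:
            raise ValueError("ph_lo must be < ph_hi")
        return self


class BRPumpConfig(PumpConfig):
    """BR kinetics: the calibrated default rate constant is 2x BPR's."""

    jmax: float = Field(_plant.BR_JMAX_DEFAULT, ge=0)


class PlantConfig(_Section):
    beta_out: float = Field(0.5, gt=0)
    beta_substrate: float = Field(1.0, ge=0)
    beta_in: float = Field(5.0, gt=0)
    leak_rate: float = Field(2.0e-4, ge=0)
    volume_out_ul: float = Field(150.0, gt=0)
    volume_in_ul: float = Field(15.0, gt=0)
    temperature_c: float = 21.0


class GDHConfig(_Section):
    vmax: float = Field(5.0e-3, ge=0)
    km_akg: float = Field(0.6, gt=0)
    km_nh4: float = Field(1.0, gt=0)
    km_nadh: float = Field(0.2, gt=0)
    ph_opt: float = Field(8.0, gt=0)
    ph_width: float = Field(0.8, gt=0)


class ControllerSection(_Section):
    kp: float = 5.0
    ki: float = 0.1
    power_min: float = Field(0.0, ge=0)
    power_max: float = Field(1.0, le=1)
    sample_interval: float = Field(1.0, gt=0)
    antiwindup: Literal["clamp", "off"] = "clamp"
    adc_averages: int = Field(16, ge=1)

    @model_validator(mode="after")
    def _check_limits(self) -> "ControllerSection":
        if not self.power_min < self.power_max:
            raise ValueError("power_min must be < power_max")
        return self


class ElectrodeConfig(_Section):
    slope: float = -0.057
    intercept: float = 2.5
    noise_sd: float = Field(0.002, ge=0)

    @model_validator(mode="after")
    def _check_slope(self) -> "ElectrodeConfig":
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        return self


class ScenarioConfig(_Section):
    staircase_setpoints: tuple[float, ...] = (6.0, 6.25, 6.5, 6.75, 7.0)
    dwell_s: float = Field(600.0, gt=0)
    range_test_low: float = 5.9
    range_test_high: float = 7.2
    range_test_dwell_s: float = Field(1800.0, gt=0)
    gdh_phase1_s: float = Field(3600.0, gt=0)
    gdh_phase2_s: float = Field(5400.0, gt=0)
    gdh_setpoint_low: float = 6.0
    gdh_setpoint_high: float = 8.5
    assay_interval_s: float = Field(900.0, gt=0)  # 600 reproduces 10-min sampling
    assay_noise_sd: float = Field(0.002, ge=0)
    sweep_duration_s: float = Field(1800.0, gt=0)
    sweep_threshold_ph: float = Field(0.05, gt=0)
    plateau_rate_ph_per_s: float = Field(1.0e-4, gt=0)
    plateau_hold_s: float = Field(60.0, gt=0)
    plateau_cap_s: float = Field(2700.0, gt=0)
    integrator_dt_s: float = Field(0.1, gt=0)


class RunConfig(_Section):
    """Top-level configuration: nested sections plus the global seed."""

    spectra: SpectraConfig = SpectraConfig()
    prep: PrepConfig = PrepConfig()
    plant: PlantConfig = PlantConfig()
    br: BRPumpConfig = BRPumpConfig()
    bpr: PumpConfig = PumpConfig()
    gdh: GDHConfig = GDHConfig()
    controller: ControllerSection = ControllerSection()
    electrode: ElectrodeConfig = ElectrodeConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    seed: int = 0

    # -- builders ----------------------------------------------------------
    def grid(self):
        return _spectra.default_grid(
            self.spectra.grid_min_nm, self.spectra.grid_max_nm, self.spectra.grid_step_nm
        )

    def build_pump_photos(self):
        g = self.grid()
        br = _spectra.default_br(self.spectra.br_center_nm, self.spectra.br_fwhm_nm, g)
        bpr = _spectra.default_bpr(self.spectra.bpr_center_nm, self.spectra.bpr_fwhm_nm, g)
        return br, bpr

    def build_leds(self):
        g = self.grid()
        return {
            "blue": _spectra.default_led(
                "blue", self.spectra.blue_center_nm, self.spectra.blue_fwhm_nm, g
            ),
            "red": _spectra.default_led(
                "red", self.spectra.red_center_nm, self.spectra.red_fwhm_nm, g
            ),
        }

    def build_prep(self) -> "_plant.VesiclePreparation":
        return _plant.VesiclePreparation(**self.prep.model_dump())

    def build_plant(self, with_gdh: bool = False) -> "_plant.PlantModel":
        br_photo, bpr_photo = self.build_pump_photos()
        return _plant.build_default_plant(
            prep=self.build_prep(),
            params=_plant.PlantParams(**self.plant.model_dump()),
            br_kinetics=_plant.PumpKineticParams(**self.br.model_dump()),
            bpr_kinetics=_plant.PumpKineticParams(**self.bpr.model_dump()),
            br_photo=br_photo,
            bpr_photo=bpr_photo,
            leds=self.build_leds(),
            gdh=_plant.GDHParams(**self.gdh.model_dump()) if with_gdh else None,
            with_gdh=with_gdh,
        )

    def build_electrode(self, seed: int | None = None) -> "_plant.ElectrodeModel":
        return _plant.ElectrodeModel(
            slope=self.electrode.slope,
            intercept=self.electrode.intercept,
            noise_sd=self.electrode.noise_sd,
            seed=self.seed if seed is None else seed,
        )

    def build_controller(self) -> _CtrlRuntime:
        return _CtrlRuntime(**self.controller.model_dump())


def default_config() -> RunConfig:
    """The packaged defaults (identical to loading an empty file)."""
    return RunConfig()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML configuration file.

    ``None`` (or an empty file) yields the packaged defaults. Unknown keys
    and invariant violations raise :class:`ConfigError` naming the key path.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        details = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: {details}") from exc
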