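"""PI feedback controller, electrode calibration, and the closed loop.

Re-implements the measuring-device software around the vesicle plant:

* a linear voltage-to-pH calibration fitted from buffers of known pH;
* a proportional-integral control law ``u = kp*e + ki*sum(e)`` on the error
  ``e = setpoint - measured pH``, whose sign selects the LED color — a
  positive command powers the red LEDs (BR raises the bulk pH), a negative
  command powers the blue LEDs (BPR lowers it); at most one color is ever on;
* setpoint schedules (predefined staircases or real-time edits) and live
  gain updates from a ``PIDparams``-style text file that is re-read every
  control tick without crashing the loop on a malformed edit;
* a tab-delimited log, one record per tick: time, measured pH, setpoint,
  color, intensity, and the gains in force.

The integral gain is per sample (default tick 1 s). Anti-windup is
conditional integration: the accumulator freezes whenever the output is
saturated in the direction of the error; switching it off reproduces the
sustained-full-power behavior seen when gains are not tuned for a range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigError, ParameterError
from .plant import ElectrodeModel, PlantModel, PlantState, _advance
from .seeding import child_seed

__all__ = [
    "CalibrationModel",
    "ControllerConfig",
    "ControllerState",
    "SetpointSchedule",
    "LogRecord",
    "ClosedLoopResult",
    "fit_calibration",
    "voltage_to_pH",
    "pi_update",
    "read_gain_updates",
    "run_closed_loop",
    "calibrate_from_buffers",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear voltage <-> pH map: ``voltage = slope * pH + intercept``."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise CalibrationError("calibration slope must be nonzero")


def fit_calibration(readings: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of voltage on known pH.

    ``readings`` are ``(voltage_V, known_pH)`` pairs from buffer solutions;
    at least two distinct pH values are required. With exactly two points the
    fit passes through both.
    """
    if len(readings) < 2:
        raise CalibrationError("need at least 2 calibration points")
    volts = np.array([r[0] for r in readings], dtype=float)
    phs = np.array([r[1] for r in readings], dtype=float)
    if np.unique(phs).size < 2:
        raise CalibrationError("calibration points must span at least 2 distinct pH values")
    slope, intercept = np.polyfit(phs, volts, 1)
    return CalibrationModel(float(slope), float(intercept))


def voltage_to_pH(cal: CalibrationModel, v: float) -> float:
    """Invert the calibration: ``pH = (voltage - intercept) / slope``."""
    return (v - cal.intercept) / cal.slope


@dataclass(frozen=True)
class ControllerConfig:
    """PI gains, actuation limits, tick length, anti-windup mode."""

    kp: float = 5.0
    ki: float = 0.1  # per sample
    power_min: float = 0.0
    power_max: float = 1.0
    sample_interval: float = 1.0  # s
    antiwindup: str = "clamp"  # {"clamp", "off"}
    adc_averages: int = 16  # raw electrode reads averaged per tick

    def __post_init__(self) -> None:
        if not 0.0 <= self.power_min < self.power_max <= 1.0:
            raise ParameterError("require 0 <= power_min < power_max <= 1")
        if self.sample_interval <= 0:
            raise ParameterError("sample_interval must be > 0")
        if self.antiwindup not in ("clamp", "off"):
            raise ParameterError("antiwindup must be 'clamp' or 'off'")
        if self.adc_averages < 1:
            raise ParameterError("adc_averages must be >= 1")


@dataclass(frozen=True)
class ControllerState:
    """Integral accumulator, last error, and the current LED powers."""

    integral: float = 0.0
    last_error: float = 0.0
    power_blue: float = 0.0
    power_red: float = 0.0


def pi_update(
    cfg: ControllerConfig,
    state: ControllerState,
    setpoint: float,
    measured: float,
) -> ControllerState:
    """One PI tick: compute the command and pick the LED color.

    The command uses the accumulator as carried into the tick,
    ``u = kp*e + ki*integral``; the accumulator is then advanced by ``e``
    unless anti-windup freezes it (output saturated in the error's
    direction). ``u > 0`` drives red (raise pH), ``u < 0`` drives blue.
    """
    e = setpoint - measured
    u = cfg.kp * e + cfg.ki * state.integral
    new_integral = state.integral + e
    if cfg.antiwindup == "clamp":
        u_next = cfg.kp * e + cfg.ki * new_integral
        if abs(u_next) > cfg.power_max and u_next * e > 0:
            new_integral = state.integral
    if u > 0:
        power_red = min(max(u, cfg.power_min), cfg.power_max)
        power_blue = 0.0
    elif u < 0:
        power_blue = min(max(-u, cfg.power_min), cfg.power_max)
        power_red = 0.0
    else:
        power_blue = power_red = 0.0
    return ControllerState(
        integral=new_integral,
        last_error=e,
        power_blue=power_blue,
        power_red=power_red,
    )


@dataclass(frozen=True)
class SetpointSchedule:
    """Ordered ``(start_time_s, setpoint_pH)`` entries.

    The setpoint in force at time ``t`` is that of the latest entry with
    ``start_time <= t`` (the first entry before its own start).
    """

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ParameterError("schedule must contain at least one entry")
        entries = tuple((float(t), float(sp)) for t, sp in self.entries)
        starts = [t for t, _ in entries]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ParameterError("schedule start times must be strictly increasing")
        for _, sp in entries:
            if not 3.0 < sp < 12.0:
                raise ParameterError(f"setpoint {sp} outside (3, 12)")
        object.__setattr__(self, "entries", entries)

    def setpoint_at(self, t: float) -> float:
        sp = self.entries[0][1]
        for start, value in self.entries:
            if start <= t:
                sp = value
            else:
                break
        return sp

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["start_s\tsetpoint"] + [
            f"{_fmt(t)}\t{_fmt(sp)}" for t, sp in self.entries
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "SetpointSchedule":
        path = Path(path)
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not lines or lines[0].split("\t") != ["start_s", "setpoint"]:
            raise ConfigError(f"{path}: expected header 'start_s\\tsetpoint'")
        entries = []
        for i, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ConfigError(f"{path}:{i}: expected 2 tab-separated fields")
            try:
                entries.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ConfigError(f"{path}:{i}: {exc}") from exc
        return cls(tuple(entries))


def _fmt(x: float) -> str:
    return repr(float(x))


@dataclass(frozen=True)
class LogRecord:
    """One control tick as written to the run log."""

    time_s: float
    ph: float
    setpoint: float
    color: str  # {"red", "blue", "none"}
    intensity: float
    kp: float
    ki: float


def read_gain_updates(
    path: str | Path, previous: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Read live ``kp=`` / ``ki=`` gains from a parameter file.

    A missing or malformed file at startup (``previous is None``) is a
    :class:`ConfigError`; during a run it leaves the previous gains in force
    and emits a warning, so an editing mistake never crashes the loop.
    """
    path = Path(path)
    try:
        text = path.read_text()
        gains: dict[str, float] = {}
        for ln in text.splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            key, _, value = ln.partition("=")
            key = key.strip().lower()
            if key in ("kp", "ki"):
                gains[key] = float(value.strip())
        if set(gains) != {"kp", "ki"}:
            raise ValueError("file must define both kp= and ki=")
        return gains["kp"], gains["ki"]
    except (OSError, ValueError) as exc:
        if previous is None:
            raise ConfigError(f"cannot read gain file {path}: {exc}") from exc
        warnings.warn(
            f"gain file {path} unreadable ({exc}); keeping kp={previous[0]}, "
            f"ki={previous[1]}",
            stacklevel=2,
        )
        return previous


@dataclass
class ClosedLoopResult:
    """Log, true-state trajectory, samples taken, and the final plant state."""

    log: list[LogRecord]
    trajectory: pd.DataFrame
    final_state: PlantState
    samples: list[tuple[float, PlantState]] = field(default_factory=list)
    calibration: CalibrationModel | None = None


def calibrate_from_buffers(
    electrode: ElectrodeModel,
    buffer_phs: Sequence[float] = (4.0, 7.0, 10.0),
    n_average: int = 64,
) -> CalibrationModel:
    """Calibrate against buffer solutions of known pH using the electrode."""
    readings = [(electrode.measure(ph, n_average), ph) for ph in buffer_phs]
    return fit_calibration(readings)


def run_closed_loop(
    model: PlantModel,
    initial_state: PlantState,
    electrode: ElectrodeModel,
    calibration: CalibrationModel,
    cfg: ControllerConfig,
    schedule: SetpointSchedule,
    duration: float,
    seed: int | None = None,
    gains_file: str | Path | None = None,
    dt: float = 0.1,
    sample_times: Sequence[float] = (),
    hook: Callable[[float, PlantState], None] | None = None,
) -> ClosedLoopResult:
    """Run the feedback loop against the simulated plant.

    Per tick: read the scheduled setpoint, measure the electrode voltage
    (ADC-averaged), convert to pH, update the PI state, apply the selected
    LED power to the plant for one sample interval (RK4 substeps of ``dt``),
    and append a log record. Deterministic for a fixed ``seed``. States at
    ``sample_times`` are captured on the first tick boundary at or past each
    requested time (e.g. for assay sampling).
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if seed is not None:
        electrode.reset(child_seed(seed, "electrode"))
    gains = (cfg.kp, cfg.ki)
    if gains_file is not None:
        gains = read_gain_updates(gains_file)  # must exist at startup
    cstate = ControllerState()
    state = initial_state
    n_ticks = int(round(duration / cfg.sample_interval))
    n_sub = max(1, int(round(cfg.sample_interval / dt)))
    h = cfg.sample_interval / n_sub
    f = model.rhs()
    records: list[LogRecord] = []
    traj_rows: list[tuple] = []
    samples: list[tuple[float, PlantState]] = []
    pending = sorted(float(t) for t in sample_times)
    while pending and pending[0] <= 0.0:
        pending.pop(0)
        samples.append((0.0, state))
    t0 = state.t
    for k in range(n_ticks):
        t = k * cfg.sample_interval
        if gains_file is not None:
            gains = read_gain_updates(gains_file, previous=gains)
        kp, ki = gains
        tick_cfg = replace(cfg, kp=kp, ki=ki) if (kp, ki) != (cfg.kp, cfg.ki) else cfg
        setpoint = schedule.setpoint_at(t)
        v = electrode.measure(state.ph_out, cfg.adc_averages)
        ph_meas = voltage_to_pH(calibration, v)
        cstate = pi_update(tick_cfg, cstate, setpoint, ph_meas)
        if cstate.power_red > 0:
            color, intensity = "red", cstate.power_red
        elif cstate.power_blue > 0:
            color, intensity = "blue", cstate.power_blue
        else:
            color, intensity = "none", 0.0
        records.append(LogRecord(t, ph_meas, setpoint, color, intensity, kp, ki))
        traj_rows.append(
            (
                t,
                state.ph_out,
                state.ph_in,
                cstate.power_blue,
                cstate.power_red,
                state.akg,
                state.nh4,
                state.nadh,
                state.glu,
                state.nad,
            )
        )
        y = _advance(
            f, state.as_vector(), cstate.power_blue, cstate.power_red, h, n_sub, "rk4"
        )
        state = PlantState.from_vector(t0 + (k + 1) * cfg.sample_interval, y)
        t_next = (k + 1) * cfg.sample_interval
        while pending and pending[0] <= t_next:
            pending.pop(0)
            samples.append((t_next, state))
        if hook is not None:
            hook(t_next, state)
    trajectory = pd.DataFrame(
        traj_rows,
        columns=[
            "t",
            "ph_out",
            "ph_in",
            "power_blue",
            "power_red",
            "akg",
            "nh4",
            "nadh",
            "glu",
            "nad",
        ],
    )
    return ClosedLoopResult(
        log=records,
        trajectory=trajectory,
        final_state=state,
        samples=samples,
        calibration=calibration,
    )
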