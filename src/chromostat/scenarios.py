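"""Scripted end-to-end reproductions of the characterization experiments.

Each scenario wires the default (or user-configured) plant, electrode, and
controller together and reports summary metrics computed only from the run
log and the state trajectory:

* ``scenario_staircase``      - setpoint staircase between pH 6 and 7, 10-min
  dwells: per-dwell settling and steady-state accuracy.
* ``scenario_range_test``     - pumping-power qualification: setpoints 5.9 and
  7.2 from a washed pH-6 prep; metric is the achieved pH span.
* ``scenario_gdh_run``        - the enzymatic application: hold pH 6 for an
  hour under blue light, then setpoint 8.5; off-line triplicate spectra every
  sampling interval; metrics include the post-switch turning point of the pH
  trace and the NADH consumption profile.
* ``scenario_range_sweep``    - open-loop maximal up/down ranges as a function
  of starting pH (wash, full blue to plateau; re-wash, full red to plateau).
* ``evanescence_limit``       - the starting pH at which 30 min of full
  illumination no longer moves the bulk pH by more than a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayPoint, extract_A340, generate_assay_spectra
from .config import RunConfig, default_config
from .controller import (
    ClosedLoopResult,
    LogRecord,
    SetpointSchedule,
    calibrate_from_buffers,
    run_closed_loop,
)
from .errors import ParameterError
from .plant import (
    GDH_MIX_MM,
    PlantState,
    simulate,
    wash_to_pH,
    with_substrates,
)
from .seeding import child_seed

__all__ = [
    "ScenarioResult",
    "scenario_staircase",
    "scenario_range_test",
    "scenario_gdh_run",
    "scenario_range_sweep",
    "evanescence_limit",
    "compute_settling_metrics",
    "SCENARIOS",
]


@dataclass
class ScenarioResult:
    """Log, trajectory, and named scalar metrics of one scenario run."""

    name: str
    log: list[LogRecord]
    trajectory: pd.DataFrame
    metrics: dict
    assay_points: list[AssayPoint] = field(default_factory=list)
    assay_table: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# Settling metrics
# --------------------------------------------------------------------------

def compute_settling_metrics(
    log: list[LogRecord], band: float = 0.05, tail_fraction: float = 0.2
) -> dict:
    """Per-dwell settling statistics from a run log.

    A *dwell* is a maximal stretch of constant setpoint. For each dwell:
    time from dwell start until |pH - setpoint| first drops below ``band``,
    mean absolute error over the final ``tail_fraction`` of the dwell, the
    maximum commanded power, and the total time spent at full power.
    All times are relative to the dwell start, so the metrics are invariant
    to a global timestamp offset. A log without any setpoint change yields
    an empty per-dwell list for the changes-dependent entries rather than an
    error.
    """
    if not log:
        return {"dwells": [], "n_setpoint_changes": 0}
    dwells: list[list[LogRecord]] = [[log[0]]]
    for rec in log[1:]:
        if rec.setpoint != dwells[-1][-1].setpoint:
            dwells.append([rec])
        else:
            dwells[-1].append(rec)
    tick = log[1].time_s - log[0].time_s if len(log) > 1 else 1.0
    out = []
    for recs in dwells:
        t0 = recs[0].time_s
        errors = np.array([abs(r.ph - r.setpoint) for r in recs])
        inside = np.nonzero(errors < band)[0]
        time_to_band = float(recs[inside[0]].time_s - t0) if inside.size else None
        n_tail = max(1, int(round(tail_fraction * len(recs))))
        tail_error = float(errors[-n_tail:].mean())
        powers = np.array([r.intensity for r in recs])
        out.append(
            {
                "setpoint": recs[0].setpoint,
                "duration_s": float(recs[-1].time_s - t0 + tick),
                "time_to_band_s": time_to_band,
                "steady_state_abs_error": tail_error,
                "max_power": float(powers.max()),
                "saturation_s": float((powers >= 1.0 - 1e-9).sum() * tick),
            }
        )
    return {"dwells": out, "n_setpoint_changes": len(dwells) - 1}


# --------------------------------------------------------------------------
# Closed-loop scenarios
# --------------------------------------------------------------------------

def _setup(config: RunConfig | None, seed: int | None, with_gdh: bool = False):
    cfg = config or default_config()
    seed = cfg.seed if seed is None else seed
    model = cfg.build_plant(with_gdh=with_gdh)
    electrode = cfg.build_electrode(seed=child_seed(seed, "electrode"))
    cal = calibrate_from_buffers(cfg.build_electrode(seed=child_seed(seed, "calibration")))
    ctrl = cfg.build_controller()
    return cfg, seed, model, electrode, cal, ctrl


def scenario_staircase(
    config: RunConfig | None = None, seed: int | None = None
) -> ScenarioResult:
    """Staircase of setpoints between pH 6 and 7 with fixed dwells."""
    cfg, seed, model, electrode, cal, ctrl = _setup(config, seed)
    sc = cfg.scenario
    entries = [
        (i * sc.dwell_s, sp) for i, sp in enumerate(sc.staircase_setpoints)
    ]
    schedule = SetpointSchedule(tuple(entries))
    state = wash_to_pH(sc.staircase_setpoints[0])
    result = run_closed_loop(
        model,
        state,
        electrode,
        cal,
        ctrl,
        schedule,
        duration=sc.dwell_s * len(sc.staircase_setpoints),
        seed=seed,
        dt=sc.integrator_dt_s,
    )
    metrics = compute_settling_metrics(result.log)
    return ScenarioResult("staircase", result.log, result.trajectory, metrics)


def scenario_range_test(
    config: RunConfig | None = None, seed: int | None = None
) -> ScenarioResult:
    """Qualification run: 5.9 -> 7.2 -> 5.9 from a washed pH-6 prep.

    The headline metric ``achieved_span_ph`` is max - min of the true bulk
    pH; preparations covering at least one unit qualify for enzymatic runs.
    """
    cfg, seed, model, electrode, cal, ctrl = _setup(config, seed)
    sc = cfg.scenario
    d = sc.range_test_dwell_s
    schedule = SetpointSchedule(
        ((0.0, sc.range_test_low), (d, sc.range_test_high), (2 * d, sc.range_test_low))
    )
    state = wash_to_pH(6.0)
    result = run_closed_loop(
        model, state, electrode, cal, ctrl, schedule,
        duration=3 * d, seed=seed, dt=sc.integrator_dt_s,
    )
    ph = result.trajectory["ph_out"]
    metrics = compute_settling_metrics(result.log)
    metrics.update(
        {
            "achieved_span_ph": float(ph.max() - ph.min()),
            "max_ph": float(ph.max()),
            "min_ph": float(ph.min()),
        }
    )
    return ScenarioResult("range_test", result.log, result.trajectory, metrics)


def _turning_point(trajectory: pd.DataFrame, after_s: float, bin_s: float = 60.0):
    """Time of the pH turning point after ``after_s``.

    The trace is binned, and the turning point is the first local minimum
    of the binned pH rate after the setpoint switch (the moment the
    pump-driven rise hands over to the enzyme-driven rise); if the rate
    actually changes sign (a dip), the first sign change wins.
    """
    t = trajectory["t"].to_numpy()
    ph = trajectory["ph_out"].to_numpy()
    if t[-1] <= after_s:
        return None
    edges = np.arange(after_s, t[-1], bin_s)
    if edges.size < 4:
        return None
    idx = np.searchsorted(t, edges)
    idx = np.unique(np.clip(idx, 0, t.size - 1))
    tb, phb = t[idx], ph[idx]
    rate = np.diff(phb) / np.diff(tb)
    mid = 0.5 * (tb[:-1] + tb[1:])
    # first dip-then-rise sign change
    for i in range(1, rate.size):
        if rate[i - 1] <= 0.0 < rate[i]:
            return float(mid[i])
    # else: first strict local minimum of the rate
    for i in range(1, rate.size - 1):
        if rate[i] < rate[i - 1] and rate[i] <= rate[i + 1]:
            return float(mid[i])
    return None


def scenario_gdh_run(
    config: RunConfig | None = None, seed: int | None = None
) -> ScenarioResult:
    """Light-controlled GDH reaction: hold pH 6, then release to 8.5.

    Phase 1 holds the mixture at pH 6 (blue light, unfavorably low pH keeps
    the enzyme slow); after ``gdh_phase1_s`` the setpoint jumps to 8.5, red
    light saturates, and the reaction accelerates as the pH climbs, pushing
    the pH beyond the pump limit. Aliquots are sampled on a fixed interval
    and reduced to background-corrected A340 points aligned with the pH log.
    """
    cfg, seed, model, electrode, cal, ctrl = _setup(config, seed, with_gdh=True)
    sc = cfg.scenario
    duration = sc.gdh_phase1_s + sc.gdh_phase2_s
    schedule = SetpointSchedule(
        ((0.0, sc.gdh_setpoint_low), (sc.gdh_phase1_s, sc.gdh_setpoint_high))
    )
    state = with_substrates(wash_to_pH(6.0))
    sample_times = np.arange(0.0, duration + 1e-9, sc.assay_interval_s)
    result = run_closed_loop(
        model, state, electrode, cal, ctrl, schedule,
        duration=duration, seed=seed, dt=sc.integrator_dt_s,
        sample_times=sample_times,
    )
    nadh_series = [s.nadh for _, s in result.samples]
    times = [t for t, _ in result.samples]
    raw = generate_assay_spectra(
        nadh_series, times, noise_sd=sc.assay_noise_sd,
        seed=child_seed(seed, "assay"),
    )
    points = [extract_A340(s) for s in raw]
    log_df = pd.DataFrame(
        {"t": [r.time_s for r in result.log], "ph": [r.ph for r in result.log]}
    )
    ph_at = np.interp(times, log_df["t"], log_df["ph"])
    assay_table = pd.DataFrame(
        {
            "time_s": times,
            "pH": ph_at,
            "a340": [p.a340 for p in points],
            "sd": [p.sd for p in points],
        }
    )
    steps = -np.diff([p.a340 for p in points])
    metrics = compute_settling_metrics(result.log)
    metrics.update(
        {
            "turning_point_s": _turning_point(result.trajectory, sc.gdh_phase1_s),
            "nadh_consumed_mm": float(nadh_series[0] - nadh_series[-1]),
            "phase1_nadh_consumed_mm": float(
                nadh_series[0]
                - nadh_series[int(sc.gdh_phase1_s // sc.assay_interval_s)]
            ),
            "a340_step_first": float(steps[0]) if steps.size else None,
            "a340_step_max": float(steps.max()) if steps.size else None,
            "a340_step_last": float(steps[-1]) if steps.size else None,
            "max_ph": float(result.trajectory["ph_out"].max()),
        }
    )
    return ScenarioResult(
        "gdh_run", result.log, result.trajectory, metrics,
        assay_points=points, assay_table=assay_table,
    )


# --------------------------------------------------------------------------
# Open-loop sweeps
# --------------------------------------------------------------------------

def _drive_to_plateau(
    model, state: PlantState, powers: dict, sc, duration_s: float | None
) -> PlantState:
    """Integrate under constant light either for a fixed time or to plateau.

    Plateau = |dpH/dt| below ``plateau_rate_ph_per_s`` sustained for
    ``plateau_hold_s``, with a hard cap of ``plateau_cap_s``.
    """
    if duration_s is not None:
        return simulate(model, state, powers, duration_s, dt=sc.integrator_dt_s)
    chunk = sc.plateau_hold_s
    elapsed = 0.0
    while elapsed < sc.plateau_cap_s:
        nxt = simulate(model, state, powers, chunk, dt=sc.integrator_dt_s)
        rate = abs(nxt.ph_out - state.ph_out) / chunk
        state = nxt
        elapsed += chunk
        if rate < sc.plateau_rate_ph_per_s:
            break
    return state


def scenario_range_sweep(
    start_phs,
    config: RunConfig | None = None,
    duration_s: float | None = None,
) -> pd.DataFrame:
    """Maximal up/down pH ranges versus starting pH.

    For each starting pH: wash, apply full blue until plateau (or for
    ``duration_s``), record the downward range; re-wash, full red, record the
    upward range. Returns a table with signed ranges and the total span.
    """
    cfg = config or default_config()
    sc = cfg.scenario
    model = cfg.build_plant()
    rows = []
    for start in start_phs:
        if not 3.0 < start < 12.0:
            raise ParameterError(f"start pH {start} outside (3, 12)")
        down = _drive_to_plateau(
            model, wash_to_pH(start), {"blue": 1.0, "red": 0.0}, sc, duration_s
        )
        up = _drive_to_plateau(
            model, wash_to_pH(start), {"blue": 0.0, "red": 1.0}, sc, duration_s
        )
        rows.append(
            {
                "start_ph": float(start),
                "down_range": float(down.ph_out - start),
                "up_range": float(up.ph_out - start),
                "total_span": float(up.ph_out - down.ph_out),
            }
        )
    return pd.DataFrame(rows)


def evanescence_limit(
    side: str,
    config: RunConfig | None = None,
    step: float = 0.5,
    duration_s: float | None = None,
    threshold: float | None = None,
) -> dict:
    """Starting pH at which pumping activity becomes evanescent.

    ``side='acidic'``: sweep starting pH 3.5-8.0 under full blue light and
    report the lowest start that still moves the bulk pH by more than the
    threshold within the sweep duration, minus one step — the pH where
    activity has vanished. ``side='basic'``: mirror sweep 8.0-11.5 under
    full red light, reporting the highest active start plus one step.
    """
    cfg = config or default_config()
    sc = cfg.scenario
    duration_s = sc.sweep_duration_s if duration_s is None else duration_s
    threshold = sc.sweep_threshold_ph if threshold is None else threshold
    model = cfg.build_plant()
    if side == "acidic":
        starts = np.arange(3.5, 8.0 + 1e-9, step)
        powers = {"blue": 1.0, "red": 0.0}
    elif side == "basic":
        starts = np.arange(8.0, 11.5 + 1e-9, step)
        powers = {"blue": 0.0, "red": 1.0}
    else:
        raise ParameterError("side must be 'acidic' or 'basic'")
    deltas = []
    for start in starts:
        final = simulate(model, wash_to_pH(float(start)), powers, duration_s,
                         dt=sc.integrator_dt_s)
        deltas.append(abs(final.ph_out - start))
    deltas = np.asarray(deltas)
    active = deltas > threshold
    if side == "acidic":
        if not active.any():
            limit = float(starts[-1])
        else:
            limit = float(starts[active.argmax()] - step)
    else:
        if not active.any():
            limit = float(starts[0])
        else:
            last = len(starts) - 1 - int(active[::-1].argmax())
            limit = float(starts[last] + step)
    return {
        "side": side,
        "limit_ph": limit,
        "starts": starts.tolist(),
        "abs_delta_ph": deltas.tolist(),
        "threshold": threshold,
        "duration_s": duration_s,
    }


SCENARIOS = {
    "staircase": scenario_staircase,
    "range-test": scenario_range_test,
    "gdh-run": scenario_gdh_run,
}
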