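"""Two-compartment digital twin of the proteoliposome suspension.

The "plant" of the control loop is a stirred ~150 uL suspension of DOPC
vesicles co-reconstituted with two light-driven proton pumps in opposite
orientations: BPR (pumps protons out of the lumen, acidifying the bulk under
blue light) and BR (pumps protons into the lumen, alkalinizing the bulk under
red light). The model lumps the whole vesicle population into a single pair
of compartments (extravesicular bulk / vesicle lumen) coupled by pump fluxes
and a slow transmembrane proton leak.

Flux law
--------
Each pump contributes a proton flux onto the extravesicular solution

    flux = direction * jmax * pool * orientation * drive * backpressure * window

* ``drive``   - sum over LED colors of activation coefficient x power in [0,1]
  (spectral overlap, :mod:`chromostat.spectra`);
* ``backpressure = max(0, 1 - dpH_signed / dpH_max)`` - a pump stalls once the
  pH gradient it has built across the membrane reaches ``dpH_max`` (it cannot
  pump against an established proton gradient); ``dpH_signed`` is measured
  along the pump's own direction, so a favorable gradient speeds it up;
* ``window``  - a logistic window in the *absolute* extravesicular pH with
  soft limits ``ph_lo``/``ph_hi``, capturing the loss of pumping at extreme
  bulk pH;
* ``pool``    - relative molar amount of the pump (BPR:BR = 2:1 by weight and,
  at ~20 kDa each, by moles);
* ``orientation`` - net orientation factor. Two-thirds of BR inserts with the
  C-terminus out; the mis-oriented third pumps the opposite way with the same
  kinetics, leaving a net factor 2f - 1 = 1/3. BPR inserts uniformly (factor 1).

Fluxes are expressed in pH-units/s referenced to the *washed* bulk buffer
capacity ``beta_out``; internally they are converted to acid equivalents
(mM/s) so that buffer-weighted proton bookkeeping between the compartments is
exact. Adding the GDH substrate mix raises the bulk buffer capacity by
``beta_substrate`` and correspondingly slows all pH excursions — the main
practical difficulty of driving reactions with this actuator.

The optional glutamate dehydrogenase reaction

    alpha-ketoglutarate + NH4+ + NADH + H+  ->  L-glutamate + NAD+ + H2O

consumes one extravesicular proton per NADH oxidized, modeled forward-only
with Michaelis-Menten substrate terms and a Gaussian bell in pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ActuationError, ParameterError
from .seeding import child_rng
from .spectra import (
    LightSourceModel,
    PumpPhotoModel,
    activation_coefficient,
    default_bpr,
    default_br,
    default_led,
)

__all__ = [
    "VesiclePreparation",
    "PumpKineticParams",
    "PlantParams",
    "GDHParams",
    "PlantState",
    "ElectrodeModel",
    "LightGatedPump",
    "PlantModel",
    "pump_flux",
    "gdh_rate",
    "plant_derivatives",
    "step_plant",
    "simulate",
    "wash_to_pH",
    "with_substrates",
    "measure_voltage",
    "sample_vesicle_population",
    "simulate_digestion_assay",
    "DigestionResult",
    "build_default_plant",
    "GDH_MIX_MM",
]

#: Final substrate concentrations of the enzymatic run (mM):
#: 1.25 alpha-ketoglutarate, 5 NH4Cl, 2 NADH.
GDH_MIX_MM = {"akg": 1.25, "nh4": 5.0, "nadh": 2.0}

#: Calibrated per-pump rate constants (pH-units/s at full activation per
#: unit pool, washed buffer reference). BR is intrinsically the stronger
#: pump here; BPR dominates blue-light behavior through its 2x pool and
#: near-optimal spectral overlap with the blue LED.
BR_JMAX_DEFAULT = 0.02
BPR_JMAX_DEFAULT = 0.01


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VesiclePreparation:
    """Composition and orientation statistics of one vesicle prep.

    Defaults reproduce the characterized preparation: ~20 nM particles of
    ~130 nm mean diameter, BPR:BR 2:1 (w/w), two-thirds of BR C-termini
    facing out, all BPR C-termini facing the lumen.
    """

    particle_conc_nm: float = 20.0
    #: lognormal parameters on the nm scale; the analytic mean
    #: exp(logmu + logsigma**2 / 2) equals 130 nm with the defaults.
    diameter_logmu: float = math.log(130.0) - 0.5 * 0.35**2
    diameter_logsigma: float = 0.35
    mass_ratio_bpr_to_br: float = 2.0
    br_out_fraction: float = 2.0 / 3.0
    bpr_in_fraction: float = 1.0
    #: model the mis-oriented pump fraction as pumping the opposite way
    #: (net factor 2f - 1); if False the minority fraction is simply inert.
    counter_pumping: bool = True

    def __post_init__(self) -> None:
        if self.particle_conc_nm <= 0:
            raise ParameterError("particle concentration must be > 0")
        if self.diameter_logsigma < 0:
            raise ParameterError("diameter_logsigma must be >= 0")
        if self.mass_ratio_bpr_to_br <= 0:
            raise ParameterError("mass ratio must be > 0")
        for name in ("br_out_fraction", "bpr_in_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")

    def orientation_factor(self, pump: str) -> float:
        """Net pumping factor from the majority-orientation fraction."""
        f = self.br_out_fraction if pump == "BR" else self.bpr_in_fraction
        return 2.0 * f - 1.0 if self.counter_pumping else f

    def pool(self, pump: str) -> float:
        """Relative molar pool (both pumps ~20 kDa, so w/w ratio = molar)."""
        return self.mass_ratio_bpr_to_br if pump == "BPR" else 1.0


@dataclass(frozen=True)
class PumpKineticParams:
    """Lumped kinetics of one pump population.

    ``jmax`` is the pH-units/s contribution at full activation per unit
    effective pump pool, referenced to the washed bulk buffer capacity.
    """

    jmax: float = 0.01
    dph_max: float = 2.8
    ph_lo: float = 5.0
    ph_hi: float = 10.2
    logistic_width: float = 0.15

    def __post_init__(self) -> None:
        if self.jmax < 0:
            raise ParameterError("jmax must be >= 0")
        if self.dph_max <= 0:
            raise ParameterError("dph_max must be > 0")
        if self.ph_lo >= self.ph_hi:
            raise ParameterError("ph_lo must be < ph_hi")
        if self.logistic_width <= 0:
            raise ParameterError("logistic_width must be > 0")


@dataclass(frozen=True)
class PlantParams:
    """Bulk/lumen buffering, leak, and geometry.

    Buffer capacities convert acid-equivalent fluxes (mM/s) into pH rates.
    ``beta_substrate`` is added to ``beta_out`` while the GDH substrate mix
    is present. ``leak_rate`` is the first-order relaxation rate of the
    transmembrane pH gradient.
    """

    beta_out: float = 0.5
    beta_substrate: float = 1.0
    beta_in: float = 5.0
    leak_rate: float = 2.0e-4
    volume_out_ul: float = 150.0
    volume_in_ul: float = 15.0
    temperature_c: float = 21.0  # informational

    def __post_init__(self) -> None:
        if self.beta_out <= 0 or self.beta_in <= 0:
            raise ParameterError("buffer capacities must be > 0")
        if self.beta_substrate < 0:
            raise ParameterError("beta_substrate must be >= 0")
        if self.leak_rate < 0:
            raise ParameterError("leak_rate must be >= 0")
        if self.volume_out_ul <= 0 or self.volume_in_ul <= 0:
            raise ParameterError("volumes must be > 0")


@dataclass(frozen=True)
class GDHParams:
    """Glutamate dehydrogenase kinetics (forward direction only)."""

    vmax: float = 5.0e-3  # mM/s
    km_akg: float = 0.6  # mM
    km_nh4: float = 1.0  # mM
    km_nadh: float = 0.2  # mM
    ph_opt: float = 8.0
    ph_width: float = 0.8

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ParameterError("vmax must be >= 0")
        for name in ("km_akg", "km_nh4", "km_nadh", "ph_opt", "ph_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class PlantState:
    """Instantaneous state: time, both compartment pHs, substrate pools (mM)."""

    t: float = 0.0
    ph_out: float = 7.0
    ph_in: float = 7.0
    akg: float = 0.0
    nh4: float = 0.0
    nadh: float = 0.0
    glu: float = 0.0
    nad: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ph_out", "ph_in"):
            ph = getattr(self, name)
            if not 0.0 < ph < 14.0:
                raise ParameterError(f"{name}={ph} outside (0, 14)")
        for name in ("akg", "nh4", "nadh", "glu", "nad"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def as_vector(self) -> tuple[float, ...]:
        return (self.ph_out, self.ph_in, self.akg, self.nh4, self.nadh, self.glu, self.nad)

    @classmethod
    def from_vector(cls, t: float, y: Sequence[float]) -> "PlantState":
        return cls(t, *map(float, y))


@dataclass(frozen=True)
class StateDerivative:
    """Time-derivatives of :class:`PlantState` fields (pH/s and mM/s)."""

    ph_out: float
    ph_in: float
    akg: float
    nh4: float
    nadh: float
    glu: float
    nad: float


# --------------------------------------------------------------------------
# Pumps
# --------------------------------------------------------------------------

def _validate_powers(powers: Mapping[str, float]) -> None:
    for color, p in powers.items():
        if not 0.0 <= p <= 1.0:
            raise ActuationError(f"power[{color}]={p} outside [0, 1]")


@dataclass(frozen=True)
class LightGatedPump:
    """One assembled pump population: photophysics + kinetics + prep weights.

    ``activations`` maps LED color -> spectral activation coefficient,
    precomputed against the installed LED models.
    """

    photo: PumpPhotoModel
    kinetics: PumpKineticParams
    pool: float
    orientation_factor: float
    activations: Mapping[str, float]

    @property
    def name(self) -> str:
        return self.photo.name

    def flux(self, state: PlantState, powers: Mapping[str, float]) -> float:
        return pump_flux(self, state, powers)


def pump_flux(
    pump: LightGatedPump, state: PlantState, powers: Mapping[str, float]
) -> float:
    """Signed proton flux of one pump onto the bulk, in pH-units/s.

    Positive flux adds protons to (acidifies) the extravesicular solution.
    Zero whenever all powers are zero, the opposing gradient has reached
    ``dph_max``, or the bulk pH sits outside the logistic activity window.
    """
    _validate_powers(powers)
    kin = pump.kinetics
    d = float(pump.photo.direction)
    drive = sum(pump.activations.get(c, 0.0) * p for c, p in powers.items())
    if drive == 0.0:
        return 0.0
    # Gradient built along the pump's own direction opposes further pumping.
    dph_signed = d * (state.ph_in - state.ph_out)
    backpressure = max(0.0, 1.0 - dph_signed / kin.dph_max)
    w = kin.logistic_width
    window = _logistic((state.ph_out - kin.ph_lo) / w) * _logistic(
        (kin.ph_hi - state.ph_out) / w
    )
    return d * kin.jmax * pump.pool * pump.orientation_factor * drive * backpressure * window


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


# --------------------------------------------------------------------------
# Enzyme
# --------------------------------------------------------------------------

def gdh_rate(p: GDHParams, state: PlantState) -> float:
    """Forward GDH rate in mM/s at the current bulk pH and substrate pools.

    ``vmax`` times a Gaussian bell in pH times a product of Michaelis-Menten
    saturation terms; exactly zero if any substrate pool is empty.
    """
    if state.akg <= 0.0 or state.nh4 <= 0.0 or state.nadh <= 0.0:
        return 0.0
    bell = math.exp(-0.5 * ((state.ph_out - p.ph_opt) / p.ph_width) ** 2)
    mm = (
        state.akg / (state.akg + p.km_akg)
        * state.nh4 / (state.nh4 + p.km_nh4)
        * state.nadh / (state.nadh + p.km_nadh)
    )
    return p.vmax * bell * mm


# --------------------------------------------------------------------------
# Assembled plant and dynamics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantModel:
    """Everything needed to evaluate the plant dynamics."""

    prep: VesiclePreparation
    params: PlantParams
    pumps: tuple[LightGatedPump, ...]
    gdh: GDHParams | None = None
    #: True while the GDH substrate mix is in the vessel (adds buffer).
    substrate_buffer: bool = False

    @property
    def beta_out_effective(self) -> float:
        b = self.params.beta_out
        if self.substrate_buffer:
            b += self.params.beta_substrate
        return b

    def rhs(self) -> Callable[[tuple[float, ...], float, float], tuple[float, ...]]:
        """Compile the derivative function over raw state vectors.

        Returns ``f(y, power_blue, power_red) -> dy/dt`` with
        ``y = (ph_out, ph_in, akg, nh4, nadh, glu, nad)``. Used by the
        integrators; :func:`plant_derivatives` is the dataclass-level view
        of the same math.
        """
        p = self.params
        beta0 = p.beta_out  # jmax reference capacity (washed prep)
        beta_eff = self.beta_out_effective
        vol_ratio = p.volume_out_ul / p.volume_in_ul
        beta_in = p.beta_in
        leak_rate = p.leak_rate
        # leak acid flux scale chosen so the gradient relaxes at leak_rate
        leak_scale = beta_in / vol_ratio
        gdh = self.gdh
        pumps = [
            (
                float(pp.photo.direction),
                pp.kinetics.jmax * pp.pool * pp.orientation_factor,
                pp.kinetics.dph_max,
                pp.kinetics.ph_lo,
                pp.kinetics.ph_hi,
                pp.kinetics.logistic_width,
                pp.activations.get("blue", 0.0),
                pp.activations.get("red", 0.0),
            )
            for pp in self.pumps
        ]

        def f(y: tuple[float, ...], pb: float, pr: float) -> tuple[float, ...]:
            ph_out, ph_in, akg, nh4, nadh, glu, nad = y
            # pump fluxes -> acid equivalents added to the bulk (mM/s)
            j_pump = 0.0
            for d, jeff, dmax, lo, hi, w, ab, ar in pumps:
                drive = ab * pb + ar * pr
                if drive == 0.0 or jeff == 0.0:
                    continue
                bp = 1.0 - d * (ph_in - ph_out) / dmax
                if bp <= 0.0:
                    continue
                window = _logistic((ph_out - lo) / w) * _logistic((hi - ph_out) / w)
                j_pump += d * jeff * drive * bp * window
            j_pump *= beta0
            # transmembrane leak: protons flow down their gradient
            j_leak = leak_rate * (ph_out - ph_in) * leak_scale
            # enzyme: consumes one bulk proton per NADH oxidized
            if gdh is not None and akg > 0.0 and nh4 > 0.0 and nadh > 0.0:
                bell = math.exp(-0.5 * ((ph_out - gdh.ph_opt) / gdh.ph_width) ** 2)
                v = (
                    gdh.vmax
                    * bell
                    * akg / (akg + gdh.km_akg)
                    * nh4 / (nh4 + gdh.km_nh4)
                    * nadh / (nadh + gdh.km_nadh)
                )
            else:
                v = 0.0
            dph_out = -(j_pump + j_leak - v) / beta_eff
            dph_in = (j_pump + j_leak) * vol_ratio / beta_in
            return (dph_out, dph_in, -v, -v, -v, v, v)

        return f


def plant_derivatives(
    model: PlantModel, state: PlantState, powers: Mapping[str, float]
) -> StateDerivative:
    """Time-derivatives of every :class:`PlantState` field.

    Acid equivalents removed from the lumen appear in the bulk exactly
    (buffer-weighted proton conservation); substrate derivatives follow the
    1:1:1 -> 1:1 stoichiometry of the GDH reaction.
    """
    _validate_powers(powers)
    f = model.rhs()
    dy = f(state.as_vector(), powers.get("blue", 0.0), powers.get("red", 0.0))
    return StateDerivative(*dy)


def _rebalance_clamp(y: list[float]) -> list[float]:
    """Clamp pools at zero, preserving nadh+nad and akg+glu totals."""
    # pairs: (nadh idx 4, nad idx 6), (akg idx 2, glu idx 5)
    for a, b in ((4, 6), (2, 5)):
        if y[a] < 0.0:
            y[b] += y[a]
            y[a] = 0.0
        elif y[b] < 0.0:
            y[a] += y[b]
            y[b] = 0.0
    if y[3] < 0.0:  # nh4 has no tracked partner
        y[3] = 0.0
    for i in (2, 3, 4, 5, 6):
        if y[i] < 0.0:
            y[i] = 0.0
    return y


def step_plant(
    model: PlantModel,
    state: PlantState,
    powers: Mapping[str, float],
    dt: float,
    method: str = "rk4",
) -> PlantState:
    """Advance the plant by one step of ``dt`` seconds (euler or rk4)."""
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    _validate_powers(powers)
    if method not in ("euler", "rk4"):
        raise ParameterError(f"unknown integration method {method!r}")
    f = model.rhs()
    pb = powers.get("blue", 0.0)
    pr = powers.get("red", 0.0)
    y = _advance(f, state.as_vector(), pb, pr, dt, 1, method)
    return PlantState.from_vector(state.t + dt, y)


def _advance(
    f: Callable,
    y: tuple[float, ...],
    pb: float,
    pr: float,
    dt: float,
    n_steps: int,
    method: str,
) -> list[float]:
    yv = list(y)
    if method == "euler":
        for _ in range(n_steps):
            dy = f(tuple(yv), pb, pr)
            for i in range(7):
                yv[i] += dt * dy[i]
            yv = _rebalance_clamp(yv)
        return yv
    h2 = dt / 2.0
    h6 = dt / 6.0
    for _ in range(n_steps):
        y0 = tuple(yv)
        k1 = f(y0, pb, pr)
        k2 = f(tuple(y0[i] + h2 * k1[i] for i in range(7)), pb, pr)
        k3 = f(tuple(y0[i] + h2 * k2[i] for i in range(7)), pb, pr)
        k4 = f(tuple(y0[i] + dt * k3[i] for i in range(7)), pb, pr)
        yv = [y0[i] + h6 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) for i in range(7)]
        yv = _rebalance_clamp(yv)
    return yv


def simulate(
    model: PlantModel,
    state: PlantState,
    powers: Mapping[str, float],
    duration: float,
    dt: float = 0.1,
    method: str = "rk4",
) -> PlantState:
    """Integrate under constant illumination for ``duration`` seconds."""
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    _validate_powers(powers)
    if method not in ("euler", "rk4"):
        raise ParameterError(f"unknown integration method {method!r}")
    n = max(1, int(round(duration / dt)))
    f = model.rhs()
    y = _advance(
        f, state.as_vector(), powers.get("blue", 0.0), powers.get("red", 0.0), dt, n, method
    )
    return PlantState.from_vector(state.t + n * dt, y)


def wash_to_pH(target_ph: float, t: float = 0.0) -> PlantState:
    """State after washing the prep into unbuffered saline at ``target_ph``.

    Both compartments equilibrate to the wash pH (zero gradient), substrate
    pools are removed, and the clock is reset. Idempotent.
    """
    if not 3.0 <= target_ph <= 12.0:
        raise ParameterError(f"wash target pH {target_ph} outside [3, 12]")
    return PlantState(t=t, ph_out=target_ph, ph_in=target_ph)


def with_substrates(
    state: PlantState,
    akg: float = GDH_MIX_MM["akg"],
    nh4: float = GDH_MIX_MM["nh4"],
    nadh: float = GDH_MIX_MM["nadh"],
) -> PlantState:
    """Add the GDH substrate mix to an existing state (defaults: assay mix)."""
    for name, v in (("akg", akg), ("nh4", nh4), ("nadh", nadh)):
        if v < 0:
            raise ParameterError(f"{name} must be >= 0")
    return replace(state, akg=akg, nh4=nh4, nadh=nadh, glu=0.0, nad=0.0)


# --------------------------------------------------------------------------
# Electrode
# --------------------------------------------------------------------------

@dataclass
class ElectrodeModel:
    """Affine pH electrode with Gaussian read noise.

    ``measure`` draws from a generator seeded at construction (or at the
    last ``reset``), so two electrodes with equal seeds produce identical
    voltage sequences.
    """

    slope: float = -0.057  # V per pH unit
    intercept: float = 2.5  # V
    noise_sd: float = 0.002  # V per raw read
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ParameterError("electrode slope must be nonzero")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        self._rng = np.random.default_rng(self.seed)

    def reset(self, seed: int | None = None) -> None:
        if seed is not None:
            self.seed = seed
        self._rng = np.random.default_rng(self.seed)

    def measure(self, ph: float, n_average: int = 1) -> float:
        """One (optionally ADC-oversampled) voltage reading at true ``ph``."""
        if n_average < 1:
            raise ParameterError("n_average must be >= 1")
        v = self.slope * ph + self.intercept
        if self.noise_sd == 0.0:
            return v
        noise = self._rng.normal(0.0, self.noise_sd, size=n_average).mean()
        return v + float(noise)


def measure_voltage(e: ElectrodeModel, ph: float, n_average: int = 1) -> float:
    """Functional alias for :meth:`ElectrodeModel.measure`."""
    return e.measure(ph, n_average)


# --------------------------------------------------------------------------
# Population / orientation generators
# --------------------------------------------------------------------------

def sample_vesicle_population(
    prep: VesiclePreparation, n: int, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Draw ``n`` vesicle diameters (nm) as in a nanoparticle-tracking run.

    Returns the diameters and a summary with the sample mean/median/SD, the
    analytic lognormal mean, and the configured particle concentration.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = child_rng(seed, "vesicle-population")
    diameters = rng.lognormal(prep.diameter_logmu, prep.diameter_logsigma, size=n)
    summary = {
        "n": int(n),
        "mean_diameter_nm": float(diameters.mean()),
        "median_diameter_nm": float(np.median(diameters)),
        "sd_diameter_nm": float(diameters.std(ddof=1)) if n > 1 else 0.0,
        "analytic_mean_nm": float(
            math.exp(prep.diameter_logmu + 0.5 * prep.diameter_logsigma**2)
        ),
        "particle_conc_nm": float(prep.particle_conc_nm),
    }
    return diameters, summary


@dataclass(frozen=True)
class DigestionResult:
    """Digested fraction of one pump species with its exact binomial 95% CI."""

    species: str
    n: int
    n_digested: int
    fraction: float
    ci_low: float
    ci_high: float


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def simulate_digestion_assay(
    prep: VesiclePreparation, n_molecules: int, seed: int = 0
) -> dict[str, DigestionResult]:
    """Carboxypeptidase accessibility assay on ``n_molecules`` of each pump.

    A C-terminus is digested iff it faces the extravesicular solution, so the
    per-molecule digestion probability is the outward-C-terminus fraction:
    ``br_out_fraction`` for BR and ``1 - bpr_in_fraction`` for BPR.
    """
    if n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")
    rng = child_rng(seed, "digestion-assay")
    out: dict[str, DigestionResult] = {}
    for species, p in (
        ("BR", prep.br_out_fraction),
        ("BPR", 1.0 - prep.bpr_in_fraction),
    ):
        k = int(rng.binomial(n_molecules, p))
        lo, hi = _clopper_pearson(k, n_molecules)
        out[species] = DigestionResult(species, n_molecules, k, k / n_molecules, lo, hi)
    return out


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

def build_default_plant(
    *,
    prep: VesiclePreparation | None = None,
    params: PlantParams | None = None,
    br_kinetics: PumpKineticParams | None = None,
    bpr_kinetics: PumpKineticParams | None = None,
    br_photo: PumpPhotoModel | None = None,
    bpr_photo: PumpPhotoModel | None = None,
    leds: Mapping[str, LightSourceModel] | None = None,
    gdh: GDHParams | None = None,
    with_gdh: bool = False,
) -> PlantModel:
    """Assemble a :class:`PlantModel` from defaults, overriding selectively.

    ``with_gdh=True`` installs default GDH kinetics and switches on the
    substrate buffer contribution.
    """
    prep = prep or VesiclePreparation()
    params = params or PlantParams()
    br_photo = br_photo or default_br()
    bpr_photo = bpr_photo or default_bpr()
    if leds is None:
        leds = {"blue": default_led("blue"), "red": default_led("red")}
    if with_gdh and gdh is None:
        gdh = GDHParams()
    pumps = []
    for photo, kin in (
        (br_photo, br_kinetics or PumpKineticParams(jmax=BR_JMAX_DEFAULT)),
        (bpr_photo, bpr_kinetics or PumpKineticParams(jmax=BPR_JMAX_DEFAULT)),
    ):
        acts = {color: activation_coefficient(photo, led) for color, led in leds.items()}
        pumps.append(
            LightGatedPump(
                photo=photo,
                kinetics=kin,
                pool=prep.pool(photo.name),
                orientation_factor=prep.orientation_factor(photo.name),
                activations=acts,
            )
        )
    return PlantModel(
        prep=prep,
        params=params,
        pumps=tuple(pumps),
        gdh=gdh,
        substrate_buffer=gdh is not None,
    )
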