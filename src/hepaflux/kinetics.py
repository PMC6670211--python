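"""Rate laws and the ODE right-hand side of the blood nitrogen model.

Three species are tracked in a single well-mixed blood compartment: total
ammonia (NH3 + NH4+, no distinction made), urea, and glutamine. Three enzyme
fluxes connect them -- glutaminase (GLS, Gln -> NH3), carbamoyl phosphate
synthetase 1 (CPS1, NH3 -> urea, first committed urea-cycle step), and
glutamine synthetase (GLUL, NH3 -> Gln, competitively inhibited by
glutamine) -- plus zero-order dietary ammonia absorption and urinary
ammonia/urea excretion.

Because the urea cycle consumes two nitrogens per urea but CPS1 fixes only
one, a duplicate of the CPS1 flux ("urea for balance") removes a second
ammonia without adding counted product, so each urea carries two nitrogens.

Liver acinus zonation is modeled temporally: during phase 1 (zones 1-2 of the
sinusoid transit) CPS1 and GLS are active; during phase 2 (zone 3) GLUL is
active. Absorption and excretion run unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInput
from .params import Scenario

__all__ = [
    "BloodState",
    "PhaseFlags",
    "FluxVector",
    "EFFLUX_FLOOR_MM",
    "rate_gls",
    "rate_cps1",
    "rate_glul",
    "compute_fluxes",
    "rhs",
]

#: Concentration floor (mM) below which the zero-order effluxes are smoothly
#: switched off so the integrator cannot drive a species negative. Far below
#: every reported concentration (>= uM scale); has no effect on results.
EFFLUX_FLOOR_MM = 1e-6

PHASE1 = 1  # CPS1 + GLS active (acinus zones 1-2)
PHASE2 = 2  # GLUL active (acinus zone 3)


@dataclass(frozen=True)
class BloodState:
    """Blood concentrations in mM (ammonia is total NH3 + NH4+)."""

    nh3: float
    urea: float
    gln: float

    def __post_init__(self):
        if self.nh3 < 0 or self.urea < 0 or self.gln < 0:
            raise InvalidInput("blood concentrations must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.nh3, self.urea, self.gln])


@dataclass(frozen=True)
class PhaseFlags:
    """Which enzyme group is active; exactly one of the two flags is set."""

    cps1_gls_active: bool
    glul_active: bool

    def __post_init__(self):
        if self.cps1_gls_active == self.glul_active:
            raise InvalidInput(
                "exactly one of cps1_gls_active / glul_active must be true"
            )

    @classmethod
    def phase1(cls) -> "PhaseFlags":
        return cls(cps1_gls_active=True, glul_active=False)

    @classmethod
    def phase2(cls) -> "PhaseFlags":
        return cls(cps1_gls_active=False, glul_active=True)


@dataclass(frozen=True)
class FluxVector:
    """Instantaneous reaction fluxes in mmol/min.

    ``v_urea_balance`` is not stored: it equals ``v_cps1`` identically by
    construction (the stoichiometry-balancing duplicate reaction), so a flux
    vector violating that invariant cannot be built.
    """

    v_nh3_abs: float
    v_gls: float
    v_cps1: float
    v_glul: float
    v_nh3_ex: float
    v_urea_ex: float

    @property
    def v_urea_balance(self) -> float:
        return self.v_cps1

    def nitrogen_flux(self) -> float:
        """Net nitrogen inflow to blood, mmol N/min.

        Equals V_blood * d(nh3 + gln + 2*urea)/dt: the enzyme fluxes only
        shuttle nitrogen between the three pools (one urea carries two N), so
        only absorption and the two excretions appear.
        """
        return self.v_nh3_abs - self.v_nh3_ex - 2.0 * self.v_urea_ex


def rate_gls(gln: float, vmax: float, km: float) -> float:
    """Glutaminase flux, mmol/min: Michaelis-Menten in glutamine."""
    if gln < 0:
        raise InvalidInput("gln must be >= 0")
    if km <= 0:
        raise InvalidInput("km must be > 0")
    return vmax * gln / (km + gln)


def rate_cps1(nh3: float, vmax: float, km: float) -> float:
    """CPS1 flux, mmol/min: Michaelis-Menten in total ammonia."""
    if nh3 < 0:
        raise InvalidInput("nh3 must be >= 0")
    if km <= 0:
        raise InvalidInput("km must be > 0")
    return vmax * nh3 / (km + nh3)


def rate_glul(nh3: float, gln: float, vmax: float, km: float, ki: float) -> float:
    """Glutamine synthetase flux, mmol/min.

    Michaelis-Menten in ammonia with competitive inhibition by glutamine:
    the effective Km is ``km * (1 + gln/ki)``, so at gln = ki the apparent
    Km doubles and at gln = 0 the law reduces to plain Michaelis-Menten.
    """
    if nh3 < 0 or gln < 0:
        raise InvalidInput("nh3 and gln must be >= 0")
    if km <= 0 or ki <= 0:
        raise InvalidInput("km and ki must be > 0")
    return vmax * nh3 / (km * (1.0 + gln / ki) + nh3)


def _efflux_switch(conc: float, floor: float = EFFLUX_FLOOR_MM) -> float:
    """Smoothstep from 0 at conc <= 0 to 1 at conc >= floor (C1 continuous)."""
    x = conc / floor
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return x * x * (3.0 - 2.0 * x)


def compute_fluxes(
    state: BloodState, phase: PhaseFlags, scenario: Scenario
) -> FluxVector:
    """Evaluate all reaction fluxes for one state under one zonation phase.

    Enzyme fluxes are zeroed when their phase flag is off; absorption runs
    always; the zero-order effluxes are smoothly gated off below
    :data:`EFFLUX_FLOOR_MM` so they cannot overdraw an empty pool.
    """
    k = scenario.kinetics
    if phase.cps1_gls_active:
        v_gls = rate_gls(state.gln, k.vmax_gls, k.km_gln)
        v_cps1 = rate_cps1(state.nh3, k.vmax_cps1, k.km_nh3_cps1)
        v_glul = 0.0
    else:
        v_gls = 0.0
        v_cps1 = 0.0
        v_glul = rate_glul(state.nh3, state.gln, k.vmax_glul, k.km_nh3_glul, k.ki_gln)
    return FluxVector(
        v_nh3_abs=k.v_nh3_abs,
        v_gls=v_gls,
        v_cps1=v_cps1,
        v_glul=v_glul,
        v_nh3_ex=k.v_nh3_ex * _efflux_switch(state.nh3),
        v_urea_ex=k.v_urea_ex * _efflux_switch(state.urea),
    )


def rhs(state: BloodState, phase: PhaseFlags, scenario: Scenario) -> np.ndarray:
    """Time derivative of (nh3, urea, gln) in mM/min.

    d[NH3]/dt = (abs + GLS - balance - CPS1 - ex - GLUL) / V_blood, where the
    balance flux equals the CPS1 flux, so CPS1 removes two ammonia per urea
    produced; d[urea]/dt = (CPS1 - urea_ex)/V; d[Gln]/dt = (GLUL - GLS)/V.
    """
    f = compute_fluxes(state, phase, scenario)
    v = scenario.physiology.blood_volume_l
    d_nh3 = (
        f.v_nh3_abs + f.v_gls - f.v_urea_balance - f.v_cps1 - f.v_nh3_ex - f.v_glul
    ) / v
    d_urea = (f.v_cps1 - f.v_urea_ex) / v
    d_gln = (f.v_glul - f.v_gls) / v
    return np.array([d_nh3, d_urea, d_gln])


def make_phase_rhs(scenario: Scenario, cps1_gls_active: bool):
    """Build a fast ``f(t, y) -> dy/dt in mM/s`` closure for one phase.

    This is the integrator-facing twin of :func:`rhs`: identical kinetics on
    plain floats, with the single mmol/min -> mM/s conversion applied here.
    Substrate concentrations are clamped at zero inside the Michaelis-Menten
    terms so solver overshoot below zero cannot produce negative fluxes.
    """
    k = scenario.kinetics
    v_blood = scenario.physiology.blood_volume_l
    vabs, vexn, vexu = k.v_nh3_abs, k.v_nh3_ex, k.v_urea_ex
    vg, kmg = k.vmax_gls, k.km_gln
    vc, kmc = k.vmax_cps1, k.km_nh3_cps1
    vu, kmu, ki = k.vmax_glul, k.km_nh3_glul, k.ki_gln
    scale = 1.0 / (v_blood * 60.0)

    def f(t, y):
        nh3 = y[0] if y[0] > 0.0 else 0.0
        urea = y[1] if y[1] > 0.0 else 0.0
        gln = y[2] if y[2] > 0.0 else 0.0
        if cps1_gls_active:
            gls = vg * gln / (kmg + gln)
            cps1 = vc * nh3 / (kmc + nh3)
            glul = 0.0
        else:
            gls = 0.0
            cps1 = 0.0
            glul = vu * nh3 / (kmu * (1.0 + gln / ki) + nh3)
        exn = vexn * _efflux_switch(nh3)
        exu = vexu * _efflux_switch(urea)
        d_nh3 = vabs + gls - 2.0 * cps1 - exn - glul
        d_urea = cps1 - exu
        d_gln = glul - gls
        return (d_nh3 * scale, d_urea * scale, d_gln * scale)

    return f
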