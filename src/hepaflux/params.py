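"""Parameter assembly: literature constants, diet/disease scaling, scenarios.

Every number the model runs on is assembled here from published values: enzyme
specific activities scaled to a whole average male liver (1561 g), dietary
nitrogen absorption derived from protein intake, renal excretion rates anchored
at three canonical diets, and disease conditions expressed as multiplicative
changes of enzyme Vmax values.

Units contract: all fluxes are stored in mmol/min, all concentrations in mM,
volumes in L, masses in g or kg as annotated. Conversion to per-second rates
happens once, inside the integrator (see :mod:`hepaflux.simulate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import InvalidInput, OutOfRange

__all__ = [
    "LiverCondition",
    "PhysiologyConstants",
    "DietSpec",
    "KineticParams",
    "Scenario",
    "nitrogen_absorption_rate",
    "scale_specific_activity",
    "blood_volume_for_mass",
    "cps1_vmax",
    "excretion_rates",
    "build_scenario",
]

NITROGEN_MOLAR_MASS_G = 14.0
MINUTES_PER_DAY = 1440.0

#: Reference individual: blood volume scales linearly with body mass from
#: 5.2 L at 70 kg.
REFERENCE_BODY_MASS_KG = 70.0
REFERENCE_BLOOD_VOLUME_L = 5.2

#: Canonical dietary protein intakes (g/day): recommended, average, high.
DIET_ANCHORS_G = np.array([71.0, 100.0, 122.0])

#: NAG-adjusted whole-liver CPS1 Vmax (mmol/min) at the three canonical diets.
#: N-acetyl-glutamate allosterically activates CPS1 and rises with dietary
#: protein; these constants already fold that activation in.
CPS1_VMAX_ANCHORS = np.array([8.05, 8.47, 8.78])

#: Fully NAG-activated CPS1 capacity (mmol/min), retained for documentation:
#: 45 nmol/min/mg * 0.25 protein fraction * 1561 g liver.
CPS1_VMAX_MAXIMAL = 17.561

#: Urinary ammonia and urea excretion (mmol/min) at the three canonical diets,
#: from reference-range daily amounts assuming constant excretion over 24 h.
NH3_EX_ANCHORS = np.array([0.004, 0.008, 0.012])
UREA_EX_ANCHORS = np.array([0.244, 0.343, 0.417])

#: Whole-liver glutaminase Vmax (91.4 nmol/min/mg, 20% hepatocyte protein).
VMAX_GLS = 28.54
KM_GLN = 4.0  # mM, human recombinant glutaminase
KM_NH3_CPS1 = 0.35  # mM, human recombinant CPS1
#: Whole-liver glutamine synthetase Vmax (0.47 umol/15 min/mg liver tissue,
#: 25% tissue protein).
VMAX_GLUL = 12.3
KM_NH3_GLUL = 0.15  # mM
KI_GLN = 0.6  # mM, competitive product inhibition of GLUL by glutamine

#: Cirrhosis reduces CPS1 Vmax to 70% and GLUL Vmax to 20% of normal;
#: a CPS1 loss-of-function heterozygote retains 50% CPS1 Vmax.
CIRRHOSIS_CPS1_FACTOR = 0.70
CIRRHOSIS_GLUL_FACTOR = 0.20
CPS1_HET_FACTOR = 0.50


class LiverCondition(str, Enum):
    """Liver condition of the simulated individual."""

    NORMAL = "normal"
    CIRRHOSIS = "cirrhosis"
    CPS1_HET = "cps1_het"

    @classmethod
    def parse(cls, value: "LiverCondition | str") -> "LiverCondition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise InvalidInput(
                f"unknown liver condition {value!r}; valid values: {valid}"
            ) from None


@dataclass(frozen=True)
class PhysiologyConstants:
    """Whole-body constants of the simulated average adult male.

    The blood compartment is the only compartment whose volume enters the
    equations; the default 6.59 L is the linear blood-volume estimate for an
    88.7 kg individual, rounded as conventionally reported.
    """

    body_mass_kg: float = 88.7
    liver_mass_g: float = 1561.0
    blood_volume_l: float = 6.59
    sinusoid_transit_s: float = 4.3
    reference_body_mass_kg: float = REFERENCE_BODY_MASS_KG
    reference_blood_volume_l: float = REFERENCE_BLOOD_VOLUME_L

    def __post_init__(self):
        for name in (
            "body_mass_kg",
            "liver_mass_g",
            "blood_volume_l",
            "sinusoid_transit_s",
            "reference_body_mass_kg",
            "reference_blood_volume_l",
        ):
            if not getattr(self, name) > 0:
                raise InvalidInput(f"{name} must be strictly positive")


@dataclass(frozen=True)
class DietSpec:
    """Dietary protein intake and the nitrogen bookkeeping fractions.

    Protein is 16% nitrogen by mass; 12.7% of ingested nitrogen is lost in
    feces. The remainder is assumed absorbed at a constant rate over 24 h
    (continuous nutritional supply; no discrete meals).
    """

    protein_g_per_day: float
    nitrogen_mass_fraction: float = 0.16
    fecal_loss_fraction: float = 0.127

    def __post_init__(self):
        if self.protein_g_per_day < 0:
            raise InvalidInput("protein_g_per_day must be >= 0")
        for name in ("nitrogen_mass_fraction", "fecal_loss_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidInput(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class KineticParams:
    """Resolved kinetic constants of one scenario.

    Vmax values are whole-liver capacities in mmol/min; Km/Ki are in mM.
    The absorption and excretion terms are zero-order rates in mmol/min.
    """

    vmax_gls: float
    km_gln: float
    vmax_cps1: float
    km_nh3_cps1: float
    vmax_glul: float
    km_nh3_glul: float
    ki_gln: float
    v_nh3_abs: float
    v_nh3_ex: float
    v_urea_ex: float

    def __post_init__(self):
        for name in (
            "vmax_gls",
            "vmax_cps1",
            "vmax_glul",
            "v_nh3_abs",
            "v_nh3_ex",
            "v_urea_ex",
        ):
            if getattr(self, name) < 0:
                raise InvalidInput(f"{name} must be >= 0")
        for name in ("km_gln", "km_nh3_cps1", "km_nh3_glul", "ki_gln"):
            if not getattr(self, name) > 0:
                raise InvalidInput(f"{name} must be > 0")


@dataclass(frozen=True)
class Scenario:
    """A fully resolved (diet, liver condition) parameter set.

    ``initial_state`` is (ammonia, urea, glutamine) in mM; the conventional
    start is 0 uM ammonia, 5.5 mM urea, 0 mM glutamine.
    """

    diet: DietSpec
    condition: LiverCondition
    physiology: PhysiologyConstants
    kinetics: KineticParams
    initial_state: tuple[float, float, float] = (0.0, 5.5, 0.0)

    def with_kinetics(self, **changes: float) -> "Scenario":
        """Return a copy with some kinetic constants replaced."""
        return replace(self, kinetics=replace(self.kinetics, **changes))


def nitrogen_absorption_rate(diet: DietSpec) -> float:
    """Constant blood ammonia-nitrogen input rate, in mmol N/min.

    The daily protein mass is converted to nitrogen (16% by mass), reduced by
    fecal loss (12.7%), converted to moles (14 g N/mol) and spread uniformly
    over 1440 min. For the recommended 71 g/day this yields 0.492 mmol/min.
    """
    n_g_per_day = (
        diet.protein_g_per_day
        * diet.nitrogen_mass_fraction
        * (1.0 - diet.fecal_loss_fraction)
    )
    return n_g_per_day / NITROGEN_MOLAR_MASS_G * 1000.0 / MINUTES_PER_DAY


def scale_specific_activity(
    activity_nmol_min_mg: float,
    tissue_protein_fraction: float,
    liver_mass_g: float,
) -> float:
    """Scale a published specific activity to a whole-liver Vmax in mmol/min.

    Parameters
    ----------
    activity_nmol_min_mg :
        Specific activity in nmol/min per mg protein.
    tissue_protein_fraction :
        Protein mass fraction of the source tissue (0.20 for cultured
        hepatocytes, 0.25 for liver tissue).
    liver_mass_g :
        Whole liver mass to scale to (1561 g average male liver).

    Notes
    -----
    nmol/min/mg * 1e-6 mmol/nmol * 1e3 mg/g protein * protein fraction *
    liver mass; e.g. glutaminase at 91.4 nmol/min/mg with 20% protein in a
    1561 g liver gives 28.54 mmol/min.
    """
    if activity_nmol_min_mg < 0 or liver_mass_g < 0:
        raise InvalidInput("activity and liver mass must be >= 0")
    if not 0.0 < tissue_protein_fraction <= 1.0:
        raise InvalidInput("tissue_protein_fraction must lie in (0, 1]")
    return activity_nmol_min_mg * 1e-3 * tissue_protein_fraction * liver_mass_g


def blood_volume_for_mass(body_mass_kg: float) -> float:
    """Blood volume in L, linear in body mass (5.2 L at 70 kg)."""
    if body_mass_kg < 0:
        raise InvalidInput("body_mass_kg must be >= 0")
    return REFERENCE_BLOOD_VOLUME_L * body_mass_kg / REFERENCE_BODY_MASS_KG


def _interp_anchored(protein_g_per_day: float, anchors: np.ndarray) -> float:
    lo, hi = DIET_ANCHORS_G[0], DIET_ANCHORS_G[-1]
    if not lo <= protein_g_per_day <= hi:
        raise OutOfRange(
            f"protein intake {protein_g_per_day} g/day outside the anchored "
            f"range [{lo}, {hi}]; extrapolation is refused"
        )
    return float(np.interp(protein_g_per_day, DIET_ANCHORS_G, anchors))


def cps1_vmax(
    diet: DietSpec | float, condition: LiverCondition | str = LiverCondition.NORMAL
) -> float:
    """Diet- and condition-adjusted whole-liver CPS1 Vmax in mmol/min.

    The normal-liver values at the three canonical diets are the printed
    NAG-adjusted constants 8.05 / 8.47 / 8.78 mmol/min (71/100/122 g/day);
    intermediate intakes are interpolated linearly between adjacent anchors.
    Cirrhosis retains 70% and a CPS1 loss-of-function heterozygote 50% of the
    diet-adjusted value.
    """
    protein = diet.protein_g_per_day if isinstance(diet, DietSpec) else float(diet)
    base = _interp_anchored(protein, CPS1_VMAX_ANCHORS)
    condition = LiverCondition.parse(condition)
    if condition is LiverCondition.CIRRHOSIS:
        return base * CIRRHOSIS_CPS1_FACTOR
    if condition is LiverCondition.CPS1_HET:
        return base * CPS1_HET_FACTOR
    return base


def excretion_rates(diet: DietSpec | float) -> tuple[float, float]:
    """(ammonia, urea) urinary excretion rates in mmol/min for a diet.

    Anchored at the printed pairs (0.004, 0.244), (0.008, 0.343),
    (0.012, 0.417) for 71/100/122 g/day; linear between adjacent anchors.
    """
    protein = diet.protein_g_per_day if isinstance(diet, DietSpec) else float(diet)
    return (
        _interp_anchored(protein, NH3_EX_ANCHORS),
        _interp_anchored(protein, UREA_EX_ANCHORS),
    )


def build_scenario(
    protein_g_per_day: float,
    condition: LiverCondition | str = LiverCondition.NORMAL,
    physiology: PhysiologyConstants | None = None,
    initial_state: tuple[float, float, float] = (0.0, 5.5, 0.0),
) -> Scenario:
    """Resolve a full Scenario for one (diet, liver condition) pair.

    Glutaminase Vmax is condition-independent (28.54 mmol/min); GLUL Vmax is
    12.3 mmol/min except in cirrhosis (2.46, i.e. 20% of normal); CPS1 Vmax
    comes from :func:`cps1_vmax`; absorption from
    :func:`nitrogen_absorption_rate`; excretion from :func:`excretion_rates`.
    """
    condition = LiverCondition.parse(condition)
    diet = DietSpec(protein_g_per_day=float(protein_g_per_day))
    physiology = physiology or PhysiologyConstants()
    v_nh3_ex, v_urea_ex = excretion_rates(diet)
    vmax_glul = VMAX_GLUL * (
        CIRRHOSIS_GLUL_FACTOR if condition is LiverCondition.CIRRHOSIS else 1.0
    )
    kinetics = KineticParams(
        vmax_gls=VMAX_GLS,
        km_gln=KM_GLN,
        vmax_cps1=cps1_vmax(diet, condition),
        km_nh3_cps1=KM_NH3_CPS1,
        vmax_glul=vmax_glul,
        km_nh3_glul=KM_NH3_GLUL,
        ki_gln=KI_GLN,
        v_nh3_abs=nitrogen_absorption_rate(diet),
        v_nh3_ex=v_nh3_ex,
        v_urea_ex=v_urea_ex,
    )
    return Scenario(
        diet=diet,
        condition=condition,
        physiology=physiology,
        kinetics=kinetics,
        initial_state=tuple(float(x) for x in initial_state),
    )
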