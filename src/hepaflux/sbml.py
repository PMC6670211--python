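"""SBML Level 3 Version 2 export of the resolved model.

The document is generated directly as XML (lxml): one blood compartment, the
three species, all kinetic constants as parameters, seven reactions with
their kinetic laws in MathML, and two events that encode the periodic
zonation switching. The enzyme gates appear in the kinetic laws as the 0/1
parameters ``cps1_gls_active`` / ``glul_active``, toggled by events driven by
the phase clock ``time - cycle * floor(time / cycle)``.

Note the exported kinetic laws are the ideal rate laws; the tiny
negative-concentration guard used by the internal integrator (see
:data:`hepaflux.kinetics.EFFLUX_FLOOR_MM`) is a solver detail and is not
part of the exported model.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .params import Scenario
from .simulate import ZonationSchedule

__all__ = ["export_sbml", "read_sbml_summary"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"

_M = "{%s}" % MATHML_NS


def _ci(name: str):
    e = etree.Element(_M + "ci")
    e.text = f" {name} "
    return e


def _cn(value: float):
    e = etree.Element(_M + "cn")
    e.text = f" {value!r} "
    return e


def _time():
    e = etree.Element(_M + "csymbol")
    e.set("encoding", "text")
    e.set("definitionURL", TIME_CSYMBOL)
    e.text = " time "
    return e


def _apply(op: str, *args):
    e = etree.Element(_M + "apply")
    e.append(etree.Element(_M + op))
    for a in args:
        e.append(a)
    return e


def _math(expr):
    e = etree.Element(_M + "math")
    e.append(expr)
    return e


def _mm(gate: str, vmax: str, substrate: str, km_expr):
    """gate * vmax * S / (km_expr + S)"""
    return _apply(
        "divide",
        _apply("times", _ci(gate), _ci(vmax), _ci(substrate)),
        _apply("plus", km_expr, _ci(substrate)),
    )


def _phase_clock(cycle_param: str):
    """time - cycle * floor(time / cycle)"""
    return _apply(
        "minus",
        _time(),
        _apply(
            "times",
            _ci(cycle_param),
            _apply("floor", _apply("divide", _time(), _ci(cycle_param))),
        ),
    )


def _species(parent, sid: str, amount_mmol: float):
    etree.SubElement(
        parent,
        "species",
        id=sid,
        compartment="blood",
        initialAmount=repr(amount_mmol),
        hasOnlySubstanceUnits="false",
        boundaryCondition="false",
        constant="false",
    )


def _parameter(parent, pid: str, value: float, constant: bool = True):
    etree.SubElement(
        parent,
        "parameter",
        id=pid,
        value=repr(float(value)),
        constant="true" if constant else "false",
    )


def _reaction(parent, rid: str, reactants, products, law_math):
    r = etree.SubElement(parent, "reaction", id=rid, reversible="false")
    if reactants:
        lor = etree.SubElement(r, "listOfReactants")
        for sid in reactants:
            etree.SubElement(
                lor, "speciesReference", species=sid, stoichiometry="1", constant="true"
            )
    if products:
        lop = etree.SubElement(r, "listOfProducts")
        for sid in products:
            etree.SubElement(
                lop, "speciesReference", species=sid, stoichiometry="1", constant="true"
            )
    kl = etree.SubElement(r, "kineticLaw")
    kl.append(_math(law_math))


def _event(parent, eid: str, trigger_math, assignments):
    ev = etree.SubElement(parent, "event", id=eid, useValuesFromTriggerTime="true")
    tr = etree.SubElement(ev, "trigger", initialValue="true", persistent="true")
    tr.append(_math(trigger_math))
    loea = etree.SubElement(ev, "listOfEventAssignments")
    for target, value in assignments:
        ea = etree.SubElement(loea, "eventAssignment", variable=target)
        ea.append(_math(_cn(value)))


def export_sbml(
    scenario: Scenario,
    schedule: ZonationSchedule | None = None,
    path: str | Path | None = None,
) -> etree._ElementTree:
    """Serialize a resolved scenario as an SBML L3V2 document.

    Returns the element tree; writes it to ``path`` when given. Initial
    species amounts are concentration (mM) times the blood volume (L), i.e.
    mmol; kinetic laws evaluate species as concentrations and yield mmol/min.
    """
    schedule = schedule or ZonationSchedule()
    k = scenario.kinetics
    v_blood = scenario.physiology.blood_volume_l

    root = etree.Element("sbml", nsmap={None: SBML_NS}, level="3", version="2")
    model = etree.SubElement(root, "model", id="blood_ammonia_zonation",
                             timeUnits="minute", extentUnits="millimole")

    loc = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(
        loc,
        "compartment",
        id="blood",
        spatialDimensions="3",
        size=repr(v_blood),
        constant="true",
    )

    los = etree.SubElement(model, "listOfSpecies")
    nh3_0, urea_0, gln_0 = scenario.initial_state
    _species(los, "NH3", nh3_0 * v_blood)
    _species(los, "Urea", urea_0 * v_blood)
    _species(los, "Gln", gln_0 * v_blood)

    lop = etree.SubElement(model, "listOfParameters")
    for pid, value in (
        ("vmax_gls", k.vmax_gls),
        ("km_gln", k.km_gln),
        ("vmax_cps1", k.vmax_cps1),
        ("km_nh3_cps1", k.km_nh3_cps1),
        ("vmax_glul", k.vmax_glul),
        ("km_nh3_glul", k.km_nh3_glul),
        ("ki_gln", k.ki_gln),
        ("v_nh3_abs", k.v_nh3_abs),
        ("v_nh3_ex", k.v_nh3_ex),
        ("v_urea_ex", k.v_urea_ex),
        ("phase1_s", schedule.phase1_s),
        ("cycle_s", schedule.cycle_s),
    ):
        _parameter(lop, pid, value)
    _parameter(lop, "cps1_gls_active", 1.0, constant=False)
    _parameter(lop, "glul_active", 0.0, constant=False)

    lor = etree.SubElement(model, "listOfReactions")
    _reaction(lor, "nh3_absorption", [], ["NH3"], _ci("v_nh3_abs"))
    _reaction(
        lor, "gls", ["Gln"], ["NH3"],
        _mm("cps1_gls_active", "vmax_gls", "Gln", _ci("km_gln")),
    )
    _reaction(
        lor, "cps1", ["NH3"], ["Urea"],
        _mm("cps1_gls_active", "vmax_cps1", "NH3", _ci("km_nh3_cps1")),
    )
    # duplicate CPS1 flux; product discarded so one urea costs two nitrogens
    _reaction(
        lor, "urea_for_balance", ["NH3"], [],
        _mm("cps1_gls_active", "vmax_cps1", "NH3", _ci("km_nh3_cps1")),
    )
    _reaction(
        lor, "glul", ["NH3"], ["Gln"],
        _mm(
            "glul_active", "vmax_glul", "NH3",
            _apply(
                "times",
                _ci("km_nh3_glul"),
                _apply("plus", _cn(1.0), _apply("divide", _ci("Gln"), _ci("ki_gln"))),
            ),
        ),
    )
    _reaction(lor, "nh3_excretion", ["NH3"], [], _ci("v_nh3_ex"))
    _reaction(lor, "urea_excretion", ["Urea"], [], _ci("v_urea_ex"))

    loe = etree.SubElement(model, "listOfEvents")
    _event(
        loe,
        "zones_1_2_on",
        _apply("lt", _phase_clock("cycle_s"), _ci("phase1_s")),
        [("cps1_gls_active", 1.0), ("glul_active", 0.0)],
    )
    _event(
        loe,
        "zone_3_on",
        _apply("geq", _phase_clock("cycle_s"), _ci("phase1_s")),
        [("cps1_gls_active", 0.0), ("glul_active", 1.0)],
    )

    tree = etree.ElementTree(root)
    if path is not None:
        tree.write(
            str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    return tree


def read_sbml_summary(path: str | Path) -> dict:
    """Re-parse an exported document into a plain summary dict (round-trip
    checks and provenance)."""
    tree = etree.parse(str(path))
    ns = {"s": SBML_NS}
    comp = tree.find(".//s:compartment", ns)
    species = {
        e.get("id"): float(e.get("initialAmount"))
        for e in tree.findall(".//s:species", ns)
    }
    parameters = {
        e.get("id"): float(e.get("value"))
        for e in tree.findall(".//s:listOfParameters/s:parameter", ns)
    }
    reactions = [e.get("id") for e in tree.findall(".//s:reaction", ns)]
    events = [e.get("id") for e in tree.findall(".//s:event", ns)]
    return {
        "compartment_size": float(comp.get("size")),
        "species_initial_amounts": species,
        "parameters": parameters,
        "reactions": reactions,
        "events": events,
    }
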