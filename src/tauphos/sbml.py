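"""SBML Level 3 import/export of the tau model.

Writes a self-contained SBML L3 core document: three species per residue
(``<site>_closed``, ``<site>_open``, ``p<site>``), global parameters for
every kinetic constant, and one reaction per (site, enzyme) flux with its
competitive Michaelis–Menten rate law spelled out in MathML — the
document is meant to be human-diffable against the published model file.
Concentrations are declared in μM and time in minutes via unit
definitions.

The reader reconstructs the model from the species list (site order) and
the parameter table; the sequential-mechanism prerequisites and the
per-condition parameter variants ride in a small annotation block under
the ``tauphos`` namespace, since SBML core has no native notion of a
condition switch.  Parsing is strict: malformed documents fail with the
offending element named, never silently.
"""

from __future__ import annotations

import re

from lxml import etree

from .model import EnzymeSpec, PhosphoModel, SiteSpec, initialize

__all__ = ["export_sbml", "import_sbml", "validate_structure"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TAUPHOS_NS = "https://tauphos.invalid/sbml-annotations"

NSMAP = {None: SBML_NS}
_Q = lambda tag: f"{{{SBML_NS}}}{tag}"
_M = lambda tag: f"{{{MATHML_NS}}}{tag}"
_T = lambda tag: f"{{{TAUPHOS_NS}}}{tag}"

_COMPARTMENT = "cytosol"


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


# ---------------------------------------------------------------------------
# MathML helpers
# ---------------------------------------------------------------------------

def _ci(parent, name: str):
    el = etree.SubElement(parent, _M("ci"))
    el.text = f" {name} "
    return el


def _apply(parent, op: str):
    ap = etree.SubElement(parent, _M("apply"))
    etree.SubElement(ap, _M(op))
    return ap


def _rate_law_math(numerator_cis: list[str], km_ci: str,
                   denom_cis: list[str]):
    """MathML for  prod(numerator) / (km + sum(denominator))."""
    math = etree.Element(_M("math"), nsmap={None: MATHML_NS})
    div = _apply(math, "divide")
    if len(numerator_cis) == 1:
        _ci(div, numerator_cis[0])
    else:
        times = _apply(div, "times")
        for name in numerator_cis:
            _ci(times, name)
    plus = _apply(div, "plus")
    _ci(plus, km_ci)
    for name in denom_cis:
        _ci(plus, name)
    return math


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_sbml(model: PhosphoModel, path=None) -> bytes:
    """Serialise a model (under its current condition) to SBML L3 bytes."""
    root = etree.Element(_Q("sbml"), nsmap=NSMAP, level="3", version="2")
    mdl = etree.SubElement(root, _Q("model"), id="tau_multisite_phosphorylation",
                           timeUnits="minute", substanceUnits="micromole",
                           extentUnits="micromole")

    # -- annotation: condition switches and prerequisites ------------------
    ann = etree.SubElement(mdl, _Q("annotation"))
    tp = etree.SubElement(ann, _T("tauphos"), nsmap={"tauphos": TAUPHOS_NS})
    etree.SubElement(tp, _T("condition"),
                     kinase=model.condition_kinase, pka=str(model.pka_flag))
    if model.pp2a_gsk3b_coupling is not None:
        etree.SubElement(tp, _T("coupling"),
                         value=repr(float(model.pp2a_gsk3b_coupling)))
    for s in model.sites:
        se = etree.SubElement(tp, _T("site"), name=s.name)
        for kin, pre in sorted(s.prerequisite.items()):
            etree.SubElement(se, _T("prerequisite"), kinase=kin, site=pre)
        for (kin, pka), a in sorted(s.alpha.items()):
            etree.SubElement(se, _T("alpha"), kinase=kin, pka=str(pka),
                             value=repr(float(a)))
        for (kin, pka), k in sorted(s.kcat.items()):
            etree.SubElement(se, _T("kcat"), kinase=kin, pka=str(pka),
                             value=repr(float(k)))

    # -- units -------------------------------------------------------------
    uds = etree.SubElement(mdl, _Q("listOfUnitDefinitions"))
    for uid, kind, exp, scale in (("minute", "second", 1, 0),
                                  ("micromole", "mole", 1, -6),
                                  ("perMin", "second", -1, 0)):
        ud = etree.SubElement(uds, _Q("unitDefinition"), id=uid)
        lu = etree.SubElement(ud, _Q("listOfUnits"))
        mult = "60" if kind == "second" else "1"
        etree.SubElement(lu, _Q("unit"), kind=kind, exponent=str(exp),
                         scale=str(scale), multiplier=mult)

    comps = etree.SubElement(mdl, _Q("listOfCompartments"))
    etree.SubElement(comps, _Q("compartment"), id=_COMPARTMENT, size="1",
                     constant="true", spatialDimensions="3")

    # -- species: initial state under the current condition ----------------
    state0 = initialize(model)
    sps = etree.SubElement(mdl, _Q("listOfSpecies"))
    for i, s in enumerate(model.sites):
        for sid, amount in ((f"{_sanitize(s.name)}_closed", state0.r_closed[i]),
                            (f"{_sanitize(s.name)}_open", state0.r_open[i]),
                            (f"p{_sanitize(s.name)}", state0.p[i])):
            etree.SubElement(sps, _Q("species"), id=sid,
                             compartment=_COMPARTMENT,
                             initialConcentration=repr(float(amount)),
                             hasOnlySubstanceUnits="false",
                             boundaryCondition="false", constant="false")

    # -- parameters ---------------------------------------------------------
    pars = etree.SubElement(mdl, _Q("listOfParameters"))

    def par(pid: str, value: float, units: str = "perMin"):
        etree.SubElement(pars, _Q("parameter"), id=pid, value=repr(float(value)),
                         constant="true", units=units)

    par("tau_total", model.tau_total, "micromole")
    for e in model.enzymes.values():
        par(f"conc_{_sanitize(e.name)}", e.concentration, "micromole")
        par(f"km_{_sanitize(e.name)}", e.km, "micromole")
        etree.SubElement(pars, _Q("parameter"),
                         id=f"role_{_sanitize(e.name)}",
                         value="1" if e.role == "kinase" else "0",
                         constant="true")
    pka = model.pka_flag
    kin = model.condition_kinase
    for s in model.sites:
        sid = _sanitize(s.name)
        par(f"k_{sid}", s.get_kcat(kin, pka))
        par(f"alpha_{sid}", s.get_alpha(kin, pka), "dimensionless")
        par(f"kpp2a_{sid}", s.kcat_pp2a)
        par(f"kopen_{sid}", s.k_open)
        par(f"kclose_{sid}", s.k_close)

    # -- reactions -----------------------------------------------------------
    rxns = etree.SubElement(mdl, _Q("listOfReactions"))
    kinase_names = [e.name for e in model.enzymes.values() if e.role == "kinase"]
    for s in model.sites:
        sid = _sanitize(s.name)
        # conformational exchange (usually frozen: rates 0)
        rx = etree.SubElement(rxns, _Q("reaction"), id=f"open_{sid}",
                              reversible="true")
        lr = etree.SubElement(rx, _Q("listOfReactants"))
        etree.SubElement(lr, _Q("speciesReference"), species=f"{sid}_closed",
                         stoichiometry="1", constant="true")
        lp = etree.SubElement(rx, _Q("listOfProducts"))
        etree.SubElement(lp, _Q("speciesReference"), species=f"{sid}_open",
                         stoichiometry="1", constant="true")

        for kname in kinase_names:
            if s.get_kcat(kname, pka) <= 0:
                continue
            rx = etree.SubElement(rxns, _Q("reaction"),
                                  id=f"phos_{sid}_{_sanitize(kname)}",
                                  reversible="false")
            lr = etree.SubElement(rx, _Q("listOfReactants"))
            etree.SubElement(lr, _Q("speciesReference"),
                             species=f"{sid}_open", stoichiometry="1",
                             constant="true")
            lp = etree.SubElement(rx, _Q("listOfProducts"))
            etree.SubElement(lp, _Q("speciesReference"), species=f"p{sid}",
                             stoichiometry="1", constant="true")
            kl = etree.SubElement(rx, _Q("kineticLaw"))
            numer = [f"k_{sid}", f"conc_{_sanitize(kname)}", f"{sid}_open"]
            pre = s.prerequisite.get(kname)
            if pre is not None:
                numer += [f"p{_sanitize(pre)}"]
            denom = []
            for other in model.sites:
                if other.get_kcat(kname, pka) > 0:
                    denom.append(f"{_sanitize(other.name)}_open")
            kl.append(_rate_law_math(numer, f"km_{_sanitize(kname)}", denom))

        if s.kcat_pp2a > 0 and any(e.role == "phosphatase"
                                   for e in model.enzymes.values()):
            pp2a = next(e for e in model.enzymes.values()
                        if e.role == "phosphatase")
            rx = etree.SubElement(rxns, _Q("reaction"), id=f"dephos_{sid}",
                                  reversible="false")
            lr = etree.SubElement(rx, _Q("listOfReactants"))
            etree.SubElement(lr, _Q("speciesReference"), species=f"p{sid}",
                             stoichiometry="1", constant="true")
            lp = etree.SubElement(rx, _Q("listOfProducts"))
            etree.SubElement(lp, _Q("speciesReference"),
                             species=f"{sid}_open", stoichiometry="1",
                             constant="true")
            kl = etree.SubElement(rx, _Q("kineticLaw"))
            denom = [f"p{_sanitize(o.name)}" for o in model.sites
                     if o.kcat_pp2a > 0]
            kl.append(_rate_law_math(
                [f"kpp2a_{sid}", f"conc_{_sanitize(pp2a.name)}", f"p{sid}"],
                f"km_{_sanitize(pp2a.name)}", denom))

    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

class SBMLParseError(ValueError):
    """Malformed or unsupported SBML document."""


def _require(el, tag: str):
    found = el.find(_Q(tag))
    if found is None:
        raise SBMLParseError(f"missing <{tag}> under <{etree.QName(el).localname}>")
    return found


def validate_structure(doc: etree._ElementTree | etree._Element) -> None:
    """Structural sanity checks on the SBML L3 core skeleton."""
    root = doc.getroot() if hasattr(doc, "getroot") else doc
    if etree.QName(root).localname != "sbml" or etree.QName(root).namespace != SBML_NS:
        raise SBMLParseError("document root is not SBML Level 3 core")
    if root.get("level") != "3":
        raise SBMLParseError("only SBML Level 3 is supported")
    mdl = _require(root, "model")
    _require(mdl, "listOfSpecies")
    _require(mdl, "listOfParameters")
    for sp in mdl.find(_Q("listOfSpecies")):
        if sp.get("id") is None or sp.get("initialConcentration") is None:
            raise SBMLParseError(
                f"species record missing id/initialConcentration: "
                f"{etree.tostring(sp, encoding='unicode').strip()}")


def import_sbml(source) -> PhosphoModel:
    """Rebuild a :class:`PhosphoModel` from an exported document.

    ``source`` may be a path or bytes.  The full per-condition parameter
    tables and prerequisites are recovered from the tauphos annotation.
    """
    if isinstance(source, (bytes, bytearray)):
        root = etree.fromstring(bytes(source))
    else:
        root = etree.parse(str(source)).getroot()
    validate_structure(root)
    mdl = root.find(_Q("model"))

    params: dict[str, float] = {}
    roles: dict[str, str] = {}
    for p in mdl.find(_Q("listOfParameters")):
        pid = p.get("id")
        if pid.startswith("role_"):
            roles[pid[5:]] = "kinase" if p.get("value") == "1" else "phosphatase"
        else:
            params[pid] = float(p.get("value"))

    # site order from the *_open species sequence
    site_order: list[str] = []
    for sp in mdl.find(_Q("listOfSpecies")):
        sid = sp.get("id")
        if sid.endswith("_open"):
            site_order.append(sid[:-5])

    ann = mdl.find(_Q("annotation"))
    if ann is None or ann.find(_T("tauphos")) is None:
        raise SBMLParseError("missing tauphos annotation block")
    tp = ann.find(_T("tauphos"))
    cond = tp.find(_T("condition"))
    coupling_el = tp.find(_T("coupling"))

    site_specs: dict[str, SiteSpec] = {
        name: SiteSpec(name=name,
                       kcat_pp2a=params.get(f"kpp2a_{name}", 0.0),
                       k_open=params.get(f"kopen_{name}", 0.0),
                       k_close=params.get(f"kclose_{name}", 0.0))
        for name in site_order}
    for se in tp.findall(_T("site")):
        name = se.get("name")
        if name not in site_specs:
            raise SBMLParseError(f"annotation references unknown site {name!r}")
        spec = site_specs[name]
        for el in se.findall(_T("prerequisite")):
            spec.prerequisite[el.get("kinase")] = el.get("site")
        for el in se.findall(_T("alpha")):
            spec.alpha[(el.get("kinase"), int(el.get("pka")))] = float(el.get("value"))
        for el in se.findall(_T("kcat")):
            spec.kcat[(el.get("kinase"), int(el.get("pka")))] = float(el.get("value"))

    enzymes = {}
    for ename, role in roles.items():
        enzymes[ename] = EnzymeSpec(name=ename,
                                    concentration=params[f"conc_{ename}"],
                                    km=params[f"km_{ename}"], role=role)

    return PhosphoModel(
        sites=[site_specs[n] for n in site_order], enzymes=enzymes,
        tau_total=params["tau_total"],
        pka_flag=int(cond.get("pka")), condition_kinase=cond.get("kinase"),
        pp2a_gsk3b_coupling=(float(coupling_el.get("value"))
                             if coupling_el is not None else None))
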