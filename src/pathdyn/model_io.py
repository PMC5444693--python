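"""Reaction-network model: domain types, SBML I/O, drug catalogue.

The in-memory model is a :class:`ReactionNetwork` of species, reactions
(with sympy kinetic laws) and parameters, using one internal unit system:
concentrations in nM, time in minutes, velocities in nM/min.

SBML support covers the Level 2 Version 4 and Level 3 Version 1 *core*
subset: compartments (constant volume), species, global and reaction-local
parameters, and reactions with content-MathML kinetic laws over
{+, -, *, /, power}.  Events, rules, function definitions, initial
assignments, constraints and piecewise/delay math are rejected with
:class:`~pathdyn.errors.UnsupportedFeatureError` — intervention regimes are
supplied externally (see :mod:`pathdyn.interventions`), not encoded in the
model file.
"""

from __future__ import annotations

import io
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import sympy

from . import _mathml
from ._mathml import TIME, parse_mathml, to_mathml
from .errors import (
    IntegrityError,
    SBMLFormatError,
    UnknownTargetError,
    UnsupportedFeatureError,
    ValidationError,
)

SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
SBML_L2V4_NS = "http://www.sbml.org/sbml/level2/version4"

__all__ = [
    "Species",
    "Parameter",
    "KineticExpression",
    "Reaction",
    "Compartment",
    "ReactionNetwork",
    "DrugCatalogue",
    "DrugEntry",
    "load_sbml",
    "write_sbml",
    "load_drug_catalogue",
]


@dataclass
class Species:
    """A molecular species (protein, complex, drug).

    ``initial_concentration`` is in nM.  Boundary species have their
    concentration held fixed by the simulator (zero derivative).
    """

    id: str
    name: str = ""
    initial_concentration: float = 0.0
    is_boundary: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("species id must be non-empty")
        if self.initial_concentration < 0:
            raise ValidationError(
                f"species '{self.id}': initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass
class Parameter:
    """A kinetic constant; ``scope`` is 'global' or the owning reaction id."""

    id: str
    value: float
    scope: str = "global"


@dataclass
class Compartment:
    id: str
    size: float = 1.0


def _parse_rate_string(text: str) -> sympy.Expr:
    """Parse an arithmetic rate-law string; every identifier is a plain symbol.

    An empty global namespace keeps ids like ``I``, ``E`` or ``pi`` from
    colliding with sympy built-ins (drug species are routinely called I).
    """
    from sympy.parsing.sympy_parser import parse_expr, standard_transformations

    return parse_expr(
        text,
        global_dict={"Symbol": sympy.Symbol, "Integer": sympy.Integer,
                     "Float": sympy.Float, "Rational": sympy.Rational},
        transformations=standard_transformations,
    )


class KineticExpression:
    """A rate law: a sympy expression over species ids, parameter ids and time.

    Wraps the expression tree so the rest of the package never manipulates
    sympy objects directly; equality is structural (after sympy's automatic
    canonicalization).
    """

    def __init__(self, expr):
        if isinstance(expr, str):
            expr = _parse_rate_string(expr)
        self.expr = sympy.sympify(expr)

    @property
    def free_symbols(self) -> set[str]:
        return {s.name for s in self.expr.free_symbols if s is not TIME}

    @property
    def uses_time(self) -> bool:
        return TIME in self.expr.free_symbols

    def substituted(self, mapping: dict[str, float | str]) -> "KineticExpression":
        subs = {
            sympy.Symbol(k): (sympy.Symbol(v) if isinstance(v, str) else sympy.Float(v))
            for k, v in mapping.items()
        }
        return KineticExpression(self.expr.subs(subs, simultaneous=True))

    def __eq__(self, other):
        if not isinstance(other, KineticExpression):
            return NotImplemented
        if self.expr == other.expr:
            return True
        diff = sympy.simplify(self.expr - other.expr)
        return diff == 0

    def __repr__(self):
        return f"KineticExpression({self.expr})"


@dataclass
class Reaction:
    """A reaction with stoichiometric reactants/products and a kinetic law.

    ``reactants`` and ``products`` are lists of ``(species_id, stoichiometry)``
    with stoichiometry > 0; ``modifiers`` are species that appear in the rate
    law without being consumed or produced.
    """

    id: str
    reactants: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    kinetic_law: KineticExpression = field(default_factory=lambda: KineticExpression(0))
    reversible: bool = False

    def __post_init__(self):
        for sid, stoich in list(self.reactants) + list(self.products):
            if stoich <= 0:
                raise ValidationError(
                    f"reaction '{self.id}': stoichiometry for '{sid}' must be > 0"
                )


@dataclass
class ReactionNetwork:
    """Species + reactions + parameters, with referential integrity."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    id: str = "model"

    # -- lookups -----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def parameter_ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise UnknownTargetError(f"unknown species '{sid}'")

    def get_parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise UnknownTargetError(f"unknown parameter '{pid}'")

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise UnknownTargetError(f"unknown reaction '{rid}'")

    # -- validation --------------------------------------------------------
    def validate(self) -> "ReactionNetwork":
        """Check all invariants; raise on violation, return self otherwise."""
        if not self.species:
            raise IntegrityError("a network must declare at least one species")
        sids = self.species_ids
        if len(set(sids)) != len(sids):
            dup = sorted({s for s in sids if sids.count(s) > 1})
            raise IntegrityError(f"duplicate species ids: {dup}")
        pids = self.parameter_ids
        if len(set(pids)) != len(pids):
            dup = sorted({p for p in pids if pids.count(p) > 1})
            raise IntegrityError(f"duplicate parameter ids: {dup}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise IntegrityError(f"duplicate reaction ids: {dup}")
        known = set(sids)
        symbols_ok = known | set(pids)
        for rxn in self.reactions:
            for sid, _ in list(rxn.reactants) + list(rxn.products):
                if sid not in known:
                    raise IntegrityError(
                        f"reaction '{rxn.id}' references undeclared species '{sid}'"
                    )
            for sid in rxn.modifiers:
                if sid not in known:
                    raise IntegrityError(
                        f"reaction '{rxn.id}' references undeclared modifier '{sid}'"
                    )
            unresolved = rxn.kinetic_law.free_symbols - symbols_ok
            if unresolved:
                raise IntegrityError(
                    f"reaction '{rxn.id}': kinetic law has unresolved "
                    f"symbol(s) {sorted(unresolved)}"
                )
        return self

    def structurally_equal(self, other: "ReactionNetwork") -> bool:
        """Field-by-field equality up to float representation of values."""
        import math

        if self.species_ids != other.species_ids:
            return False
        for a, b in zip(self.species, other.species):
            if a.is_boundary != b.is_boundary or not math.isclose(
                a.initial_concentration, b.initial_concentration, rel_tol=1e-12, abs_tol=1e-15
            ):
                return False
        if sorted(self.parameter_ids) != sorted(other.parameter_ids):
            return False
        mine = {p.id: p for p in self.parameters}
        theirs = {p.id: p for p in other.parameters}
        for pid in mine:
            if not math.isclose(mine[pid].value, theirs[pid].value, rel_tol=1e-12, abs_tol=1e-15):
                return False
        if self.reaction_ids != other.reaction_ids:
            return False
        for ra, rb in zip(self.reactions, other.reactions):
            if (
                ra.reactants != rb.reactants
                or ra.products != rb.products
                or sorted(ra.modifiers) != sorted(rb.modifiers)
                or ra.reversible != rb.reversible
                or ra.kinetic_law != rb.kinetic_law
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# SBML reading
# ---------------------------------------------------------------------------

_REJECTED_LISTS = (
    "listOfEvents",
    "listOfRules",
    "listOfFunctionDefinitions",
    "listOfInitialAssignments",
    "listOfConstraints",
)


def load_sbml(path: str | os.PathLike) -> ReactionNetwork:
    """Parse an SBML L2V4/L3V1 core file into a :class:`ReactionNetwork`.

    Initial amounts are converted to concentrations (divided by compartment
    volume); reaction-local parameters are namespaced as
    ``<reaction_id>__<parameter_id>`` and hoisted to the global list.
    """
    net = _load_sbml_raw(path)
    for rxn in net.reactions:
        for lp in getattr(rxn, "_local_parameters", []):
            net.parameters.append(lp)
        if hasattr(rxn, "_local_parameters"):
            del rxn._local_parameters
    return net.validate()


def _load_sbml_raw(path: str | os.PathLike) -> ReactionNetwork:
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise SBMLFormatError(f"not well-formed XML: {path}: {e}") from e
    root = tree.getroot()
    if not root.tag.startswith("{"):
        raise SBMLFormatError(f"{path}: missing SBML namespace on root element")
    ns = root.tag[1:].split("}")[0]
    if ns not in (SBML_L3V1_NS, SBML_L2V4_NS):
        raise UnsupportedFeatureError(
            f"unsupported SBML namespace '{ns}' (supported: L2V4, L3V1 core)"
        )
    model = root.find(f"{{{ns}}}model")
    if model is None:
        raise SBMLFormatError(f"{path}: no <model> element")

    for bad in _REJECTED_LISTS:
        if model.find(f"{{{ns}}}{bad}") is not None:
            raise UnsupportedFeatureError(f"SBML construct '{bad}' is not supported")

    net = ReactionNetwork(id=model.get("id", "model"))

    comp_list = model.find(f"{{{ns}}}listOfCompartments")
    sizes: dict[str, float] = {}
    if comp_list is not None:
        for c in comp_list:
            size = c.get("size", c.get("volume", "1"))
            comp = Compartment(id=c.get("id", "default"), size=float(size))
            net.compartments.append(comp)
            sizes[comp.id] = comp.size
    if not net.compartments:
        net.compartments.append(Compartment(id="default", size=1.0))
        sizes["default"] = 1.0

    sp_list = model.find(f"{{{ns}}}listOfSpecies")
    if sp_list is not None:
        for s in sp_list:
            sid = s.get("id")
            if sid is None:
                raise SBMLFormatError("species without id")
            comp_id = s.get("compartment", net.compartments[0].id)
            vol = sizes.get(comp_id, 1.0)
            if s.get("initialConcentration") is not None:
                conc = float(s.get("initialConcentration"))
            elif s.get("initialAmount") is not None:
                conc = float(s.get("initialAmount")) / vol
            else:
                conc = 0.0
            net.species.append(
                Species(
                    id=sid,
                    name=s.get("name", sid),
                    initial_concentration=conc,
                    is_boundary=s.get("boundaryCondition", "false") == "true",
                )
            )

    par_list = model.find(f"{{{ns}}}listOfParameters")
    if par_list is not None:
        for p in par_list:
            net.parameters.append(
                Parameter(id=p.get("id"), value=float(p.get("value", "0")), scope="global")
            )

    rxn_list = model.find(f"{{{ns}}}listOfReactions")
    if rxn_list is not None:
        for r in rxn_list:
            net.reactions.append(_parse_reaction(r, ns, sizes))

    return net  # validated by load_sbml after local-parameter hoisting


def _parse_reaction(r: ET.Element, ns: str, sizes: dict[str, float]) -> Reaction:
    rid = r.get("id")
    if rid is None:
        raise SBMLFormatError("reaction without id")

    def refs(list_name: str) -> list[tuple[str, float]]:
        out = []
        lst = r.find(f"{{{ns}}}{list_name}")
        if lst is not None:
            for ref in lst:
                out.append((ref.get("species"), float(ref.get("stoichiometry", "1"))))
        return out

    modifiers = []
    mods = r.find(f"{{{ns}}}listOfModifiers")
    if mods is not None:
        modifiers = [m.get("species") for m in mods]

    law = KineticExpression(0)
    kl = r.find(f"{{{ns}}}kineticLaw")
    local_params: list[Parameter] = []
    if kl is not None:
        math_el = kl.find(f"{{{_mathml.MATHML_NS}}}math")
        if math_el is None:
            raise SBMLFormatError(f"reaction '{rid}': kineticLaw without <math>")
        expr = parse_mathml(math_el)
        # local parameters (L3: listOfLocalParameters, L2: listOfParameters)
        rename: dict[str, str] = {}
        for lpl_name in ("listOfLocalParameters", "listOfParameters"):
            lpl = kl.find(f"{{{ns}}}{lpl_name}")
            if lpl is not None:
                for lp in lpl:
                    pid = lp.get("id")
                    namespaced = f"{rid}__{pid}"
                    rename[pid] = namespaced
                    local_params.append(
                        Parameter(id=namespaced, value=float(lp.get("value", "0")), scope=rid)
                    )
        # substitute renamed locals and constant compartment sizes
        subs = {k: v for k, v in rename.items()}
        subs.update({cid: float(sz) for cid, sz in sizes.items()})
        if subs:
            law = KineticExpression(expr).substituted(subs)
        else:
            law = KineticExpression(expr)

    rxn = Reaction(
        id=rid,
        reactants=refs("listOfReactants"),
        products=refs("listOfProducts"),
        modifiers=modifiers,
        kinetic_law=law,
        reversible=r.get("reversible", "false") == "true",
    )
    rxn._local_parameters = local_params  # hoisted into the global list by load_sbml
    return rxn


# ---------------------------------------------------------------------------
# SBML writing
# ---------------------------------------------------------------------------


def write_sbml(network: ReactionNetwork, path: str | os.PathLike) -> str:
    """Write a network as SBML Level 3 Version 1; round-trips via load_sbml."""
    network.validate()
    ET.register_namespace("", SBML_L3V1_NS)
    ET.register_namespace("math", _mathml.MATHML_NS)
    ns = f"{{{SBML_L3V1_NS}}}"
    root = ET.Element(ns + "sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(root, ns + "model", {"id": network.id})

    comps = ET.SubElement(model, ns + "listOfCompartments")
    for c in network.compartments or [Compartment("default", 1.0)]:
        ET.SubElement(
            comps,
            ns + "compartment",
            {"id": c.id, "size": repr(float(c.size)), "constant": "true"},
        )
    comp_id = (network.compartments or [Compartment("default")])[0].id

    sps = ET.SubElement(model, ns + "listOfSpecies")
    for s in network.species:
        ET.SubElement(
            sps,
            ns + "species",
            {
                "id": s.id,
                "name": s.name or s.id,
                "compartment": comp_id,
                "initialConcentration": repr(float(s.initial_concentration)),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "true" if s.is_boundary else "false",
                "constant": "false",
            },
        )

    pars = ET.SubElement(model, ns + "listOfParameters")
    for p in network.parameters:
        ET.SubElement(
            pars,
            ns + "parameter",
            {"id": p.id, "value": repr(float(p.value)), "constant": "true"},
        )

    rxns = ET.SubElement(model, ns + "listOfReactions")
    for r in network.reactions:
        rel = ET.SubElement(
            rxns,
            ns + "reaction",
            {"id": r.id, "reversible": "true" if r.reversible else "false", "fast": "false"},
        )
        if r.reactants:
            lst = ET.SubElement(rel, ns + "listOfReactants")
            for sid, st in r.reactants:
                ET.SubElement(
                    lst,
                    ns + "speciesReference",
                    {"species": sid, "stoichiometry": repr(float(st)), "constant": "true"},
                )
        if r.products:
            lst = ET.SubElement(rel, ns + "listOfProducts")
            for sid, st in r.products:
                ET.SubElement(
                    lst,
                    ns + "speciesReference",
                    {"species": sid, "stoichiometry": repr(float(st)), "constant": "true"},
                )
        if r.modifiers:
            lst = ET.SubElement(rel, ns + "listOfModifiers")
            for sid in r.modifiers:
                ET.SubElement(lst, ns + "modifierSpeciesReference", {"species": sid})
        kl = ET.SubElement(rel, ns + "kineticLaw")
        kl.append(to_mathml(r.kinetic_law.expr))

    ET.indent(root)
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="UTF-8", xml_declaration=True)
    data = buf.getvalue() + b"\n"
    with open(path, "wb") as fh:
        fh.write(data)
    return os.fspath(path)


# ---------------------------------------------------------------------------
# Drug catalogue
# ---------------------------------------------------------------------------


@dataclass
class DrugEntry:
    name: str
    default_dosage: float  # nM
    target_species: str


@dataclass
class DrugCatalogue:
    """Named drugs with default dosages (nM), bound to network species."""

    entries: list[DrugEntry] = field(default_factory=list)

    def get(self, name: str) -> DrugEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise UnknownTargetError(f"unknown drug '{name}'")

    def __len__(self):
        return len(self.entries)

    def __contains__(self, name: str):
        return any(e.name == name for e in self.entries)


def load_drug_catalogue(path: str | os.PathLike, network: ReactionNetwork) -> DrugCatalogue:
    """Load a delimited drug catalogue and bind it to ``network``.

    Format: comma- or tab-separated rows ``name, dosage_nM, target_species``;
    a header row is detected (non-numeric second field) and skipped.
    """
    cat = DrugCatalogue()
    known = set(network.species_ids)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    for i, line in enumerate(lines):
        sep = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != 3:
            raise ValidationError(
                f"catalogue line {i + 1}: expected 3 fields (name, dosage_nM, "
                f"target_species), got {len(fields)}"
            )
        name, dose_s, target = fields
        try:
            dosage = float(dose_s)
        except ValueError:
            if i == 0:  # header row
                continue
            raise ValidationError(f"catalogue line {i + 1}: dosage '{dose_s}' is not a number")
        if dosage < 0:
            raise ValidationError(f"drug '{name}': dosage must be >= 0, got {dosage}")
        if target not in known:
            raise IntegrityError(
                f"drug '{name}' targets species '{target}' absent from the network"
            )
        if name in cat:
            raise ValidationError(f"duplicate drug name '{name}'")
        cat.entries.append(DrugEntry(name=name, default_dosage=dosage, target_species=target))
    return cat
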