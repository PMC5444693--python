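"""Small mass-action network motifs with known analytic structure.

These generated networks make the whole toolchain testable without any
external model file, while echoing the biology of receptor-driven kinase
signaling: ligand-induced receptor dimerization inhibited by an antibody
drug, and two kinase cascades cross-coupled through a shared phosphatase
(the mechanism by which inhibiting one cascade frees phosphatase for the
other).  Kinetics are mass action with rate constants of order 0.01-1 in
nM/min units; they are deliberately generic stand-ins, not a published
parameterization of any real pathway model.

Motifs
------
``decay``
    A -> B at rate k*A; closed form A(t) = A0*exp(-k*t).
``reversible_pair``
    A <-> B; A+B conserved.
``linear_cascade(n)``
    n tiers of inactive/active pairs; tier i activation is catalyzed by the
    active species of tier i-1 (tier 1 self-activates); each tier's total
    is conserved.
``receptor_inhibitor``
    L + R3 <-> LR3;  LR3 + R2 <-> D (active dimer);  I + R2 <-> IR2.
    Ligand L binds receptor R3; the complex dimerizes with co-receptor R2
    into the signaling dimer D; inhibitor I sequesters R2.  Total R2
    (R2 + D + IR2), total R3 (R3 + LR3 + D) and total I are conserved.
``crosstalk_shared_phosphatase``
    Two cascades X -> Xa and Y -> Ya (first-order activation), both
    deactivated by a shared phosphatase P via complexes
    Xa + P <-> XaP -> X + P and Ya + P <-> YaP -> Y + P, plus an inhibitor
    I_x sequestering Xa.  Inhibiting cascade X frees P, so the YaP complex
    rises — the shared-phosphatase crosstalk effect.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .interventions import Intervention, Regime
from .model_io import (
    DrugCatalogue,
    DrugEntry,
    KineticExpression,
    Parameter,
    Reaction,
    ReactionNetwork,
    Species,
    write_sbml,
)

MOTIFS = (
    "decay",
    "reversible_pair",
    "linear_cascade",
    "receptor_inhibitor",
    "crosstalk_shared_phosphatase",
)

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "make_regime_suite",
           "make_catalogue", "emit_fixture_tree", "MOTIFS"]


@dataclass
class FixtureSpec:
    """Which motif to build, its size, and optional seeded parameter jitter."""

    motif: str = "decay"
    n_tiers: int = 3  # linear_cascade only
    seed: int = 0
    jitter: float = 0.0  # relative sd of lognormal rate-constant jitter

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise ValidationError(f"unknown motif '{self.motif}' (choose from {MOTIFS})")
        if self.n_tiers < 1:
            raise ValidationError("linear_cascade needs n_tiers >= 1")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")


@dataclass
class Fixture:
    """A generated network plus its documented analytic properties."""

    network: ReactionNetwork
    properties: dict = field(default_factory=dict)


def _jitter(rng: np.random.RandomState, value: float, rel_sd: float) -> float:
    if rel_sd == 0:
        return value
    return float(value * rng.lognormal(0.0, rel_sd))


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the motif named by ``spec``; the returned properties record
    closed forms and conserved totals used by tests and the oracle suite."""
    rng = np.random.RandomState(spec.seed & 0x7FFFFFFF)
    j = lambda v: _jitter(rng, v, spec.jitter)  # noqa: E731

    if spec.motif == "decay":
        k = j(0.1)
        a0 = 10.0
        net = ReactionNetwork(id="decay")
        net.species = [Species("A", "A", a0), Species("B", "B", 0.0)]
        net.parameters = [Parameter("k_decay", k)]
        net.reactions = [
            Reaction("r_decay", reactants=[("A", 1.0)], products=[("B", 1.0)],
                     kinetic_law=KineticExpression("k_decay*A"))
        ]
        props = {
            "closed_form": {"A": {"kind": "exponential", "A0": a0, "k": k}},
            "conserved_totals": {"A_plus_B": ["A", "B"]},
        }

    elif spec.motif == "reversible_pair":
        kf, kr = j(0.4), j(0.25)
        net = ReactionNetwork(id="reversible_pair")
        net.species = [Species("A", "A", 8.0), Species("B", "B", 2.0)]
        net.parameters = [Parameter("k_f", kf), Parameter("k_r", kr)]
        net.reactions = [
            Reaction("r_fwd", reactants=[("A", 1.0)], products=[("B", 1.0)],
                     kinetic_law=KineticExpression("k_f*A")),
            Reaction("r_rev", reactants=[("B", 1.0)], products=[("A", 1.0)],
                     kinetic_law=KineticExpression("k_r*B")),
        ]
        props = {"conserved_totals": {"A_plus_B": ["A", "B"]}}

    elif spec.motif == "linear_cascade":
        n = spec.n_tiers
        net = ReactionNetwork(id=f"linear_cascade_{n}")
        props_totals = {}
        for i in range(1, n + 1):
            net.species += [
                Species(f"X{i}", f"X{i}", 10.0),
                Species(f"X{i}a", f"X{i} active", 0.0),
            ]
            props_totals[f"tier_{i}"] = [f"X{i}", f"X{i}a"]
            k_act, k_de = j(0.3), j(0.15)
            net.parameters += [
                Parameter(f"k_act_{i}", k_act),
                Parameter(f"k_de_{i}", k_de),
            ]
            if i == 1:
                law = KineticExpression("k_act_1*X1")
                mods = []
            else:
                law = KineticExpression(f"k_act_{i}*X{i}*X{i - 1}a")
                mods = [f"X{i - 1}a"]
            net.reactions += [
                Reaction(f"r_act_{i}", reactants=[(f"X{i}", 1.0)],
                         products=[(f"X{i}a", 1.0)], modifiers=mods,
                         kinetic_law=law),
                Reaction(f"r_de_{i}", reactants=[(f"X{i}a", 1.0)],
                         products=[(f"X{i}", 1.0)],
                         kinetic_law=KineticExpression(f"k_de_{i}*X{i}a")),
            ]
        props = {"conserved_totals": props_totals}

    elif spec.motif == "receptor_inhibitor":
        net = ReactionNetwork(id="receptor_inhibitor")
        net.species = [
            Species("L", "ligand", 20.0),
            Species("R3", "receptor", 10.0),
            Species("LR3", "ligand-receptor complex", 0.0),
            Species("R2", "co-receptor", 10.0),
            Species("D", "active dimer", 0.0),
            Species("I", "inhibitor drug", 0.0),
            Species("IR2", "inhibited co-receptor", 0.0),
        ]
        net.parameters = [
            Parameter("k_bind", j(0.05)),
            Parameter("k_unbind", j(0.1)),
            Parameter("k_dim", j(0.05)),
            Parameter("k_undim", j(0.05)),
            Parameter("k_inh", j(0.1)),
            Parameter("k_uninh", j(0.01)),
        ]
        net.reactions = [
            Reaction("r_bind", reactants=[("L", 1.0), ("R3", 1.0)],
                     products=[("LR3", 1.0)],
                     kinetic_law=KineticExpression("k_bind*L*R3")),
            Reaction("r_unbind", reactants=[("LR3", 1.0)],
                     products=[("L", 1.0), ("R3", 1.0)],
                     kinetic_law=KineticExpression("k_unbind*LR3")),
            Reaction("r_dimerize", reactants=[("LR3", 1.0), ("R2", 1.0)],
                     products=[("D", 1.0)],
                     kinetic_law=KineticExpression("k_dim*LR3*R2")),
            Reaction("r_undimerize", reactants=[("D", 1.0)],
                     products=[("LR3", 1.0), ("R2", 1.0)],
                     kinetic_law=KineticExpression("k_undim*D")),
            Reaction("r_inhibit", reactants=[("I", 1.0), ("R2", 1.0)],
                     products=[("IR2", 1.0)],
                     kinetic_law=KineticExpression("k_inh*I*R2")),
            Reaction("r_uninhibit", reactants=[("IR2", 1.0)],
                     products=[("I", 1.0), ("R2", 1.0)],
                     kinetic_law=KineticExpression("k_uninh*IR2")),
        ]
        props = {
            "conserved_totals": {
                "total_R2": ["R2", "D", "IR2"],
                "total_R3": ["R3", "LR3", "D"],
                "total_L": ["L", "LR3", "D"],
                "total_I": ["I", "IR2"],
            },
            "drug_target": "I",
            "readout": "D",
        }

    else:  # crosstalk_shared_phosphatase
        net = ReactionNetwork(id="crosstalk_shared_phosphatase")
        net.species = [
            Species("X", "kinase X", 10.0),
            Species("Xa", "active X", 0.0),
            Species("Y", "kinase Y", 10.0),
            Species("Ya", "active Y", 0.0),
            Species("P", "shared phosphatase", 5.0),
            Species("XaP", "Xa-phosphatase complex", 0.0),
            Species("YaP", "Ya-phosphatase complex", 0.0),
            Species("I_x", "cascade-X inhibitor", 0.0),
            Species("IXa", "inhibited Xa", 0.0),
        ]
        net.parameters = [
            Parameter("k_act_x", j(0.5)),
            Parameter("k_act_y", j(0.5)),
            Parameter("k_on", j(0.1)),
            Parameter("k_off", j(0.05)),
            Parameter("k_cat", j(0.2)),
            Parameter("k_ix", j(0.2)),
        ]

        def rxn(rid, reactants, products, law, mods=()):
            return Reaction(rid, reactants=reactants, products=products,
                            modifiers=list(mods),
                            kinetic_law=KineticExpression(law))

        net.reactions = [
            rxn("r_act_x", [("X", 1.0)], [("Xa", 1.0)], "k_act_x*X"),
            rxn("r_act_y", [("Y", 1.0)], [("Ya", 1.0)], "k_act_y*Y"),
            rxn("r_xp_on", [("Xa", 1.0), ("P", 1.0)], [("XaP", 1.0)], "k_on*Xa*P"),
            rxn("r_xp_off", [("XaP", 1.0)], [("Xa", 1.0), ("P", 1.0)], "k_off*XaP"),
            rxn("r_xp_cat", [("XaP", 1.0)], [("X", 1.0), ("P", 1.0)], "k_cat*XaP"),
            rxn("r_yp_on", [("Ya", 1.0), ("P", 1.0)], [("YaP", 1.0)], "k_on*Ya*P"),
            rxn("r_yp_off", [("YaP", 1.0)], [("Ya", 1.0), ("P", 1.0)], "k_off*YaP"),
            rxn("r_yp_cat", [("YaP", 1.0)], [("Y", 1.0), ("P", 1.0)], "k_cat*YaP"),
            rxn("r_ix", [("I_x", 1.0), ("Xa", 1.0)], [("IXa", 1.0)], "k_ix*I_x*Xa"),
        ]
        props = {
            "conserved_totals": {
                "total_X": ["X", "Xa", "XaP", "IXa"],
                "total_Y": ["Y", "Ya", "YaP"],
                "total_P": ["P", "XaP", "YaP"],
                "total_I": ["I_x", "IXa"],
            },
            "drug_target": "I_x",
            "readout": "YaP",
        }

    net.validate()
    return Fixture(network=net, properties=props)


def make_catalogue(fixture: Fixture) -> DrugCatalogue:
    """Drug catalogue bound to a dosable fixture's inhibitor species.

    Entries follow the anti-HER2 / PI3K-inhibitor dosing pattern of
    published combination-therapy screens: a 30 nM antibody-like inhibitor
    and a 100 nM small-molecule-like second inhibitor.
    """
    target = fixture.properties.get("drug_target")
    if target is None:
        raise ValidationError(
            f"motif '{fixture.network.id}' has no dosable inhibitor species"
        )
    if fixture.network.id == "crosstalk_shared_phosphatase":
        entries = [DrugEntry("cascade_x_inhibitor", 100.0, target)]
    else:
        entries = [DrugEntry("inhibitor", 30.0, target)]
    return DrugCatalogue(entries=entries)


def make_regime_suite(fixture: Fixture, mutated_species: str | None = None) -> list[Regime]:
    """The four standard experimental regimes for a dosable motif.

    1. empty Control; 2. 30 nM inhibitor at t=0; 3. a mutation modeled as a
    50% reduction of one species' level at t=0; 4. the combination of both.
    """
    target = fixture.properties.get("drug_target")
    if target is None:
        raise ValidationError(
            f"motif '{fixture.network.id}' has no dosable inhibitor species"
        )
    if mutated_species is None:
        mutated_species = "R3" if fixture.network.id == "receptor_inhibitor" else "P"
    fixture.network.get_species(mutated_species)  # raises if absent
    dosage = make_catalogue(fixture).entries[0].default_dosage
    dose = Intervention("dose", target, dosage, 0.0)
    mut = Intervention("scale_concentration", mutated_species, 0.5, 0.0)
    return [
        Regime("Control", []),
        Regime("Inhibitor", [dose]),
        Regime("Mutation", [mut]),
        Regime("Combination", [dose, mut]),
    ]


def emit_fixture_tree(out_dir: str | os.PathLike, seed: int = 0) -> dict:
    """Write every motif as SBML (+ regimes and catalogue where dosable).

    Returns the manifest, which is also written as ``manifest.json``.
    """
    from .interventions import save_regime

    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"seed": seed, "fixtures": {}}
    for motif in MOTIFS:
        fx = make_fixture(FixtureSpec(motif=motif, seed=seed))
        sub = os.path.join(out_dir, motif)
        os.makedirs(sub, exist_ok=True)
        files = {"sbml": write_sbml(fx.network, os.path.join(sub, "model.xml"))}
        if fx.properties.get("drug_target"):
            cat = make_catalogue(fx)
            cat_path = os.path.join(sub, "catalogue.csv")
            with open(cat_path, "w", encoding="utf-8") as fh:
                fh.write("name,dosage_nM,target_species\n")
                for e in cat.entries:
                    fh.write(f"{e.name},{e.default_dosage:g},{e.target_species}\n")
            files["catalogue"] = cat_path
            for regime in make_regime_suite(fx):
                files[f"regime_{regime.label}"] = save_regime(
                    regime, os.path.join(sub, f"regime_{regime.label.lower()}.yaml")
                )
        manifest["fixtures"][motif] = {
            "files": {k: os.path.relpath(v, out_dir) for k, v in files.items()},
            "properties": fx.properties,
        }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
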