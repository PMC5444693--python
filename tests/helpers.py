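"""Shared test utilities: an independent fixed-step RK4 integrator and small
hand-built networks.  The RK4 oracle deliberately shares nothing with the
adaptive simulation path except the compiled rate function."""

from __future__ import annotations

import numpy as np

from pathdyn import (
    KineticExpression,
    Parameter,
    Reaction,
    ReactionNetwork,
    Species,
)


def rk4_sample(sys, pars, t_end: float, h: float, sample_times) -> np.ndarray:
    """Classic fixed-step RK4 from the network's initial state.

    Returns concentrations sampled at ``sample_times`` (must be multiples
    of ``h`` up to rounding), shape (n_species, len(sample_times)).
    """
    y = np.array(sys.initial_concentrations, float)
    t = 0.0
    st = np.asarray(sample_times, float)
    out = np.empty((len(y), len(st)))
    si = 0
    n = int(round(t_end / h))
    f = sys.rhs
    for _ in range(n):
        while si < len(st) and st[si] <= t + h * 1e-6:
            out[:, si] = y
            si += 1
        k1 = f(t, y, pars)
        k2 = f(t + h / 2, y + h / 2 * k1, pars)
        k3 = f(t + h / 2, y + h / 2 * k2, pars)
        k4 = f(t + h, y + h * k3, pars)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    while si < len(st):
        out[:, si] = y
        si += 1
    return out


def triangle_network() -> ReactionNetwork:
    """Three species connected pairwise by three conversion reactions."""
    net = ReactionNetwork(id="triangle")
    net.species = [Species(s, s, 1.0) for s in "ABC"]
    net.parameters = [Parameter("k", 1.0)]
    for a, b in [("A", "B"), ("B", "C"), ("C", "A")]:
        net.reactions.append(
            Reaction(
                f"r{a}{b}",
                reactants=[(a, 1.0)],
                products=[(b, 1.0)],
                kinetic_law=KineticExpression(f"k*{a}"),
            )
        )
    return net.validate()


def random_network(seed: int) -> ReactionNetwork:
    """A randomized small mass-action network (for property tests)."""
    rng = np.random.RandomState(seed)
    n_s = rng.randint(1, 7)
    species = [f"S{i}" for i in range(n_s)]
    net = ReactionNetwork(id=f"rand{seed}")
    net.species = [
        Species(s, s, float(np.round(rng.uniform(0, 20), 6))) for s in species
    ]
    n_r = rng.randint(0, 2 * n_s + 1)
    for j in range(n_r):
        k = float(np.round(rng.uniform(0.01, 1.0), 6))
        net.parameters.append(Parameter(f"k{j}", k))
        order = rng.randint(1, 3)
        reactants = sorted(rng.choice(n_s, size=order, replace=True))
        prod = rng.randint(0, n_s)
        r_list: dict[str, float] = {}
        for idx in reactants:
            r_list[species[idx]] = r_list.get(species[idx], 0.0) + 1.0
        law = f"k{j}"
        for sid, st in r_list.items():
            law += f"*{sid}" if st == 1 else f"*{sid}**{int(st)}"
        net.reactions.append(
            Reaction(
                f"r{j}",
                reactants=list(r_list.items()),
                products=[(species[prod], 1.0)],
                kinetic_law=KineticExpression(law),
            )
        )
    return net.validate()


def conserved_total(traj, species_ids: list[str]) -> np.ndarray:
    rows = [traj.species_ids.index(s) for s in species_ids]
    return traj.concentrations[rows].sum(axis=0)
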