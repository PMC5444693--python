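"""Force-directed network layout in the plane, in 3-space, or on a sphere.

The drawn graph is bipartite: every reaction becomes a small auxiliary node
joined to each of its reactant, product and modifier species.  A reaction
with several participants then has a well-defined drawable geometry (one
hub, one spoke per participant), and per-reaction quantities (velocities,
diff colors) attach to the hub-and-spokes rather than to an ambiguous
species-species edge.

Positions come from Fruchterman-Reingold iteration: spring attraction along
graph edges toward the optimal edge length k = C*sqrt(area/n), pairwise
repulsion k^2/d, displacement capped by a temperature cooled linearly to
zero.  The sphere mode re-projects every node onto the sphere surface after
each iteration.  Layouts are deterministic for a fixed (seed, mode,
iterations).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import IntegrityError, ValidationError
from .model_io import ReactionNetwork

logger = logging.getLogger(__name__)

MODES = ("planar2d", "free3d", "sphere")

__all__ = ["Layout", "compute_layout", "edge_geometry", "edge_lengths",
           "write_layout", "read_layout"]


@dataclass
class Layout:
    """Node coordinates (arbitrary units) for species and reaction hubs."""

    positions: dict[str, np.ndarray]  # species id -> (2,) or (3,)
    reaction_positions: dict[str, np.ndarray]
    mode: str = "planar2d"
    seed: int = 0
    sphere_radius: float = 1.0
    iterations: int = 500

    @property
    def ndim(self) -> int:
        return 2 if self.mode == "planar2d" else 3


def _bipartite_graph(network: ReactionNetwork) -> nx.Graph:
    g = nx.Graph()
    for s in network.species:
        g.add_node(("s", s.id))
    for r in network.reactions:
        hub = ("r", r.id)
        g.add_node(hub)
        participants = {sid for sid, _ in r.reactants}
        participants |= {sid for sid, _ in r.products}
        participants |= set(r.modifiers)
        for sid in participants:
            g.add_edge(hub, ("s", sid))
    return g


def _fr_iterate(
    pos: np.ndarray,
    edges: np.ndarray,
    iterations: int,
    k: float,
    on_sphere: float | None,
) -> np.ndarray:
    """Core Fruchterman-Reingold loop over an (n, d) position array."""
    n = pos.shape[0]
    if n == 1:
        return pos
    t0 = 0.1 * max(1.0, on_sphere or 1.0)
    eps = 1e-12
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        disp = (delta / dist[..., None] ** 2 * k * k).sum(axis=1)
        if len(edges):
            d_e = pos[edges[:, 0]] - pos[edges[:, 1]]
            dist_e = np.maximum(np.linalg.norm(d_e, axis=-1, keepdims=True), eps)
            pull = d_e * dist_e / k
            np.add.at(disp, edges[:, 0], -pull)
            np.add.at(disp, edges[:, 1], pull)
        length = np.maximum(np.linalg.norm(disp, axis=-1, keepdims=True), eps)
        temp = t0 * (1.0 - it / iterations)
        pos = pos + disp / length * np.minimum(length, temp)
        if on_sphere is not None:
            norm = np.maximum(np.linalg.norm(pos, axis=-1, keepdims=True), eps)
            pos = pos * (on_sphere / norm)
    return pos


def compute_layout(
    network: ReactionNetwork,
    mode: str = "planar2d",
    seed: int = 0,
    iterations: int = 500,
    sphere_radius: float = 1.0,
) -> Layout:
    """Compute a force-directed layout of the bipartite species-reaction graph.

    Disconnected networks are laid out per connected component and the
    components placed side by side along the first axis (a warning is
    logged); in sphere mode all components share the one sphere.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got '{mode}'")
    if iterations < 1:
        raise ValidationError(f"iterations must be >= 1, got {iterations}")
    network.validate()
    g = _bipartite_graph(network)
    nodes = sorted(g.nodes)
    dim = 2 if mode == "planar2d" else 3
    rng = np.random.RandomState(seed & 0x7FFFFFFF)
    on_sphere = sphere_radius if mode == "sphere" else None

    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    if len(components) > 1:
        logger.warning(
            "network is disconnected (%d components); laying out per component",
            len(components),
        )

    all_pos: dict[tuple[str, str], np.ndarray] = {}
    if mode == "sphere" or len(components) == 1:
        pos = _init_positions(rng, len(nodes), dim, on_sphere)
        k = _optimal_distance(len(nodes), dim, on_sphere)
        index = {v: i for i, v in enumerate(nodes)}
        edges = np.array([(index[a], index[b]) for a, b in g.edges], int).reshape(-1, 2)
        pos = _fr_iterate(pos, edges, iterations, k, on_sphere)
        if len(nodes) == 1:
            pos = np.zeros((1, dim)) if on_sphere is None else pos
        for v, i in index.items():
            all_pos[v] = pos[i]
    else:
        offset = 0.0
        gap = 0.5
        for comp in components:
            sub = g.subgraph(comp)
            pos = _init_positions(rng, len(comp), dim, None)
            k = _optimal_distance(len(comp), dim, None)
            index = {v: i for i, v in enumerate(comp)}
            edges = np.array(
                [(index[a], index[b]) for a, b in sub.edges], int
            ).reshape(-1, 2)
            pos = _fr_iterate(pos, edges, iterations, k, None)
            if len(comp) == 1:
                pos = np.zeros((1, dim))
            pos = pos - pos.mean(axis=0)  # center component
            lo, hi = pos[:, 0].min(), pos[:, 0].max()
            pos[:, 0] += offset - lo
            offset += (hi - lo) + gap
            for v, i in index.items():
                all_pos[v] = pos[i]

    return Layout(
        positions={v[1]: all_pos[v] for v in nodes if v[0] == "s"},
        reaction_positions={v[1]: all_pos[v] for v in nodes if v[0] == "r"},
        mode=mode,
        seed=seed,
        sphere_radius=sphere_radius,
        iterations=iterations,
    )


def _init_positions(rng, n: int, dim: int, on_sphere: float | None) -> np.ndarray:
    if on_sphere is not None:
        raw = rng.normal(size=(n, dim))
        norm = np.maximum(np.linalg.norm(raw, axis=-1, keepdims=True), 1e-12)
        return raw / norm * on_sphere
    return rng.uniform(-0.5, 0.5, size=(n, dim))


def _optimal_distance(n: int, dim: int, on_sphere: float | None) -> float:
    if on_sphere is not None:
        area = 4.0 * np.pi * on_sphere**2
        return float(np.sqrt(area / max(n, 1)))
    return float(1.0 / np.sqrt(max(n, 1)))


def edge_geometry(
    layout: Layout, network: ReactionNetwork
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Drawable segments: (reaction id, species endpoint, hub endpoint)."""
    segments = []
    for r in network.reactions:
        if r.id not in layout.reaction_positions:
            raise IntegrityError(f"layout has no position for reaction '{r.id}'")
        hub = layout.reaction_positions[r.id]
        participants = dict.fromkeys(
            [sid for sid, _ in r.reactants]
            + [sid for sid, _ in r.products]
            + list(r.modifiers)
        )
        for sid in participants:
            if sid not in layout.positions:
                raise IntegrityError(f"layout has no position for species '{sid}'")
            segments.append((r.id, layout.positions[sid], hub))
    return segments


def edge_lengths(layout: Layout, network: ReactionNetwork) -> np.ndarray:
    """Lengths of all bipartite graph edges (the layout quality statistic)."""
    return np.array(
        [float(np.linalg.norm(a - b)) for _, a, b in edge_geometry(layout, network)]
    )


def write_layout(layout: Layout, path: str | os.PathLike) -> str:
    data = {
        "mode": layout.mode,
        "seed": layout.seed,
        "sphere_radius": layout.sphere_radius,
        "iterations": layout.iterations,
        "positions": {k: [float(x) for x in v] for k, v in layout.positions.items()},
        "reaction_positions": {
            k: [float(x) for x in v] for k, v in layout.reaction_positions.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return os.fspath(path)


def read_layout(path: str | os.PathLike) -> Layout:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return Layout(
        positions={k: np.array(v) for k, v in data["positions"].items()},
        reaction_positions={
            k: np.array(v) for k, v in data["reaction_positions"].items()
        },
        mode=data["mode"],
        seed=data["seed"],
        sphere_radius=data["sphere_radius"],
        iterations=data["iterations"],
    )
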