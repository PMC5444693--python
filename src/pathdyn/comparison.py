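"""Differential comparison of two simulation regimes.

Implements the white/red/blue encoding used for control-versus-experiment
animations: at every time point each species (node) and each reaction
velocity (edge) is compared between the two regimes; no difference renders
white, a higher experiment value red, a lower one blue, with color
intensity proportional to the difference magnitude.  The proportionality
scale is a normalization choice — per-entity (default; each entity's
differences are scaled by that entity's own maximum magnitude across both
regimes, keeping low-abundance species visible) or global (one scale for
all entities of a kind).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .simulation import Trajectory

__all__ = ["ComparisonResult", "compare", "diff_summary", "diff_to_rgb",
           "write_comparison"]

#: hue codes: 0 = neutral (white), +1 = high (red), -1 = low (blue)
NEUTRAL, HIGH, LOW = 0, 1, -1


@dataclass
class ComparisonResult:
    """Signed experiment-minus-control differences with color encoding.

    ``node_diff`` is (n_species, n_points) nM; ``edge_diff``
    (n_reactions, n_points) nM/min.  ``node_hue``/``edge_hue`` hold
    {-1, 0, +1} (low/neutral/high) and the intensity matrices lie in [0, 1].
    """

    time_grid: np.ndarray
    species_ids: list[str]
    reaction_ids: list[str]
    node_diff: np.ndarray
    edge_diff: np.ndarray
    node_hue: np.ndarray
    edge_hue: np.ndarray
    node_intensity: np.ndarray
    edge_intensity: np.ndarray
    node_scale: np.ndarray  # per-entity normalization constant M(e)
    edge_scale: np.ndarray
    normalization: str = "per-entity"
    control_label: str = "Control"
    experiment_label: str = "Experiment"

    def grid_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.time_grid - t)))


def _encode(diff: np.ndarray, scale: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hue = np.sign(diff).astype(int)
    safe = np.where(scale > 0, scale, 1.0)[:, None] if diff.size else scale[:, None]
    intensity = np.abs(diff) / safe
    intensity[scale == 0, :] = 0.0
    return hue, np.clip(intensity, 0.0, 1.0)


def compare(
    control: Trajectory, experiment: Trajectory, normalization: str = "per-entity"
) -> ComparisonResult:
    """Compare two trajectories of the same network on the same grid.

    diff = experiment - control, elementwise.  The intensity of entity *e*
    at time *t* is |diff(e,t)| / M(e) with M(e) the maximum |value| of *e*
    across both regimes and all times (per-entity mode) or the maximum over
    all entities of a kind (global mode); M(e)=0 maps to intensity 0.
    """
    if control.species_ids != experiment.species_ids or (
        control.reaction_ids != experiment.reaction_ids
    ):
        raise AlignmentError("trajectories cover different species/reaction sets")
    if control.n_points != experiment.n_points or not np.array_equal(
        control.time_grid, experiment.time_grid
    ):
        raise AlignmentError("trajectories are sampled on different time grids")
    if normalization not in ("per-entity", "global"):
        raise ValidationError(f"unknown normalization '{normalization}'")

    node_diff = experiment.concentrations - control.concentrations
    edge_diff = experiment.velocities - control.velocities

    def scales(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        per = np.maximum(
            np.abs(a).max(axis=1, initial=0.0), np.abs(b).max(axis=1, initial=0.0)
        )
        if normalization == "global":
            per = np.full_like(per, per.max(initial=0.0))
        return per

    node_scale = scales(control.concentrations, experiment.concentrations)
    edge_scale = scales(control.velocities, experiment.velocities)
    node_hue, node_int = _encode(node_diff, node_scale)
    edge_hue, edge_int = _encode(edge_diff, edge_scale)

    return ComparisonResult(
        time_grid=control.time_grid.copy(),
        species_ids=list(control.species_ids),
        reaction_ids=list(control.reaction_ids),
        node_diff=node_diff,
        edge_diff=edge_diff,
        node_hue=node_hue,
        edge_hue=edge_hue,
        node_intensity=node_int,
        edge_intensity=edge_int,
        node_scale=node_scale,
        edge_scale=edge_scale,
        normalization=normalization,
        control_label=control.regime_label,
        experiment_label=experiment.regime_label,
    )


def diff_summary(
    cmp: ComparisonResult, time: float, k: int = 10, kind: str = "nodes"
) -> list[tuple[str, float]]:
    """Top-k entities by |difference| at one time, descending.

    Exact zeros are excluded; ties in magnitude break by entity id.  An
    off-grid ``time`` falls back to the nearest grid point (with a warning
    from the grid lookup).
    """
    j = cmp.grid_index(time)
    if kind == "nodes":
        ids, col = cmp.species_ids, cmp.node_diff[:, j]
    elif kind == "edges":
        ids, col = cmp.reaction_ids, cmp.edge_diff[:, j]
    else:
        raise ValidationError(f"kind must be 'nodes' or 'edges', got '{kind}'")
    ranked = sorted(
        ((eid, float(d)) for eid, d in zip(ids, col) if d != 0.0),
        key=lambda item: (-abs(item[1]), item[0]),
    )
    return ranked[:k]


def diff_to_rgb(hue: int, intensity: float) -> tuple[int, int, int]:
    """Map a (hue, intensity) pair to 8-bit RGB.

    Neutral is white; positive hue interpolates white -> pure red, negative
    white -> pure blue, linearly in intensity.
    """
    v = int(round(255 * (1.0 - float(np.clip(intensity, 0.0, 1.0)))))
    if hue > 0:
        return (255, v, v)
    if hue < 0:
        return (v, v, 255)
    return (255, 255, 255)


def write_comparison(cmp: ComparisonResult, out_dir: str | os.PathLike) -> dict:
    """Export diff matrices as CSV plus a JSON sidecar with the scales."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "node_diff": os.path.join(out_dir, "node_diff.csv"),
        "edge_diff": os.path.join(out_dir, "edge_diff.csv"),
        "sidecar": os.path.join(out_dir, "comparison.json"),
    }
    pd.DataFrame(
        {"time_min": cmp.time_grid}
        | {sid: cmp.node_diff[i] for i, sid in enumerate(cmp.species_ids)}
    ).to_csv(paths["node_diff"], index=False, float_format="%.12g")
    pd.DataFrame(
        {"time_min": cmp.time_grid}
        | {rid: cmp.edge_diff[i] for i, rid in enumerate(cmp.reaction_ids)}
    ).to_csv(paths["edge_diff"], index=False, float_format="%.12g")
    sidecar = {
        "normalization": cmp.normalization,
        "control_label": cmp.control_label,
        "experiment_label": cmp.experiment_label,
        "node_scale": dict(zip(cmp.species_ids, map(float, cmp.node_scale))),
        "edge_scale": dict(zip(cmp.reaction_ids, map(float, cmp.edge_scale))),
    }
    with open(paths["sidecar"], "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
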