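"""Visual encoding of trajectories and regime comparisons into image frames.

Node radius scales linearly with species concentration (floor ``r_min`` so
empty species stay visible), edge width with |reaction velocity|, each
normalized per entity (or globally) over the run.  In single-run mode
everything renders white on a dark canvas; when a comparison is supplied,
nodes and edges take the white/red/blue differential coloring.  Animation
is realized as an exported frame sequence at a configurable number of
frames per simulated minute.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection

import numpy as np

from .comparison import ComparisonResult, diff_to_rgb
from .errors import ValidationError
from .layout import Layout, edge_geometry
from .model_io import ReactionNetwork
from .simulation import Trajectory

__all__ = ["EncodingConfig", "VisualFrame", "encode_frame", "export_frames",
           "export_timeseries_plot"]


@dataclass
class EncodingConfig:
    """Display constants for frame encoding.

    Radii/widths are in points on the fixed canvas; ``scaling`` is
    ``linear`` or ``log`` (log compresses wide dynamic ranges).
    """

    r_min: float = 4.0
    r_max: float = 28.0
    w_min: float = 0.6
    w_max: float = 7.0
    normalization: str = "per-entity"  # or "global"
    scaling: str = "linear"  # or "log"
    canvas: tuple[int, int] = (1200, 900)
    background: str = "#202030"
    node_alpha: float = 0.5
    frames_per_minute: float = 6.0

    def __post_init__(self):
        if not self.r_min < self.r_max:
            raise ValidationError("r_min must be < r_max")
        if not self.w_min < self.w_max:
            raise ValidationError("w_min must be < w_max")
        if self.normalization not in ("per-entity", "global"):
            raise ValidationError(f"unknown normalization '{self.normalization}'")
        if self.scaling not in ("linear", "log"):
            raise ValidationError(f"unknown scaling '{self.scaling}'")


@dataclass
class VisualFrame:
    """Per-time visual attributes for every node and edge."""

    time: float
    species_ids: list[str]
    reaction_ids: list[str]
    radii: np.ndarray  # (n_species,)
    widths: np.ndarray  # (n_reactions,)
    node_colors: list[tuple[int, int, int]]
    edge_colors: list[tuple[int, int, int]]


def _scale(values: np.ndarray, ceil: np.ndarray, lo: float, hi: float,
           scaling: str) -> np.ndarray:
    """Map values in [0, ceil] to [lo, hi]; ceil==0 maps to lo."""
    safe = np.where(ceil > 0, ceil, 1.0)
    x = np.clip(values / safe, 0.0, 1.0)
    if scaling == "log":
        x = np.log1p(9.0 * x) / np.log(10.0)
    out = lo + (hi - lo) * x
    out[ceil == 0] = lo
    return out


def encode_frame(
    traj: Trajectory,
    t: float,
    cfg: EncodingConfig | None = None,
    cmp: ComparisonResult | None = None,
) -> VisualFrame:
    """Encode one grid time into radii, widths and colors.

    The frame depends only on the trajectory columns at ``t`` plus the
    run-level normalization ceilings — no temporal state.
    """
    cfg = cfg or EncodingConfig()
    j = traj.grid_index(t)

    conc_ceil = np.abs(traj.concentrations).max(axis=1, initial=0.0)
    vel_ceil = np.abs(traj.velocities).max(axis=1, initial=0.0)
    if cfg.normalization == "global":
        conc_ceil = np.full_like(conc_ceil, conc_ceil.max(initial=0.0))
        vel_ceil = np.full_like(vel_ceil, vel_ceil.max(initial=0.0))

    radii = _scale(traj.concentrations[:, j], conc_ceil, cfg.r_min, cfg.r_max,
                   cfg.scaling)
    widths = _scale(np.abs(traj.velocities[:, j]), vel_ceil, cfg.w_min, cfg.w_max,
                    cfg.scaling)

    white = (255, 255, 255)
    if cmp is None:
        node_colors = [white] * len(traj.species_ids)
        edge_colors = [white] * len(traj.reaction_ids)
    else:
        jc = cmp.grid_index(traj.time_grid[j])
        node_colors = [
            diff_to_rgb(cmp.node_hue[i, jc], cmp.node_intensity[i, jc])
            for i in range(len(cmp.species_ids))
        ]
        edge_colors = [
            diff_to_rgb(cmp.edge_hue[i, jc], cmp.edge_intensity[i, jc])
            for i in range(len(cmp.reaction_ids))
        ]

    return VisualFrame(
        time=float(traj.time_grid[j]),
        species_ids=list(traj.species_ids),
        reaction_ids=list(traj.reaction_ids),
        radii=radii,
        widths=widths,
        node_colors=node_colors,
        edge_colors=edge_colors,
    )


def _project(p: np.ndarray) -> np.ndarray:
    """Orthographic projection: drop z for 3D layouts."""
    return p[:2]


def _draw_frame(frame: VisualFrame, layout: Layout, network: ReactionNetwork,
                cfg: EncodingConfig):
    w, h = cfg.canvas
    dpi = 100
    fig, ax = plt.subplots(figsize=(w / dpi, h / dpi), dpi=dpi)
    fig.patch.set_facecolor(cfg.background)
    ax.set_facecolor(cfg.background)
    ax.set_aspect("equal")
    ax.axis("off")

    width_by_rxn = dict(zip(frame.reaction_ids, frame.widths))
    color_by_rxn = dict(zip(frame.reaction_ids, frame.edge_colors))
    segs, widths, colors = [], [], []
    for rid, a, b in edge_geometry(layout, network):
        segs.append([_project(a), _project(b)])
        widths.append(width_by_rxn[rid])
        colors.append(tuple(c / 255 for c in color_by_rxn[rid]))
    if segs:
        ax.add_collection(LineCollection(segs, linewidths=widths, colors=colors,
                                         zorder=1, capstyle="round"))

    xy = np.array([_project(layout.positions[s]) for s in frame.species_ids])
    rgb = np.array([[c / 255 for c in col] for col in frame.node_colors])
    ax.scatter(
        xy[:, 0], xy[:, 1],
        s=frame.radii**2,  # matplotlib sizes are area-like (points^2)
        c=rgb, alpha=cfg.node_alpha, edgecolors="none", zorder=2,
    )
    ax.scatter(xy[:, 0], xy[:, 1], s=max(cfg.r_min, 2.0) ** 2 / 4, c="#f0d000",
               edgecolors="none", zorder=3)  # node cores

    pts = np.vstack([xy] + [[_project(p)] for p in layout.reaction_positions.values()])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    pad = 0.08 * max(float((hi - lo).max()), 1e-6)
    ax.set_xlim(lo[0] - pad, hi[0] + pad)
    ax.set_ylim(lo[1] - pad, hi[1] + pad)
    ax.set_title(f"t = {frame.time:.3f} min", color="white")
    return fig


def export_frames(
    frames: list[VisualFrame],
    layout: Layout,
    network: ReactionNetwork,
    out_dir: str | os.PathLike,
    cfg: EncodingConfig | None = None,
    fmt: str = "png",
) -> list[str]:
    """Rasterize frames to ``frame_0000.png`` ... in time order.

    PNG export is deterministic: fixed inputs give byte-identical files.
    """
    if fmt not in ("png", "jpeg", "jpg"):
        raise ValidationError(f"format must be png or jpeg, got '{fmt}'")
    cfg = cfg or EncodingConfig()
    os.makedirs(out_dir, exist_ok=True)
    ext = "jpg" if fmt in ("jpeg", "jpg") else "png"
    paths = []
    for i, frame in enumerate(frames):
        fig = _draw_frame(frame, layout, network, cfg)
        path = os.path.join(out_dir, f"frame_{i:04d}.{ext}")
        fig.savefig(path, facecolor=fig.get_facecolor(),
                    metadata={"Software": "pathdyn"} if ext == "png" else None)
        plt.close(fig)
        paths.append(path)
    return paths


def frame_times(t_end: float, cfg: EncodingConfig) -> np.ndarray:
    """Animation sample times: cfg.frames_per_minute frames per minute."""
    n = max(2, int(round(t_end * cfg.frames_per_minute)) + 1)
    return np.linspace(0.0, t_end, n)


def export_timeseries_plot(
    trajectories: Trajectory | list[Trajectory],
    species: str,
    path: str | os.PathLike,
) -> str:
    """Line plot of one species over time (control black, experiment blue)."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not 1 <= len(trajectories) <= 2:
        raise ValidationError("expected one or two trajectories")
    colors = ["black", "tab:blue"]
    fig, ax = plt.subplots(figsize=(5, 3.2), dpi=100)
    for traj, color in zip(trajectories, colors):
        ax.plot(traj.time_grid, traj.species_series(species), color=color,
                label=traj.regime_label)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"[{species}] (nM)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "pathdyn"})
    plt.close(fig)
    return os.fspath(path)
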