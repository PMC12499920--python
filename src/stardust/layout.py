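"""Force-directed 2D layout of the CGNNN.

The layout minimizes an attraction-plus-density objective,

    min_x  sum_i ( sum_j w_ij d(x_i, x_j)^2  +  D_{x_i} ),

with unit edge weights, Euclidean d, and D a measure of how crowded the
neighborhood of x_i is.  Optimization is simulated annealing over a
five-stage schedule (liquid, expansion, cooldown, crunch, simmer) with an
edge-cutting heuristic that trades cluster cohesion for white space.

Two interchangeable backends are provided: ``drl`` delegates to igraph's
DrL implementation (the standard library form of this layout family), and
``anneal`` is a self-contained vectorized annealer that optimizes the same
objective.  Both honor the seed and the stage schedule; they are accepted
through structural properties (cluster separation, objective decrease), not
coordinate equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import CellGeneGraph, Embedding2D

log = logging.getLogger(__name__)

__all__ = ["Stage", "StageSchedule", "layout_graph", "layout_objective",
           "attraction_energy"]

#: grid resolution for the density term (bins per axis)
DENSITY_GRID = 64


@dataclass
class Stage:
    iterations: int
    temperature: float
    attraction: float
    damping_mult: float
    cut: bool = False
    #: weight multiplier of the density (repulsion) term in the annealer
    density_mult: float = 1.0
    #: centroid-pull fraction for the annealer; None derives it from attraction
    pull: float | None = None


@dataclass
class StageSchedule:
    """Canonical five-stage annealing schedule.

    Temperatures are on the conventional 0-2000 scale of the original
    implementation and are rescaled internally to the layout extent; the
    attraction parameter controls the size of the pull toward the neighbor
    centroid.  Edge cutting is active during cooldown and crunch.
    """

    init: Stage = field(default_factory=lambda: Stage(0, 2000, 10, 1.0))
    liquid: Stage = field(default_factory=lambda: Stage(200, 2000, 10, 1.0))
    expansion: Stage = field(default_factory=lambda: Stage(
        200, 2000, 2, 1.0, density_mult=2.0))
    cooldown: Stage = field(default_factory=lambda: Stage(
        200, 1000, 1, 0.1, cut=True, pull=0.5))
    crunch: Stage = field(default_factory=lambda: Stage(
        50, 250, 1, 0.25, cut=True, density_mult=0.2, pull=0.7))
    simmer: Stage = field(default_factory=lambda: Stage(
        100, 250, 0.5, 0.0, cut=True, density_mult=0.05, pull=0.7))

    def stages(self) -> list[tuple[str, Stage]]:
        return [(name, getattr(self, name))
                for name in ("init", "liquid", "expansion", "cooldown", "crunch", "simmer")]

    def scaled(self, factor: float) -> "StageSchedule":
        """Schedule with iteration counts scaled by ``factor`` (min 10)."""
        out = StageSchedule()
        for name, stage in self.stages():
            s = getattr(out, name)
            s.iterations = 0 if stage.iterations == 0 else max(10, int(stage.iterations * factor))
            s.temperature, s.attraction = stage.temperature, stage.attraction
            s.damping_mult, s.cut = stage.damping_mult, stage.cut
            s.density_mult, s.pull = stage.density_mult, stage.pull
        return out

    def to_drl_options(self, edge_cut: float) -> dict:
        opts = {"edge_cut": float(edge_cut)}
        for name, stage in self.stages():
            opts[f"{name}_iterations"] = int(stage.iterations)
            opts[f"{name}_temperature"] = float(stage.temperature)
            opts[f"{name}_attraction"] = float(stage.attraction)
            opts[f"{name}_damping_mult"] = float(stage.damping_mult)
        return opts


def layout_graph(graph: CellGeneGraph, seed: int = 0, edge_cut: float = 0.8,
                 schedule: StageSchedule | None = None,
                 backend: str = "anneal") -> Embedding2D:
    """Embed every node of the CGNNN in 2D.

    Deterministic for a fixed seed, schedule, and backend.  A single node
    is placed at the origin by convention.
    """
    graph.validate()
    if not 0 <= edge_cut <= 1:
        raise ValueError("edge_cut must lie in [0, 1]")
    schedule = schedule or StageSchedule()
    n = graph.n_nodes
    if n == 1:
        coords = np.zeros((1, 2))
    elif backend == "drl":
        coords = _layout_drl(graph, seed, edge_cut, schedule)
    elif backend == "anneal":
        coords = _layout_anneal(graph, seed, edge_cut, schedule)
    else:
        raise ValueError(f"unknown layout backend {backend!r}")
    return Embedding2D(graph.node_ids, graph.node_types, coords,
                       seed=seed, edge_cut=edge_cut)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def layout_objective(graph: CellGeneGraph, emb: Embedding2D,
                     grid_bin: float | None = None) -> float:
    """Attraction-plus-density energy of an embedding.

    The attraction term sums squared Euclidean edge lengths (each edge
    once, unit weights).  The density term approximates "density of the
    edges near x_i": edge midpoints are binned on a fixed-resolution grid
    (bin width = extent/64 unless ``grid_bin`` overrides it), smoothed with
    a Gaussian kernel, and sampled at every node position.
    """
    coords = emb.lookup(graph.node_ids)
    edges = graph.edge_array()
    density = float(np.sum(_density_at(coords, _edge_midpoints(coords, edges),
                                       grid_bin=grid_bin)))
    return attraction_energy(graph, emb) + density


def attraction_energy(graph: CellGeneGraph, emb: Embedding2D) -> float:
    """The attraction term alone: sum of squared edge lengths (unit weights)."""
    coords = emb.lookup(graph.node_ids)
    edges = graph.edge_array()
    if not edges.size:
        return 0.0
    diff = coords[edges[:, 0]] - coords[edges[:, 1]]
    return float(np.sum(diff ** 2))


def _edge_midpoints(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    if not edges.size:
        return coords
    return 0.5 * (coords[edges[:, 0]] + coords[edges[:, 1]])


def _density_at(query: np.ndarray, mass_points: np.ndarray,
                grid_bin: float | None = None, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-smoothed occupancy-grid density evaluated at query points."""
    lo = mass_points.min(axis=0)
    hi = mass_points.max(axis=0)
    extent = float(max(hi.max() - lo.min(), 1e-9))
    width = grid_bin if grid_bin is not None else extent / DENSITY_GRID
    nbins = max(2, int(np.ceil(extent / width)) + 1)
    lo_all = np.minimum(lo, query.min(axis=0)) - width
    hist, xe, ye = np.histogram2d(
        mass_points[:, 0], mass_points[:, 1], bins=nbins,
        range=[[lo_all[0], lo_all[0] + (nbins + 1) * width],
               [lo_all[1], lo_all[1] + (nbins + 1) * width]])
    smooth = gaussian_filter(hist, sigma=sigma)
    ix = np.clip(np.searchsorted(xe, query[:, 0]) - 1, 0, nbins - 1)
    iy = np.clip(np.searchsorted(ye, query[:, 1]) - 1, 0, nbins - 1)
    return smooth[ix, iy]


# ---------------------------------------------------------------------------
# DrL backend
# ---------------------------------------------------------------------------

def _layout_drl(graph: CellGeneGraph, seed: int, edge_cut: float,
                schedule: StageSchedule) -> np.ndarray:
    import random as _random

    import igraph as ig

    g = graph.to_igraph()
    rng = np.random.default_rng(seed)
    init = rng.uniform(-1, 1, size=(graph.n_nodes, 2)).tolist()
    ig.set_random_number_generator(_random.Random(seed))
    try:
        lay = g.layout_drl(options=schedule.to_drl_options(edge_cut), seed=init)
    finally:
        ig.set_random_number_generator(_random)
    return np.asarray(lay.coords, dtype=float)


# ---------------------------------------------------------------------------
# bespoke annealer
# ---------------------------------------------------------------------------

def _layout_anneal(graph: CellGeneGraph, seed: int, edge_cut: float,
                   schedule: StageSchedule) -> np.ndarray:
    """Vectorized simulated annealing on the attraction+density objective.

    Every iteration each node evaluates three candidate positions — stay,
    a damped move toward its neighbor centroid, a temperature-scaled random
    jump — and keeps the cheapest under the node-local energy
    (attraction to neighbors plus smoothed occupancy density, the density
    term rescaled each iteration so the two terms stay commensurate).
    During cutting stages the longest edges (a fraction proportional to
    ``edge_cut``) are excluded from the attraction force, opening white
    space between weakly connected regions.
    """
    n = graph.n_nodes
    edges = graph.edge_array()
    rng = np.random.default_rng(seed)
    scale = max(1.0, np.sqrt(n))  # reference length, fixed for the whole run
    X = _uniform_disc(rng, n, scale / 2)
    if not edges.size:
        return X

    cut_frac = 0.3 * edge_cut

    for _, stage in schedule.stages():
        pull = stage.pull if stage.pull is not None else (
            min(1.0, stage.attraction / 10.0) * 0.5 + 0.1)
        density_weight = None
        for it in range(stage.iterations):
            act = edges
            if stage.cut and cut_frac > 0:
                el = np.sum((X[edges[:, 0]] - X[edges[:, 1]]) ** 2, axis=1)
                keep = el <= np.quantile(el, 1 - cut_frac)
                act = edges[keep] if keep.any() else edges

            deg, S, Q = _neighbor_sums(X, act, n)
            has = deg > 0
            centroid = X.copy()
            centroid[has] = S[has] / deg[has, None]

            # temperature decays linearly within the stage toward
            # damping_mult * temperature; jumps are sized on the fixed
            # reference scale so the layout cannot expand without bound
            frac = it / max(stage.iterations - 1, 1)
            temp = stage.temperature / 2000.0 * (
                1.0 - frac * (1.0 - stage.damping_mult))
            jump_sd = max(temp * scale * 0.5, 1e-3)
            cand_a = X + pull * (centroid - X) + rng.normal(
                0, 0.02 * scale * max(temp, 0.05), size=X.shape)
            cand_b = X + rng.normal(0, jump_sd, size=X.shape)

            mids = _edge_midpoints(X, act)
            density = lambda P: _density_at(P, mids)  # noqa: E731
            attr = lambda P: deg * np.sum(P ** 2, axis=1) - 2 * np.sum(P * S, axis=1) + Q  # noqa: E731
            d0, da, db = density(X), density(cand_a), density(cand_b)
            a0, aa, ab = attr(X), attr(cand_a), attr(cand_b)
            if density_weight is None:
                # balance the two terms once per stage to avoid a feedback
                # loop between expansion and the adaptive weight
                density_weight = stage.density_mult * (
                    (np.mean(a0) + 1e-9) / (np.mean(d0) + 1e-9))
            e = np.stack([a0 + density_weight * d0,
                          aa + density_weight * da,
                          ab + density_weight * db])
            choice = np.argmin(e, axis=0)
            X = np.where(choice[:, None] == 1, cand_a,
                         np.where(choice[:, None] == 2, cand_b, X))
        log.debug("stage done: extent %.2f", float(np.ptp(X, axis=0).max()))
    return X - X.mean(axis=0)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _neighbor_sums(X: np.ndarray, edges: np.ndarray, n: int):
    """Per-node degree, neighbor coordinate sum, neighbor squared-norm sum."""
    deg = np.zeros(n)
    S = np.zeros((n, 2))
    Q = np.zeros(n)
    sq = np.sum(X ** 2, axis=1)
    for a, b in ((edges[:, 0], edges[:, 1]), (edges[:, 1], edges[:, 0])):
        np.add.at(deg, a, 1.0)
        np.add.at(S, a, X[b])
        np.add.at(Q, a, sq[b])
    return deg, S, Q
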