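"""Synthetic multi-level administrative landscapes with known migration truth.

Real inputs of this kind — census microdata flows, gridded population,
urban extent and economic surfaces — are restricted or heavy, so simulation
studies run on generated landscapes that reproduce their statistical
structure: fine units nested in coarse units on a plane, heavy-tailed
(log-normal) populations, Beta-distributed urban fractions, log-normal
per-capita economic values, contiguity from a planar tessellation of the
unit seed points, and five-year migrant counts drawn binomially at a census
sampling fraction from a gravity model with known coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, distance_matrix

from .covariates import ModelSpec, build_pair_design
from .landscape import Adjacency, pairwise_distances, validate_unit_table
from .model import CoarseFlows, aggregate_proportions, predict_vij, proportion_matrix

#: generative coefficients with signs matching the fitted fine-scale model
#: (distance decay, mild population effects); on the standardized scale
DEFAULT_TRUE_BETA = {
    "Intercept": -6.0,
    "DIST_ij": -2.0,
    "POP_j": -0.12,
    "POP_i": 0.16,
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Shape and distributional parameters of a generated landscape.

    Populations are log-normal (median exp(pop_mu) persons), urban fractions
    Beta(a, b), per-capita economic values log-normal; each coarse unit is a
    square cell of side ``extent_km`` holding its fine units' seed points.
    The default sampling fraction 0.1 mirrors a 10% census sample.
    """

    n_coarse: int = 8
    fine_per_coarse: int | tuple[int, int] = 6
    pop_mu: float = np.log(15_000.0)
    pop_sigma: float = 1.0
    urban_a: float = 2.0
    urban_b: float = 2.0
    gcp_mu: float = np.log(6.0)
    gcp_sigma: float = 0.5
    extent_km: float = 100.0
    sampling_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coarse < 1:
            raise ValueError("need at least one coarse unit")
        lo, hi = self._fine_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid fine_per_coarse")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must lie in (0, 1]")
        if self.pop_sigma <= 0 or self.gcp_sigma <= 0 or self.extent_km <= 0 \
                or self.urban_a <= 0 or self.urban_b <= 0:
            raise ValueError("invalid distribution parameters")

    @property
    def _fine_range(self) -> tuple[int, int]:
        if isinstance(self.fine_per_coarse, tuple):
            return self.fine_per_coarse
        return (self.fine_per_coarse, self.fine_per_coarse)


@dataclass
class GroundTruth:
    """Generative state of a simulated observation set."""

    beta: dict[str, float]
    spec: ModelSpec
    v: pd.DataFrame
    P: pd.DataFrame
    flows: CoarseFlows
    sampling_fraction: float

    def to_csv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            pd.Series(self.beta, name="true_value").rename_axis("parameter").to_csv(fh)


def _tessellation_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Adjacency of seed points: units are contiguous when their tessellation
    cells share a boundary, i.e. when they are Delaunay neighbours."""
    edges: set[tuple[int, int]] = set()
    if len(points) < 3:
        for i in range(len(points)):
            for j in range(i + 1, len(points)):
                edges.add((i, j))
        return edges
    tri = Delaunay(points)
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    return edges


def generate_landscape(cfg: LandscapeConfig) -> tuple[pd.DataFrame, Adjacency, pd.DataFrame]:
    """Generate (unit table, contiguity, distance matrix) from a config.

    Coarse units tile a planar grid of square cells; fine-unit seed points
    fall uniformly inside their cell; contiguity joins Delaunay neighbours
    of the seed points, augmented with each coarse cell's internal minimum
    spanning tree so that every coarse unit is internally connected.
    """
    rng = np.random.default_rng(cfg.seed)
    ncols = int(np.ceil(np.sqrt(cfg.n_coarse)))
    lo, hi = cfg._fine_range
    rows = []
    for c in range(cfg.n_coarse):
        cell_x = (c % ncols) * cfg.extent_km
        cell_y = (c // ncols) * cfg.extent_km
        n_fine = int(rng.integers(lo, hi + 1))
        coarse_id = f"C{c + 1:02d}"
        for k in range(n_fine):
            rows.append({
                "id": f"{coarse_id}M{k + 1:02d}",
                "coarse_id": coarse_id,
                "population": float(rng.lognormal(cfg.pop_mu, cfg.pop_sigma)),
                "urban_prop": float(rng.beta(cfg.urban_a, cfg.urban_b)),
                "gcp_pc": float(rng.lognormal(cfg.gcp_mu, cfg.gcp_sigma)),
                "cx": cell_x + float(rng.uniform(0, cfg.extent_km)),
                "cy": cell_y + float(rng.uniform(0, cfg.extent_km)),
            })
    units = validate_unit_table(pd.DataFrame(rows))
    points = units[["cx", "cy"]].to_numpy()
    edges = _tessellation_edges(points)
    for coarse_id, members in units.groupby("coarse_id").groups.items():
        idx = np.asarray(list(members))
        if idx.size < 2:
            continue
        d = distance_matrix(points[idx], points[idx])
        mst = minimum_spanning_tree(d).tocoo()
        for a, b in zip(mst.row, mst.col):
            edges.add(tuple(sorted((int(idx[a]), int(idx[b])))))
    ids = units["id"].to_numpy()
    adj = Adjacency(list(ids), _edge_matrix(len(ids), edges))
    return units, adj, pairwise_distances(units)


def _edge_matrix(n: int, edges) -> np.ndarray:
    mat = np.zeros((n, n), dtype=int)
    for i, j in edges:
        mat[i, j] = mat[j, i] = 1
    return mat


def simulate_flows(units: pd.DataFrame, adj: Adjacency, dist: pd.DataFrame,
                   beta_true: dict[str, float] | None = None,
                   spec: ModelSpec | None = None,
                   sampling_fraction: float = 0.1, seed: int = 0,
                   multinomial: bool = False,
                   ) -> tuple[CoarseFlows, GroundTruth]:
    """Draw coarse-level migrant counts from the model run generatively.

    The pair design is built and standardized exactly as at fitting time,
    true proportions v and P are computed through the model, each origin's
    sample size is n_I = round(sampling_fraction * N_I), and counts are
    drawn independently per destination as Binomial(n_I, P_IJ) — matching
    the fitted likelihood.  ``multinomial=True`` instead draws one
    multinomial per origin (a deliberate mis-specification for robustness
    studies).
    """
    if beta_true is None:
        beta_true = dict(DEFAULT_TRUE_BETA)
    if spec is None:
        spec = ModelSpec(tuple(k for k in beta_true if k != "Intercept"))
    beta = np.array([beta_true["Intercept"]]
                    + [beta_true[c] for c in spec.covariates])
    design, _ = build_pair_design(units, adj, dist, spec)
    v_vec = predict_vij(beta, design)
    v = proportion_matrix(design, v_vec)
    P = aggregate_proportions(v, units)
    offdiag = P.to_numpy()[~np.eye(len(P), dtype=bool)]
    if (offdiag >= 1).any():
        raise ValueError("implausible truth: an aggregated proportion reaches 1")
    rng = np.random.default_rng(seed)
    pop_I = units.groupby("coarse_id")["population"].sum()
    sizes = (sampling_fraction * pop_I).round().astype(int).clip(lower=1)
    labels = list(P.index)
    rows = []
    for I in labels:
        dests = [J for J in labels if J != I]
        pvec = P.loc[I, dests].to_numpy(dtype=float)
        n_I = int(sizes[I])
        if pvec.sum() >= 1:
            raise ValueError("implausible truth: total outmigration reaches 1")
        if multinomial:
            counts = rng.multinomial(n_I, np.append(pvec, 1.0 - pvec.sum()))[:-1]
        else:
            # independent binomials per destination; redraw in the (vanishingly
            # rare under plausible truths) event the total exceeds n_I
            while True:
                counts = rng.binomial(n_I, pvec)
                if counts.sum() <= n_I:
                    break
        rows.extend({"origin": I, "dest": J, "count": int(m)}
                    for J, m in zip(dests, counts))
    flows = CoarseFlows(pd.DataFrame(rows), sizes)
    names = ("Intercept",) + spec.covariates
    truth = GroundTruth({n: float(b) for n, b in zip(names, beta)},
                        spec, v, P, flows, sampling_fraction)
    return flows, truth


def coarsen_partition(units: pd.DataFrame, adj: Adjacency, target_groups: int,
                      seed: int = 0) -> pd.Series:
    """Random intermediate-level partition: contiguous within-coarse groups.

    Starting from singletons, randomly merges pairs of adjacent groups that
    lie in the same coarse unit until ``target_groups`` remain, producing a
    mix of single-unit and multi-unit groups, each connected under the
    contiguity relation and contained in one coarse unit.
    """
    n = len(units)
    n_coarse = units["coarse_id"].nunique()
    if not n_coarse <= target_groups <= n:
        raise ValueError(
            f"target_groups must lie in [{n_coarse}, {n}]")
    rng = np.random.default_rng(seed)
    ids = list(units["id"])
    coarse = dict(zip(units["id"], units["coarse_id"]))
    group = {u: u for u in ids}
    edges = [(a, b) for a, b in adj.edges() if coarse[a] == coarse[b]]
    n_groups = n
    while n_groups > target_groups:
        mergeable = [(a, b) for a, b in edges if group[a] != group[b]]
        if not mergeable:
            raise RuntimeError("target_groups unreachable under contiguity")
        a, b = mergeable[rng.integers(len(mergeable))]
        ga, gb = group[a], group[b]
        for u in ids:
            if group[u] == gb:
                group[u] = ga
        n_groups -= 1
    # stable group labels: the coarse id plus the lexicographically first member
    members: dict[str, list[str]] = {}
    for u in ids:
        members.setdefault(group[u], []).append(u)
    label = {g: f"{coarse[us[0]]}:{min(us)}" for g, us in members.items()}
    return pd.Series({u: label[group[u]] for u in ids}, name="group_id")
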