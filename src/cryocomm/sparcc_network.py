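"""SparCC compositional correlation inference, bootstrap significance and
co-occurrence network construction.

SparCC estimates correlations between underlying (basis) abundances from
compositional count data.  For log-ratio variances t_ij = var(log x_i/x_j)
the identity t_ij = w_i + w_j - 2*rho_ij*sqrt(w_i w_j) holds with basis
variances w.  Under a sparsity assumption (most true correlations are
small) the w are solved from the linear system obtained by summing t over
partners, strongly correlated pairs are iteratively excluded from the
system, and the correlation is rho_ij = (w_i + w_j - t_ij)/(2 sqrt(w_i w_j))
clipped to [-1, 1].  Count uncertainty is handled by drawing fractions from
a per-sample Dirichlet posterior (unit prior) and taking the median over
iterations; a deterministic (counts+1)-fraction mode is available for
reproducible unit arithmetic.

Significance: per-taxon bootstrap resampling across samples destroys
inter-taxon association while preserving marginals; the two-sided p-value
uses the (1 + m)/(1 + M) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CountTable, TaxonomyTable, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    taxon_ids: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame | None
    n_bootstrap: int
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        if not np.allclose(r, r.T, atol=1e-9):
            raise ValidationError("rho must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValidationError("rho must have unit diagonal")
        if r.min() < -1 - 1e-9 or r.max() > 1 + 1e-9:
            raise ValidationError("rho entries must lie in [-1, 1]")


def _log_ratio_variances(frac: np.ndarray) -> np.ndarray:
    """t_ij = var(log x_i - log x_j) across samples via the covariance matrix."""
    L = np.log(frac)
    C = np.cov(L, ddof=1)
    v = np.diag(C)
    return v[:, None] + v[None, :] - 2.0 * C


def _basis_solve(T: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve for basis variances from row sums of T with excluded pairs
    removed from both the sums and the coefficient matrix."""
    D = T.shape[0]
    M = np.full((D, D), 1.0)
    np.fill_diagonal(M, D - 1.0)
    t_row = T.sum(axis=1).astype(float)
    for i, j in excluded:
        t_row[i] -= T[i, j]
        t_row[j] -= T[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
    w = np.linalg.solve(M, t_row)
    return np.clip(w, 1e-12, None)


def _rho_from_basis(T: np.ndarray, w: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(w, w))
    rho = (w[:, None] + w[None, :] - T) / denom
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def _sparcc_single(frac: np.ndarray, exclusion_rounds: int,
                   exclusion_threshold: float) -> np.ndarray:
    """One SparCC pass on a fractions matrix (taxa x samples)."""
    D = frac.shape[0]
    T = _log_ratio_variances(frac)
    excluded: set[tuple[int, int]] = set()
    excl_count = np.zeros(D, dtype=int)
    w = _basis_solve(T, excluded)
    rho = _rho_from_basis(T, w)
    for _ in range(exclusion_rounds):
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        # taxa already excluded from too many pairs leave the exclusion game
        saturated = excl_count >= D - 3
        cand[saturated, :] = 0.0
        cand[:, saturated] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        excl_count[i] += 1
        excl_count[j] += 1
        w = _basis_solve(T, excluded)
        rho = _rho_from_basis(T, w)
    return rho


def _draw_fractions(counts: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Per-sample fractions; Dirichlet(counts+1) posterior draw, or the
    deterministic (counts+1)-normalised fractions when rng is None."""
    a = counts + 1.0
    if rng is None:
        return a / a.sum(axis=0)
    g = rng.gamma(a)
    g = np.clip(g, 1e-300, None)
    return g / g.sum(axis=0)


def sparcc(table: CountTable | pd.DataFrame, iterations: int = 50,
           exclusion_rounds: int = 10, exclusion_threshold: float = 0.1,
           seed: int | np.random.Generator | None = 0,
           deterministic: bool = False) -> CorrelationResult:
    """SparCC correlation matrix: median over Dirichlet-resampled passes.

    ``deterministic=True`` replaces the posterior draw by (counts+1)
    fractions and runs a single pass.
    """
    df = table.data if hasattr(table, "data") else table
    counts = df.to_numpy(dtype=float)
    D, n = counts.shape
    if D < 4:
        raise ValidationError("SparCC needs at least 4 taxa")
    if n < 3:
        raise ValidationError("SparCC needs at least 3 samples")
    if np.allclose(counts, counts[:, [0]]):
        raise ValidationError("degenerate input: all samples identical")
    if n < 20:
        warnings.warn(f"SparCC estimates are noisy with only {n} samples",
                      stacklevel=2)
    settings = {"iterations": iterations, "exclusion_rounds": exclusion_rounds,
                "exclusion_threshold": exclusion_threshold,
                "deterministic": deterministic}
    if deterministic:
        rho = _sparcc_single(_draw_fractions(counts, None),
                             exclusion_rounds, exclusion_threshold)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        stack = np.empty((iterations, D, D))
        for it in range(iterations):
            frac = _draw_fractions(counts, rng)
            stack[it] = _sparcc_single(frac, exclusion_rounds, exclusion_threshold)
        rho = np.median(stack, axis=0)
        rho = (rho + rho.T) / 2.0
        np.fill_diagonal(rho, 1.0)
    ids = tuple(df.index)
    return CorrelationResult(ids, pd.DataFrame(rho, index=ids, columns=ids),
                             p=None, n_bootstrap=0, settings=settings)


def bootstrap_pvalues(table: CountTable | pd.DataFrame, observed: CorrelationResult,
                      n_boot: int = 999, seed: int | None = 0,
                      iterations: int | None = None) -> CorrelationResult:
    """Two-sided bootstrap p-values for an observed SparCC matrix.

    Each bootstrap resamples every taxon's counts independently across
    samples (with replacement), breaking inter-taxon association, and
    recomputes rho with the same settings (``iterations`` may be lowered for
    speed).  p_ij = (1 + #{|rho_boot| >= |rho_obs|}) / (1 + n_boot), so the
    smallest attainable p is 1/(1 + n_boot).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = table.data if hasattr(table, "data") else table
    if tuple(df.index) != observed.taxon_ids:
        raise ValidationError("observed rho does not match the table's taxa")
    counts = df.to_numpy(dtype=float)
    D, n = counts.shape
    s = observed.settings
    iters = iterations if iterations is not None else s.get("iterations", 50)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed.rho.to_numpy())
    exceed = np.zeros((D, D))
    for _ in range(n_boot):
        resampled = np.empty_like(counts)
        for i in range(D):
            resampled[i] = counts[i, rng.integers(0, n, size=n)]
        if s.get("deterministic"):
            rho_b = _sparcc_single(_draw_fractions(resampled, None),
                                   s["exclusion_rounds"], s["exclusion_threshold"])
        else:
            stack = np.empty((iters, D, D))
            for it in range(iters):
                frac = _draw_fractions(resampled, rng)
                stack[it] = _sparcc_single(frac, s["exclusion_rounds"],
                                           s["exclusion_threshold"])
            rho_b = np.median(stack, axis=0)
        exceed += np.abs(rho_b) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_boot)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0
    ids = observed.taxon_ids
    return CorrelationResult(ids, observed.rho,
                             p=pd.DataFrame(p, index=ids, columns=ids),
                             n_bootstrap=n_boot, settings={**s, "bootstrap_seed": seed})


@dataclass
class CorrelationNetwork:
    """Filtered signed weighted graph over taxa plus its provenance."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "rho": d["weight"],
                 "p": d.get("p", float("nan")),
                 "sign": "positive" if d["weight"] > 0 else "negative"}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])


def build_network(corr: CorrelationResult, r_threshold: float = 0.6,
                  p_threshold: float = 0.05,
                  annotate: TaxonomyTable | None = None) -> CorrelationNetwork:
    """Edges where |rho| > r_threshold and p <= p_threshold; isolated nodes
    dropped; edge sign preserved.  The magnitude reading of the r filter
    keeps negative associations, which the cohesion analysis requires."""
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if corr.p is None:
        raise ValidationError("correlation result carries no p-values")
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    ids = corr.taxon_ids
    g = nx.Graph()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if abs(rho[a, b]) > r_threshold and p[a, b] <= p_threshold:
                g.add_edge(ids[a], ids[b], weight=float(rho[a, b]), p=float(p[a, b]))
    if annotate is not None:
        for node in g.nodes:
            g.nodes[node]["phylum"] = annotate.rank_of(node, "phylum")
    return CorrelationNetwork(g, r_threshold, p_threshold)


@dataclass(frozen=True)
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    mean_degree: float
    average_path_length: float
    diameter: float
    density: float
    clustering_coefficient: float
    modularity: float
    component_coverage: float

    def as_dict(self) -> dict[str, float]:
        return {"n_nodes": self.n_nodes, "n_edges": self.n_edges,
                "mean_degree": self.mean_degree,
                "average_path_length": self.average_path_length,
                "diameter": self.diameter, "density": self.density,
                "clustering_coefficient": self.clustering_coefficient,
                "modularity": self.modularity}


def topology(net: CorrelationNetwork) -> TopologyMetrics:
    """Standard unweighted indices on the undirected simple graph.

    Path length and diameter are computed on the largest connected
    component; ``component_coverage`` reports the node fraction it covers.
    Modularity is that of the greedy-modularity partition (the same
    partition the keystone analysis uses).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    n = g.number_of_nodes()
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    apl = nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
    diam = float(nx.diameter(giant)) if giant.number_of_nodes() > 1 else 0.0
    communities = nx.community.greedy_modularity_communities(g)
    mod = nx.community.modularity(g, communities)
    return TopologyMetrics(
        n_nodes=n, n_edges=g.number_of_edges(),
        mean_degree=2.0 * g.number_of_edges() / n,
        average_path_length=float(apl), diameter=diam,
        density=nx.density(g),
        clustering_coefficient=nx.average_clustering(g),
        modularity=float(mod),
        component_coverage=len(comps[0]) / n)


def topology_distance(metrics: Sequence[TopologyMetrics],
                      labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Euclidean distances between networks in z-scored topology space."""
    if len(metrics) < 2:
        raise ValueError("need at least 2 networks")
    frame = pd.DataFrame([m.as_dict() for m in metrics],
                         index=list(labels) if labels else range(len(metrics)))
    sd = frame.std(ddof=1)
    z = (frame - frame.mean()) / sd.replace(0.0, 1.0)
    X = z.to_numpy()
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(d, index=frame.index, columns=frame.index)


def write_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
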