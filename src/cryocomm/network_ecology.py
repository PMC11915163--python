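"""Module detection, Zi/Pi keystone classification, cohesion, phylum-removal
stability and focal-taxon association on a co-occurrence network.

Keystone rule (inclusive boundaries): module hubs Zi >= 2.5 & Pi < 0.62,
connectors Zi < 2.5 & Pi >= 0.62, network hubs Zi >= 2.5 & Pi >= 0.62;
everything else peripheral.  Cohesion is the abundance-weighted sum of each
taxon's mean positive (resp. negative) qualifying correlation; qualifying
defaults to the correlations behind retained network edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CountTable, TaxonomyTable, ValidationError
from .sparcc_network import CorrelationNetwork, CorrelationResult

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLE_MODULE_HUB = "module_hub"
ROLE_CONNECTOR = "connector"
ROLE_NETWORK_HUB = "network_hub"
ROLE_PERIPHERAL = "peripheral"
KEYSTONE_ROLES = frozenset({ROLE_MODULE_HUB, ROLE_CONNECTOR, ROLE_NETWORK_HUB})


@dataclass(frozen=True)
class ModulePartition:
    assignment: dict[str, int]
    modularity: float

    def members(self, module_id: int) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module_id]


def detect_modules(net: CorrelationNetwork, method: str = "greedy_modularity",
                   seed: int | None = None) -> ModulePartition:
    """Deterministic module partition; greedy modularity maximisation (CNM)
    by default.  The seed argument exists for stochastic methods and is
    ignored by the deterministic default."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    if method != "greedy_modularity":
        raise ValueError(f"unknown method {method!r}")
    communities = nx.community.greedy_modularity_communities(g)
    mod = nx.community.modularity(g, communities)
    assignment = {}
    for mid, members in enumerate(communities):
        for node in sorted(members):
            assignment[node] = mid
    return ModulePartition(assignment, float(mod))


def zi_pi(net: CorrelationNetwork, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    zi = (k_is - mean_s) / sd_s over module s members (zi = 0 when sd is 0);
    pi = 1 - sum_m (k_im / k_i)^2.
    """
    g = net.graph
    missing = [n for n in g.nodes if n not in partition.assignment]
    if missing:
        raise ValidationError(f"partition does not cover nodes: {missing}")
    within = {}  # node -> within-module degree
    among = {}   # node -> {module -> degree into that module}
    for node in g.nodes:
        k_by_mod: dict[int, int] = {}
        for nb in g.neighbors(node):
            m = partition.assignment[nb]
            k_by_mod[m] = k_by_mod.get(m, 0) + 1
        if sum(k_by_mod.values()) == 0:
            raise ValidationError(f"isolated node {node!r} in network")
        within[node] = k_by_mod.get(partition.assignment[node], 0)
        among[node] = k_by_mod
    rows = []
    module_stats = {}
    for mid in set(partition.assignment.values()):
        ks = np.asarray([within[n] for n in g.nodes if partition.assignment[n] == mid],
                        dtype=float)
        module_stats[mid] = (ks.mean(), ks.std(ddof=0)) if len(ks) else (0.0, 0.0)
    for node in g.nodes:
        mid = partition.assignment[node]
        mean_s, sd_s = module_stats[mid]
        zi = 0.0 if sd_s == 0 else (within[node] - mean_s) / sd_s
        k_total = sum(among[node].values())
        pi = 1.0 - sum((k / k_total) ** 2 for k in among[node].values())
        rows.append({"node": node, "module": mid, "degree": k_total,
                     "zi": float(zi), "pi": float(pi)})
    return pd.DataFrame(rows).set_index("node")


def classify_role(zi: float, pi: float, zi_threshold: float = ZI_THRESHOLD,
                  pi_threshold: float = PI_THRESHOLD) -> str:
    if zi >= zi_threshold and pi >= pi_threshold:
        return ROLE_NETWORK_HUB
    if zi >= zi_threshold:
        return ROLE_MODULE_HUB
    if pi >= pi_threshold:
        return ROLE_CONNECTOR
    return ROLE_PERIPHERAL


def classify_keystones(roles: pd.DataFrame, zi_threshold: float = ZI_THRESHOLD,
                       pi_threshold: float = PI_THRESHOLD) -> pd.DataFrame:
    """Attach role labels; keystone = module hub, connector or network hub."""
    out = roles.copy()
    out["role"] = [classify_role(z, p, zi_threshold, pi_threshold)
                   for z, p in zip(out["zi"], out["pi"])]
    out["keystone"] = out["role"].isin(KEYSTONE_ROLES)
    return out


@dataclass(frozen=True)
class CohesionResult:
    positive: pd.Series   # per-sample C+ >= 0
    negative: pd.Series   # per-sample C- <= 0
    mean_positive_corr: pd.Series  # per-taxon r-bar+
    mean_negative_corr: pd.Series  # per-taxon r-bar-


def null_corrected_pearson(rel: np.ndarray, n_null: int = 199,
                           seed: int | None = 0) -> np.ndarray:
    """Taxon-shuffle-corrected Pearson correlations of relative abundances.

    Observed correlations minus the mean correlation under independent
    permutation of each taxon's abundances across samples — the original
    cohesion method's way of removing correlation expected from abundance
    distributions alone.
    """
    rng = np.random.default_rng(seed)
    obs = np.corrcoef(rel)
    null_sum = np.zeros_like(obs)
    n = rel.shape[1]
    for _ in range(n_null):
        shuffled = np.take_along_axis(
            rel, np.argsort(rng.random((rel.shape[0], n)), axis=1), axis=1)
        null_sum += np.corrcoef(shuffled)
    corrected = obs - null_sum / n_null
    np.fill_diagonal(corrected, 0.0)
    return corrected


def _qualifying_matrix(corr: CorrelationResult, taxa: Sequence[str],
                       qualify: str, r_threshold: float, p_threshold: float,
                       net: CorrelationNetwork | None) -> np.ndarray:
    """Correlation matrix restricted to qualifying pairs (others zeroed)."""
    R = corr.rho.loc[list(taxa), list(taxa)].to_numpy().copy()
    np.fill_diagonal(R, 0.0)
    if qualify == "all":
        return R
    if qualify == "network_edges":
        if net is not None:
            mask = np.zeros_like(R, dtype=bool)
            pos = {t: i for i, t in enumerate(taxa)}
            for u, v in net.graph.edges:
                if u in pos and v in pos:
                    mask[pos[u], pos[v]] = mask[pos[v], pos[u]] = True
        else:
            if corr.p is None:
                raise ValidationError("network_edges mode needs p-values or a network")
            P = corr.p.loc[list(taxa), list(taxa)].to_numpy()
            mask = (np.abs(R) > r_threshold) & (P <= p_threshold)
        return np.where(mask, R, 0.0)
    raise ValueError(f"unknown qualify mode {qualify!r}")


def cohesion(rel_abundance: CountTable, corr: CorrelationResult | None,
             qualify: str = "network_edges", r_threshold: float = 0.6,
             p_threshold: float = 0.05,
             net: CorrelationNetwork | None = None,
             n_null: int = 199, seed: int | None = 0) -> CohesionResult:
    """Per-sample positive and negative cohesion.

    r-bar+_i is the mean of taxon i's qualifying positive correlations
    (0 when there are none), r-bar-_i analogous over negatives; then per
    sample C+ = sum_i p_i * r-bar+_i and C- = sum_i p_i * r-bar-_i with p
    the relative abundances.  Qualifying correlations default to the
    SparCC-network edges; ``qualify="all"`` uses the full matrix and
    ``qualify="pearson_null"`` the original null-corrected Pearson variant
    computed from the abundance table itself (``corr`` may be None then).
    """
    if rel_abundance.unit != "relative_fraction":
        raise ValidationError("cohesion needs a relative_fraction table")
    if qualify == "pearson_null":
        taxa = rel_abundance.taxon_ids
        Q = null_corrected_pearson(rel_abundance.data.to_numpy(), n_null, seed)
    else:
        if corr is None:
            raise ValidationError(f"qualify={qualify!r} needs a correlation result")
        taxa = [t for t in rel_abundance.taxon_ids if t in set(corr.taxon_ids)]
        if len(taxa) != len(rel_abundance.taxon_ids):
            raise ValidationError("table taxa must all appear in the correlation result")
        Q = _qualifying_matrix(corr, taxa, qualify, r_threshold, p_threshold, net)
    pos_counts = (Q > 0).sum(axis=1)
    neg_counts = (Q < 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rbar_pos = np.where(pos_counts > 0, np.where(Q > 0, Q, 0.0).sum(axis=1)
                            / np.maximum(pos_counts, 1), 0.0)
        rbar_neg = np.where(neg_counts > 0, np.where(Q < 0, Q, 0.0).sum(axis=1)
                            / np.maximum(neg_counts, 1), 0.0)
    P = rel_abundance.data.loc[taxa].to_numpy()
    c_pos = P.T @ rbar_pos
    c_neg = P.T @ rbar_neg
    samples = rel_abundance.sample_ids
    return CohesionResult(
        positive=pd.Series(c_pos, index=samples, name="positive_cohesion"),
        negative=pd.Series(c_neg, index=samples, name="negative_cohesion"),
        mean_positive_corr=pd.Series(rbar_pos, index=taxa),
        mean_negative_corr=pd.Series(rbar_neg, index=taxa))


@dataclass(frozen=True)
class RemovalTrajectory:
    phylum: str
    fractions: tuple[float, ...]
    mean_positive: tuple[float, ...]   # mean over reps & samples of C+
    mean_negative: tuple[float, ...]
    positive_slope: float
    negative_slope: float
    n_reps: int
    seed: int | None


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return float("nan")
    return float((xc @ (y - y.mean())) / denom)


def removal_stability(rel_abundance: CountTable, corr: CorrelationResult,
                      tax: TaxonomyTable, phylum: str,
                      fractions: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 2)),
                      n_reps: int = 100, seed: int | None = 0,
                      qualify: str = "network_edges", r_threshold: float = 0.6,
                      p_threshold: float = 0.05,
                      net: CorrelationNetwork | None = None) -> RemovalTrajectory:
    """Random-removal cohesion trajectory for one phylum.

    Per replicate a uniform subset of the phylum's taxa of the given
    fraction is deleted, remaining relative abundances are renormalised,
    cohesion is recomputed on the remaining taxa, and the slope is the OLS
    fit of mean cohesion on removal fraction.  Fraction 0 reproduces the
    unperturbed cohesion exactly; fraction 1 equals recomputation with the
    phylum absent.
    """
    members = [t for t in rel_abundance.taxon_ids
               if tax.rank_of(t, "phylum") == phylum]
    if not members:
        raise ValidationError(f"phylum {phylum!r} has no taxa in the table")
    rng = np.random.default_rng(seed)
    all_taxa = rel_abundance.taxon_ids

    def cohesion_without(removed: set[str]) -> tuple[float, float]:
        keep = [t for t in all_taxa if t not in removed]
        sub = rel_abundance.data.loc[keep]
        sums = sub.sum(axis=0)
        if (sums <= 0).any():
            return float("nan"), float("nan")
        rel = CountTable(data=sub / sums, unit="relative_fraction")
        sub_corr = CorrelationResult(
            tuple(keep), corr.rho.loc[keep, keep],
            corr.p.loc[keep, keep] if corr.p is not None else None,
            corr.n_bootstrap, corr.settings)
        res = cohesion(rel, sub_corr, qualify, r_threshold, p_threshold, net)
        return float(res.positive.mean()), float(res.negative.mean())

    mean_pos, mean_neg = [], []
    for frac in fractions:
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        k = int(round(frac * len(members)))
        if k == 0:
            p, n = cohesion_without(set())
            mean_pos.append(p)
            mean_neg.append(n)
            continue
        if k == len(members):
            p, n = cohesion_without(set(members))
            mean_pos.append(p)
            mean_neg.append(n)
            continue
        acc_p, acc_n = [], []
        for _ in range(n_reps):
            removed = set(rng.choice(members, size=k, replace=False))
            p, n = cohesion_without(removed)
            acc_p.append(p)
            acc_n.append(n)
        mean_pos.append(float(np.nanmean(acc_p)))
        mean_neg.append(float(np.nanmean(acc_n)))
    fr = np.asarray(fractions, dtype=float)
    return RemovalTrajectory(
        phylum=phylum, fractions=tuple(fr), mean_positive=tuple(mean_pos),
        mean_negative=tuple(mean_neg),
        positive_slope=_ols_slope(fr, np.asarray(mean_pos)),
        negative_slope=_ols_slope(fr, np.asarray(mean_neg)),
        n_reps=n_reps, seed=seed)


@dataclass(frozen=True)
class FocalAssociation:
    node_class: pd.Series            # per non-focal node: positive/negative/none
    fractions: pd.DataFrame          # per period (or 'all'): class abundance fractions
    phylum_breakdown: pd.DataFrame | None


def focal_association(net: CorrelationNetwork, corr: CorrelationResult,
                      focal_taxa: Sequence[str], abs_abundance: CountTable,
                      meta=None, tax: TaxonomyTable | None = None) -> FocalAssociation:
    """Classify every non-focal taxon by its summed edge weight to the focal
    set: positive / negative when connected, none otherwise (including taxa
    outside the network).  A multi-edge weight sum of exactly 0 classifies
    as positive (documented tie-break; probability-zero with continuous
    weights).  Fractions are abundance-weighted per period and, together
    with the focal phylum's own share, partition the community.
    """
    focal = [t for t in focal_taxa if t in set(abs_abundance.taxon_ids)]
    if not focal:
        raise ValidationError("focal taxa do not appear in the abundance table")
    g = net.graph
    classes = {}
    for taxon in abs_abundance.taxon_ids:
        if taxon in set(focal):
            continue
        if taxon in g:
            wsum = sum(d["weight"] for _, v, d in g.edges(taxon, data=True)
                       if v in set(focal))
            has_edge = any(v in set(focal) for v in g.neighbors(taxon))
            classes[taxon] = ("positive" if wsum >= 0 else "negative") if has_edge else "none"
        else:
            classes[taxon] = "none"
    node_class = pd.Series(classes, name="focal_class")

    groups = {s: (meta.period_of(s) if meta is not None else "all")
              for s in abs_abundance.sample_ids}
    rows = {}
    df = abs_abundance.data
    for period in dict.fromkeys(groups.values()):
        samples = [s for s, p in groups.items() if p == period]
        totals = df[samples].sum(axis=1)
        grand = totals.sum()
        if grand <= 0:
            raise ValidationError(f"no abundance in period {period!r}")
        row = {"focal": float(totals.loc[focal].sum() / grand)}
        for cls in ("positive", "negative", "none"):
            members = node_class.index[node_class == cls]
            row[cls] = float(totals.loc[members].sum() / grand)
        rows[period] = row
    fractions = pd.DataFrame(rows).T

    breakdown = None
    if tax is not None:
        recs = []
        for taxon, cls in node_class.items():
            recs.append({"phylum": tax.rank_of(taxon, "phylum"), "class": cls})
        breakdown = (pd.DataFrame(recs).groupby(["phylum", "class"]).size()
                     .unstack(fill_value=0))
    return FocalAssociation(node_class, fractions, breakdown)
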