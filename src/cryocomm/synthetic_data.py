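"""Synthetic glacier-surface community generator with known ground truth.

Every downstream stage of the pipeline (SparCC, cohesion/keystone analysis,
phylogenetic null models, multifunctionality) is validated against data from
this generator, which emulates the study design the pipeline targets: two
marker-gene communities (prokaryote 16S, eukaryote 18S) sampled over three
periods (accumulation, melt, late melt) with ten samples per period, a focal
phylum (Cyanobacteria) whose absolute abundance rises sharply across
periods, a keystone phylum with dense planted positive intra-correlations,
optional phylogenetic environmental filtering, and an enzyme table with a
planted linear association to focal-phylum abundance.

Model: per sample, latent log-abundances are multivariate normal with a
correlation matrix embedding the planted pairs (a Gaussian copula on the
log scale); observed counts are a multinomial draw of the per-sample softmax
composition at the configured sequencing depth.  This is deliberately the
compositional-distortion regime SparCC is designed for.  All randomness
derives from a single seed through numpy SeedSequence spawning, one child
stream per component, so a fixed config is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (CountTable, QpcrTable, SampleMetadata, TaxonomyTable, RANKS,
                      write_count_table, write_metadata, write_qpcr, write_taxonomy)
from .phylo_metrics import Phylogeny

DEFAULT_PERIODS = ("accumulation", "melt", "late_melt")

# Phylum labels assigned round-robin to non-focal, non-keystone taxa.
PROK_BACKGROUND_PHYLA = ("Actinobacteriota", "Bacteroidota", "Chloroflexi", "Deinococcota")
EUK_PHYLA = ("Chlorophyta", "Ciliophora", "Cercozoa")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic community.

    Defaults mirror the emulated design: 3 periods x 10 samples, ~5e4
    reads/sample, a cyanobacterial focal phylum whose latent abundance and
    the community's total 16S copy number both rise over the season.
    """

    n_taxa_prok: int = 60
    n_taxa_euk: int = 30
    n_samples_per_period: int = 10
    periods: tuple[str, ...] = DEFAULT_PERIODS
    seed: int = 0
    # (taxon_id_i, taxon_id_j, basis correlation) planted pairs
    correlation_spec: tuple[tuple[str, str, float], ...] = ()
    focal_phylum: str = "Cyanobacteria"
    n_taxa_focal: int = 8
    # multiplicative shift of the focal phylum's latent mean abundance per period
    focal_period_multipliers: tuple[float, ...] = (1.0, 8.0, 25.0)
    keystone_phylum: str | None = None
    n_taxa_keystone: int = 8
    keystone_rho: float = 0.75
    keystone_cross_rho: float = 0.0
    filtering_strength: float = float("inf")  # sigma_env; inf = no filtering
    period_optima: tuple[float, ...] = (-1.5, 0.0, 1.5)
    function_effect: float = 0.0  # beta linking focal abundance to enzymes
    function_noise: float = 1.0
    n_enzymes: int = 39
    sequencing_depth: int = 50_000
    latent_sd: float = 1.0
    qpcr_base_16s: float = 2.0e8
    qpcr_base_18s: float = 2.0e7
    qpcr_period_multipliers: tuple[float, ...] = (1.0, 4.0, 10.0)
    qpcr_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.n_taxa_prok < 4 or self.n_taxa_euk < 2:
            raise ValueError("need at least 4 prokaryote and 2 eukaryote taxa")
        if len(self.focal_period_multipliers) != len(self.periods):
            raise ValueError("one focal multiplier per period required")
        if len(self.qpcr_period_multipliers) != len(self.periods):
            raise ValueError("one qPCR multiplier per period required")
        if self.filtering_strength <= 0:
            raise ValueError("filtering_strength (sigma_env) must be positive; use inf to disable")
        for i, j, rho in self.correlation_spec:
            if not -1 < rho < 1:
                raise ValueError(f"basis correlation for ({i},{j}) must be in (-1,1)")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{p}_{k + 1:02d}" for p in self.periods
                for k in range(self.n_samples_per_period)]

    @property
    def prok_ids(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_taxa_prok)]

    @property
    def euk_ids(self) -> list[str]:
        return [f"E{i + 1:04d}" for i in range(self.n_taxa_euk)]


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    basis_correlation_prok: pd.DataFrame
    basis_correlation_euk: pd.DataFrame
    traits: pd.Series  # Brownian trait per taxon (empty when filtering off)
    focal_taxa: list[str]
    keystone_taxa: list[str]
    focal_absolute_mean: pd.Series  # per-period expected focal copies/mL
    function_beta: float
    function_alpha: pd.Series | None = None


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_phylogeny(n_taxa: int, seed: int, taxon_ids: Sequence[str] | None = None,
                       birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree: exponential waiting times, uniform splits.

    Returns a rooted binary tree with strictly positive branch lengths whose
    tips are labeled ``taxon_ids`` (default t1..tn, assigned in a
    seed-determined order).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    ids = list(taxon_ids) if taxon_ids is not None else [f"t{i + 1}" for i in range(n_taxa)]
    if len(ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")

    # nodes as [children, branch_length]
    root = {"children": [], "length": None}
    a = {"children": [], "length": 0.0}
    b = {"children": [], "length": 0.0}
    root["children"] = [a, b]
    active = [a, b]
    while True:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node["length"] += wait
        if len(active) == n_taxa:
            break
        pick = int(rng.integers(len(active)))
        parent = active.pop(pick)
        c1 = {"children": [], "length": 0.0}
        c2 = {"children": [], "length": 0.0}
        parent["children"] = [c1, c2]
        active.extend([c1, c2])
    order = rng.permutation(n_taxa)
    for node, k in zip(active, order):
        node["name"] = ids[int(k)]

    def to_newick(node) -> str:
        if not node["children"]:
            return f"{node['name']}:{node['length']:.10f}"
        inner = ",".join(to_newick(c) for c in node["children"])
        length = "" if node["length"] is None else f":{node['length']:.10f}"
        return f"({inner}){length}"

    return Phylogeny.from_newick(to_newick(root) + ";")


def _embed_correlations(ids: Sequence[str], planted: Sequence[tuple[str, str, float]],
                        blocks: Mapping[str, Sequence[str]] | None = None,
                        block_rho: float = 0.0) -> pd.DataFrame:
    """Identity-based correlation matrix with planted pairs and optional
    dense within-block correlations; errors if not positive definite."""
    pos = {t: i for i, t in enumerate(ids)}
    R = np.eye(len(ids))
    if blocks:
        for members in blocks.values():
            idx = [pos[m] for m in members]
            for a in idx:
                for b in idx:
                    if a != b:
                        R[a, b] = block_rho
    for i, j, rho in planted:
        if i not in pos or j not in pos:
            raise ValueError(f"planted pair ({i},{j}) not among taxa")
        R[pos[i], pos[j]] = R[pos[j], pos[i]] = rho
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin <= 1e-10:
        raise ValueError(
            f"correlation_spec is not embeddable in a positive-definite matrix "
            f"(min eigenvalue {eigmin:.3g}); shrink the planted correlations")
    return pd.DataFrame(R, index=list(ids), columns=list(ids))


def _brownian_traits(phylo: Phylogeny, rng: np.random.Generator) -> pd.Series:
    """Brownian-motion trait: independent normal increments along branches."""
    vals: dict[int, float] = {id(phylo.tree): 0.0}
    out = {}
    for node in phylo.tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(max(node.length or 0.0, 1e-12)))
        vals[id(node)] = vals[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = vals[id(node)]
    s = pd.Series(out, dtype=float)
    sd = s.std(ddof=1)
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


def _phylum_assignment(cfg: SimulationConfig) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Taxonomy for all taxa; returns (lineage frame, focal taxa, keystone taxa)."""
    rows = {}
    prok = cfg.prok_ids
    focal = prok[: cfg.n_taxa_focal]
    key_start = cfg.n_taxa_focal
    keystone: list[str] = []
    if cfg.keystone_phylum and cfg.keystone_phylum != cfg.focal_phylum:
        keystone = prok[key_start: key_start + cfg.n_taxa_keystone]
    elif cfg.keystone_phylum == cfg.focal_phylum:
        keystone = list(focal)
    rest = [t for t in prok if t not in set(focal) | set(keystone)]
    for t in focal:
        rows[t] = ("Bacteria", cfg.focal_phylum)
    for t in keystone:
        if t not in rows:
            rows[t] = ("Bacteria", cfg.keystone_phylum)
    for k, t in enumerate(rest):
        rows[t] = ("Bacteria", PROK_BACKGROUND_PHYLA[k % len(PROK_BACKGROUND_PHYLA)])
    for k, t in enumerate(cfg.euk_ids):
        rows[t] = ("Eukaryota", EUK_PHYLA[k % len(EUK_PHYLA)])
    frame = pd.DataFrame(
        [(dom, phy, f"{phy}_c", f"{phy}_o", f"{phy}_f", f"{phy}_g")
         for dom, phy in rows.values()],
        index=list(rows), columns=list(RANKS))
    return frame, focal, keystone


def simulate_communities(cfg: SimulationConfig, tree: Phylogeny
                         ) -> tuple[CountTable, CountTable, QpcrTable, SampleMetadata,
                                    TaxonomyTable, GroundTruth]:
    """Generate the full synthetic study from one config and one tree.

    The tree's tips must cover all prokaryote and eukaryote taxon ids.
    Returns (prok counts, euk counts, qPCR table, metadata, taxonomy,
    ground truth).
    """
    all_ids = cfg.prok_ids + cfg.euk_ids
    missing = set(all_ids) - set(tree.tip_names)
    if missing:
        raise ValueError(f"tree tips missing taxa: {sorted(missing)[:5]}...")

    (rng_corr, rng_trait, rng_latent_p, rng_latent_e, rng_counts_p, rng_counts_e,
     rng_qpcr) = _rngs(cfg.seed, 7)

    lineages, focal, keystone = _phylum_assignment(cfg)
    tax = TaxonomyTable(lineages=lineages)

    blocks = {"keystone": keystone} if keystone else None
    planted_p = [(i, j, r) for i, j, r in cfg.correlation_spec
                 if i in set(cfg.prok_ids) and j in set(cfg.prok_ids)]
    planted_e = [(i, j, r) for i, j, r in cfg.correlation_spec
                 if i in set(cfg.euk_ids) and j in set(cfg.euk_ids)]
    R_p = _embed_correlations(cfg.prok_ids, planted_p, blocks, cfg.keystone_rho)
    R_e = _embed_correlations(cfg.euk_ids, planted_e)

    traits = (_brownian_traits(tree, rng_trait) if np.isfinite(cfg.filtering_strength)
              else pd.Series(dtype=float))

    meta = SampleMetadata(
        periods=pd.Series({s: s.rsplit("_", 1)[0] for s in cfg.sample_ids}),
        period_order=cfg.periods)

    def latent_block(ids: list[str], R: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        L = np.linalg.cholesky(R.to_numpy())
        n = len(cfg.sample_ids)
        z = rng.standard_normal((len(ids), n))
        lat = cfg.latent_sd * (L @ z)
        # period-dependent mean shifts
        mu = np.zeros((len(ids), n))
        for pi, period in enumerate(cfg.periods):
            cols = [k for k, s in enumerate(cfg.sample_ids)
                    if meta.period_of(s) == period]
            shift = np.zeros(len(ids))
            for ti, t in enumerate(ids):
                if t in set(focal):
                    shift[ti] += np.log(cfg.focal_period_multipliers[pi])
                if np.isfinite(cfg.filtering_strength) and t in traits.index:
                    shift[ti] -= ((traits[t] - cfg.period_optima[pi]) ** 2
                                  / (2.0 * cfg.filtering_strength ** 2))
            mu[:, cols] += shift[:, None]
        return pd.DataFrame(lat + mu, index=ids, columns=cfg.sample_ids)

    def draw_counts(latent: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        lam = np.exp(latent.to_numpy() - latent.to_numpy().max(axis=0))
        frac = lam / lam.sum(axis=0)
        counts = np.empty_like(frac, dtype=np.int64)
        for k in range(frac.shape[1]):
            depth = rng.poisson(cfg.sequencing_depth)
            counts[:, k] = rng.multinomial(depth, frac[:, k])
        return pd.DataFrame(counts.astype(float), index=latent.index, columns=latent.columns)

    lat_p = latent_block(cfg.prok_ids, R_p, rng_latent_p)
    lat_e = latent_block(cfg.euk_ids, R_e, rng_latent_e)
    prok = CountTable(data=draw_counts(lat_p, rng_counts_p), unit="reads")
    euk = CountTable(data=draw_counts(lat_e, rng_counts_e), unit="reads")

    q16, q18 = [], []
    for s in cfg.sample_ids:
        pi = cfg.periods.index(meta.period_of(s))
        mult = cfg.qpcr_period_multipliers[pi]
        q16.append(cfg.qpcr_base_16s * mult * np.exp(rng_qpcr.normal(0, cfg.qpcr_sigma)))
        q18.append(cfg.qpcr_base_18s * np.exp(rng_qpcr.normal(0, cfg.qpcr_sigma)))
    qpcr = QpcrTable(copies=pd.DataFrame(
        {"marker_16S": q16, "marker_18S": q18}, index=cfg.sample_ids))

    # expected focal copies/mL per period (planted trend, for recovery tests)
    frac_focal = np.exp(lat_p.loc[focal]).sum(axis=0) / np.exp(lat_p).sum(axis=0)
    focal_abs = pd.Series(
        {p: float((frac_focal[meta.samples_in(p)]
                   * qpcr.copies.loc[meta.samples_in(p), "marker_16S"]).mean())
         for p in cfg.periods})

    truth = GroundTruth(basis_correlation_prok=R_p, basis_correlation_euk=R_e,
                        traits=traits, focal_taxa=list(focal), keystone_taxa=list(keystone),
                        focal_absolute_mean=focal_abs, function_beta=cfg.function_effect)
    return prok, euk, qpcr, meta, tax, truth


def simulate_function_table(focal_abundance: pd.Series, n_enzymes: int = 39,
                            beta: float = 0.0, noise: float = 1.0,
                            seed: int = 0,
                            enzyme_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Enzyme x sample abundances with a planted linear link to the focal
    phylum: value = alpha_e + beta * z(focal) + N(0, noise), shifted to be
    non-negative."""
    if beta < 0 or noise < 0:
        raise ValueError("beta and noise must be non-negative")
    rng = np.random.default_rng(seed)
    ids = list(enzyme_ids) if enzyme_ids is not None else \
        [f"EC:N{i + 1:02d}" for i in range(n_enzymes)]
    x = focal_abundance.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    z = (x - x.mean()) / (sd if sd > 0 else 1.0)
    alpha = rng.uniform(5.0, 10.0, size=len(ids))
    vals = alpha[:, None] + beta * z[None, :] + rng.normal(0, noise, (len(ids), len(x)))
    if vals.min() < 0:
        vals = vals - vals.min()
    return pd.DataFrame(vals, index=ids, columns=list(focal_abundance.index))


def beta_for_target_r2(target_r2: float, noise: float = 1.0, n_enzymes: int = 39) -> float:
    """Planted effect size giving a population R^2 of the multifunctionality
    index regressed on focal abundance.

    After per-enzyme z-scoring, the index is approximately
    (beta*z + mean noise)/sqrt(beta^2 + noise^2), so
    R^2 = beta^2 / (beta^2 + noise^2/E).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0,1)")
    return noise * np.sqrt(target_r2 / ((1.0 - target_r2) * n_enzymes))


def write_study(directory: str | Path, cfg: SimulationConfig) -> dict[str, Path]:
    """Materialize a full synthetic study directory in the formats the
    readers consume.  Returns the path of every file written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree = simulate_phylogeny(cfg.n_taxa_prok + cfg.n_taxa_euk,
                              seed=cfg.seed, taxon_ids=cfg.prok_ids + cfg.euk_ids)
    prok, euk, qpcr, meta, tax, truth = simulate_communities(cfg, tree)
    fn = simulate_function_table(
        prok.data.loc[truth.focal_taxa].sum(axis=0), n_enzymes=cfg.n_enzymes,
        beta=cfg.function_effect, noise=cfg.function_noise, seed=cfg.seed + 1)
    paths = {
        "counts_16s": directory / "counts_16s.tsv",
        "counts_18s": directory / "counts_18s.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "qpcr": directory / "qpcr.tsv",
        "metadata": directory / "metadata.tsv",
        "tree": directory / "tree.nwk",
        "functions": directory / "functions.tsv",
    }
    write_count_table(prok, paths["counts_16s"])
    write_count_table(euk, paths["counts_18s"])
    write_taxonomy(tax, paths["taxonomy"])
    write_qpcr(qpcr, paths["qpcr"])
    write_metadata(meta, paths["metadata"])
    tree.to_newick(paths["tree"])
    fn.rename_axis("enzyme").to_csv(paths["functions"], sep="\t")
    return paths
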