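"""Phylogenetic community structure metrics.

Implements Faith's phylogenetic diversity, the Helmus phylogenetic-species
family (PSV, PSC, PSR, PSE), mean pairwise / nearest-taxon distances with
their standardized effect sizes (NRI, NTI), and between-community beta-MNTD
with a tip-shuffle null (betaNTI).  All metrics are computed from first
principles on a rooted tree with branch lengths; nothing here assumes
ultrametricity.

Sign convention: NRI and NTI are the *negated* z-scores of MPD and MNTD, so
positive values indicate phylogenetic clustering (observed distances smaller
than the null expectation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths plus cached derived matrices.

    ``patristic`` is the tip-to-tip path-length matrix; ``correlation`` is
    the phylogenetic correlation matrix C (shared branch length from the
    root between two tips, scaled to unit diagonal).  Both are computed once
    on first access and cached.
    """

    tree: TreeNode
    _tips: tuple[str, ...] | None = field(default=None, repr=False)
    _patristic: pd.DataFrame | None = field(default=None, repr=False)
    _depths: pd.Series | None = field(default=None, repr=False)
    _corr: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and not source.rstrip().endswith(";")):
            tree = TreeNode.read(str(source), convert_underscores=False)
        else:
            tree = TreeNode.read(io.StringIO(str(source)), convert_underscores=False)
        return cls(tree=tree)

    def to_newick(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        nwk = buf.getvalue()
        if path is not None:
            Path(path).write_text(nwk)
        return nwk

    @property
    def tip_names(self) -> tuple[str, ...]:
        if self._tips is None:
            self._tips = tuple(t.name for t in self.tree.tips())
        return self._tips

    @property
    def patristic(self) -> pd.DataFrame:
        if self._patristic is None:
            dm = self.tree.tip_tip_distances()
            self._patristic = pd.DataFrame(np.asarray(dm.data, dtype=float),
                                           index=list(dm.ids), columns=list(dm.ids))
        return self._patristic

    @property
    def depths(self) -> pd.Series:
        """Root-to-tip path lengths."""
        if self._depths is None:
            out = {}
            for tip in self.tree.tips():
                d, node = 0.0, tip
                while node.parent is not None:
                    d += node.length or 0.0
                    node = node.parent
                out[tip.name] = d
            self._depths = pd.Series(out, dtype=float)
        return self._depths

    @property
    def correlation(self) -> pd.DataFrame:
        """Phylogenetic correlation C: shared root-path length, unit diagonal.

        Shared branch length V_ij = (depth_i + depth_j - d_ij)/2, then
        C_ij = V_ij / sqrt(V_ii * V_jj).
        """
        if self._corr is None:
            d = self.patristic
            ids = list(d.index)
            dep = self.depths.loc[ids].to_numpy()
            V = (dep[:, None] + dep[None, :] - d.to_numpy()) / 2.0
            diag = np.sqrt(np.clip(np.diag(V), 1e-300, None))
            C = V / np.outer(diag, diag)
            np.fill_diagonal(C, 1.0)
            self._corr = pd.DataFrame(C, index=ids, columns=ids)
        return self._corr


def faith_pd(phylo: Phylogeny, present: Iterable[str], include_root: bool = True) -> float:
    """Faith's PD: total branch length of the minimal subtree spanning the
    present tips.  With ``include_root`` (default) the path up to the root is
    included even for a single tip, so PD(single tip) is its root-to-tip
    distance.  Empty set returns 0.0.
    """
    present = set(present)
    if not present:
        return 0.0
    tips = set(phylo.tip_names)
    missing = present - tips
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    total = 0.0
    # Post-order marking: a branch counts if any present tip is below it.
    marked: dict[int, bool] = {}
    for node in phylo.tree.postorder():
        if node.is_tip():
            has = node.name in present
        else:
            has = any(marked[id(ch)] for ch in node.children)
        marked[id(node)] = has
        if has and node.parent is not None:
            total += node.length or 0.0
    if not include_root:
        # Subtract the exclusive path from the MRCA of the present set up to
        # the root (branches with *all* present tips below them, above MRCA).
        names = list(present)
        mrca = phylo.tree.lca([phylo.tree.find(n) for n in names]) if len(names) > 1 \
            else phylo.tree.find(names[0])
        node = mrca
        while node.parent is not None:
            total -= node.length or 0.0
            node = node.parent
    return total


@dataclass(frozen=True)
class PsvFamily:
    psv: float
    psr: float
    psc: float
    pse: float


def psv_family(phylo: Phylogeny, community: Sequence[str],
               abundances: Mapping[str, float] | None = None) -> PsvFamily:
    """Helmus phylogenetic-species metrics on the community submatrix of C.

    PSV = (n·tr(C) - ΣC) / (n(n-1)); PSR = n·PSV;
    PSC = 1 - mean over taxa of the largest off-diagonal C entry;
    PSE = abundance-weighted PSV (reduces to PSV at equal abundances).
    Communities with fewer than 2 taxa return NaN for all four.
    """
    taxa = list(dict.fromkeys(community))
    n = len(taxa)
    if n < 2:
        return PsvFamily(float("nan"), float("nan"), float("nan"), float("nan"))
    C = phylo.correlation.loc[taxa, taxa].to_numpy()
    psv = (n * np.trace(C) - C.sum()) / (n * (n - 1))
    psr = n * psv
    off = C - np.eye(n) * 2.0  # push diagonal below any off-diagonal value
    psc = 1.0 - float(np.mean(off.max(axis=1)))
    if abundances is None:
        pse = psv
    else:
        m = np.asarray([float(abundances[t]) for t in taxa])
        if (m < 0).any() or m.sum() <= 0:
            raise ValueError("abundances must be non-negative with positive sum")
        M = m.sum()
        num = M * float(m @ np.diag(C)) - float(m @ C @ m)
        den = M * M - M * (M / n)  # N^2 (1 - 1/n); equals n^2 - n at unit abundances
        pse = num / den if den > 0 else float("nan")
    return PsvFamily(float(psv), float(psr), float(psc), float(pse))


def mpd_mntd(dist: np.ndarray) -> tuple[float, float]:
    """Mean pairwise and mean nearest-taxon distance of a community
    patristic submatrix (n >= 2)."""
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    mpd = float(dist[iu].mean())
    masked = dist + np.diag(np.full(n, np.inf))
    mntd = float(masked.min(axis=1).mean())
    return mpd, mntd


@dataclass(frozen=True)
class SesResult:
    nri: float
    nti: float
    mpd: float
    mntd: float
    n_null: int


def nri_nti(phylo: Phylogeny, community: Sequence[str], pool: Sequence[str] | None = None,
            n_null: int = 999, seed: int | np.random.Generator | None = None) -> SesResult:
    """NRI / NTI against a tip-label-shuffle null.

    Shuffling tip labels across the pool is equivalent to drawing a random
    same-size subset of the pool, which is how the null is sampled here.
    Positive values indicate clustering.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taxa = list(dict.fromkeys(community))
    if len(taxa) < 2:
        raise ValueError("community must have at least 2 taxa")
    pool = list(pool) if pool is not None else list(phylo.tip_names)
    D = phylo.patristic.loc[pool, pool].to_numpy()
    idx = np.asarray([pool.index(t) for t in taxa])
    mpd_obs, mntd_obs = mpd_mntd(D[np.ix_(idx, idx)])
    null_mpd = np.empty(n_null)
    null_mntd = np.empty(n_null)
    k = len(idx)
    for b in range(n_null):
        sub = rng.choice(len(pool), size=k, replace=False)
        null_mpd[b], null_mntd[b] = mpd_mntd(D[np.ix_(sub, sub)])
    sd_mpd, sd_mntd = null_mpd.std(ddof=1), null_mntd.std(ddof=1)
    nri = float("nan") if sd_mpd == 0 else -(mpd_obs - null_mpd.mean()) / sd_mpd
    nti = float("nan") if sd_mntd == 0 else -(mntd_obs - null_mntd.mean()) / sd_mntd
    return SesResult(float(nri), float(nti), mpd_obs, mntd_obs, n_null)


def _beta_mntd(D: np.ndarray, ia: np.ndarray, ib: np.ndarray,
               wa: np.ndarray, wb: np.ndarray) -> float:
    sub = D[np.ix_(ia, ib)]
    return 0.5 * (float(wa @ sub.min(axis=1)) + float(wb @ sub.min(axis=0)))


@dataclass(frozen=True)
class BetaNtiResult:
    beta_mntd: float
    null_mean: float
    null_sd: float
    beta_nti: float
    n_null: int


def beta_nti(phylo: Phylogeny, abund_a: Mapping[str, float], abund_b: Mapping[str, float],
             weighted: bool = True, pool: Sequence[str] | None = None,
             n_null: int = 999, seed: int | np.random.Generator | None = None) -> BetaNtiResult:
    """betaNTI: standardized deviation of between-community beta-MNTD from a
    tip-shuffle null.

    beta-MNTD is the (optionally abundance-weighted) mean distance of each
    taxon to its nearest taxon in the other community, averaged over the two
    directions.  The null shuffles tip labels across the pool (999 reps by
    default) and betaNTI = (obs - null mean) / null sd.  |betaNTI| > 2 is
    conventionally read as deterministic assembly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ta = [t for t, v in abund_a.items() if v > 0]
    tb = [t for t, v in abund_b.items() if v > 0]
    if not ta or not tb:
        raise ValueError("both communities must be non-empty")
    pool = list(pool) if pool is not None else list(phylo.tip_names)
    pos = {t: i for i, t in enumerate(pool)}
    D = phylo.patristic.loc[pool, pool].to_numpy()
    ia = np.asarray([pos[t] for t in ta])
    ib = np.asarray([pos[t] for t in tb])
    if weighted:
        wa = np.asarray([float(abund_a[t]) for t in ta]); wa = wa / wa.sum()
        wb = np.asarray([float(abund_b[t]) for t in tb]); wb = wb / wb.sum()
    else:
        wa = np.full(len(ta), 1.0 / len(ta))
        wb = np.full(len(tb), 1.0 / len(tb))
    obs = _beta_mntd(D, ia, ib, wa, wb)
    null = np.empty(n_null)
    npool = len(pool)
    # The two communities are relabelled independently so that taxa shared
    # between them do not pin the null at zero distance.
    for b in range(n_null):
        perm_a = rng.permutation(npool)
        perm_b = rng.permutation(npool)
        null[b] = _beta_mntd(D, perm_a[ia], perm_b[ib], wa, wb)
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("null standard deviation is zero; betaNTI undefined")
    return BetaNtiResult(obs, float(null.mean()), float(sd),
                         float((obs - null.mean()) / sd), n_null)


def community_metrics(phylo: Phylogeny, table, n_null: int = 999,
                      seed: int | None = None, include_root: bool = True) -> pd.DataFrame:
    """Per-sample PD, SR, PSV/PSC/PSR/PSE, MPD, MNTD, NRI, NTI for a
    CountTable (or taxa-by-samples DataFrame) whose taxa are tree tips."""
    df = table.data if hasattr(table, "data") else table
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(df.columns))]
    rows = []
    for rng, sample in zip(rngs, df.columns):
        col = df[sample]
        present = list(col.index[col > 0])
        sr = len(present)
        pd_val = faith_pd(phylo, present, include_root=include_root)
        fam = psv_family(phylo, present, abundances=col[col > 0].to_dict())
        if sr >= 2:
            ses = nri_nti(phylo, present, n_null=n_null, seed=rng)
            mpd_v, mntd_v, nri_v, nti_v = ses.mpd, ses.mntd, ses.nri, ses.nti
        else:
            mpd_v = mntd_v = nri_v = nti_v = float("nan")
        rows.append({"sample": sample, "PD": pd_val, "SR": sr, "PSV": fam.psv,
                     "PSC": fam.psc, "PSR": fam.psr, "PSE": fam.pse,
                     "MPD": mpd_v, "MNTD": mntd_v, "NRI": nri_v, "NTI": nti_v})
    return pd.DataFrame(rows).set_index("sample")
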