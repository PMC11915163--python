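"""Alpha/beta diversity, ordination, PERMANOVA, Procrustes, turnover, Venn.

Distances: Bray-Curtis on abundances, Sørensen on presence/absence (the
latter equals the Dice dissimilarity), plain Euclidean.  PERMANOVA follows
Anderson's pseudo-F on the distance matrix with a label-permutation p-value;
Procrustes uses the symmetric superimposition (both configurations centred
and scaled to unit sum of squares) so M² lies in [0, 1], with a
row-permutation test.  Permutation p-values always use the (1 + m)/(1 + M)
estimator so p is never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountTable, SampleMetadata, TaxonomyTable, ValidationError

SUPPORTED_METRICS = ("bray_curtis", "sorensen", "euclidean")


def _frame(table) -> pd.DataFrame:
    return table.data if hasattr(table, "data") else table


def shannon(table) -> pd.Series:
    """Shannon index H = -sum p_i ln p_i per sample (natural log)."""
    df = _frame(table)
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise ValidationError(f"all-zero sample(s): {list(sums.index[sums <= 0])}")
    p = df.to_numpy() / sums.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=0), index=df.columns, name="shannon")


def gini_simpson(table) -> pd.Series:
    """Gini-Simpson index 1 - sum p_i^2 per sample."""
    df = _frame(table)
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise ValidationError(f"all-zero sample(s): {list(sums.index[sums <= 0])}")
    p = df.to_numpy() / sums.to_numpy()
    return pd.Series(1.0 - (p ** 2).sum(axis=0), index=df.columns, name="gini_simpson")


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12) or not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.sample_ids),
                            columns=list(self.sample_ids))


def distance(table, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample distances.

    bray_curtis = sum|x-y| / sum(x+y); sorensen = 1 - 2|A∩B|/(|A|+|B|) on
    presence/absence.  A pair of all-zero samples makes either undefined and
    raises.
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    df = _frame(table)
    X = df.to_numpy(dtype=float).T  # samples x taxa
    if metric in ("bray_curtis", "sorensen"):
        zero = np.nonzero(X.sum(axis=1) == 0)[0]
        if len(zero) >= 2:
            raise ValidationError(
                f"distance undefined between all-zero samples: "
                f"{[df.columns[i] for i in zero]}")
    if metric == "bray_curtis":
        d = pdist(X, metric="braycurtis")
    elif metric == "sorensen":
        d = pdist(X > 0, metric="dice")
    else:
        d = pdist(X, metric="euclidean")
    return DistanceMatrix(tuple(df.columns), squareform(d), metric)


def sorensen_presence(a: set, b: set) -> float:
    """Sørensen dissimilarity of two presence sets."""
    if not a and not b:
        raise ValidationError("Sørensen undefined for two empty sets")
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


@dataclass(frozen=True)
class PCAResult:
    coords: pd.DataFrame           # samples x axes
    proportions: np.ndarray        # variance explained per axis
    loadings: pd.DataFrame         # taxa x axes
    degenerate: bool


def hellinger(table) -> pd.DataFrame:
    """Hellinger transform: sqrt of per-sample relative fractions."""
    df = _frame(table)
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise ValidationError("all-zero sample in Hellinger transform")
    return np.sqrt(df / sums)


def pca(table, transform: str = "hellinger", n_axes: int | None = None) -> PCAResult:
    """PCA of sample profiles (samples as observations).

    Default input is the Hellinger-transformed relative abundances; ``raw``
    and ``clr`` are selectable.  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    df = _frame(table)
    if df.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if transform == "hellinger":
        df = hellinger(df)
    elif transform == "clr":
        logd = np.log(df + 1.0)
        df = logd - logd.mean(axis=0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    X = df.to_numpy(dtype=float).T  # samples x taxa
    Xc = X - X.mean(axis=0)
    total_var = (Xc ** 2).sum()
    n_sv = min(Xc.shape)
    if total_var <= 1e-12:
        axes = n_axes or n_sv
        coords = pd.DataFrame(np.zeros((X.shape[0], axes)), index=df.columns,
                              columns=[f"PC{i + 1}" for i in range(axes)])
        loads = pd.DataFrame(np.zeros((X.shape[1], axes)), index=df.index,
                             columns=coords.columns)
        return PCAResult(coords, np.zeros(axes), loads, degenerate=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest |loading| positive per axis
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    prop = S ** 2 / (S ** 2).sum()
    axes = min(n_axes or n_sv, n_sv)
    coords = pd.DataFrame(U[:, :axes] * S[:axes], index=df.columns,
                          columns=[f"PC{i + 1}" for i in range(axes)])
    loads = pd.DataFrame(Vt[:axes].T, index=df.index, columns=coords.columns)
    return PCAResult(coords, prop[:axes], loads, degenerate=False)


@dataclass(frozen=True)
class PermanovaResult:
    f: float
    r2: float
    p_value: float
    n_perm: int


def permanova(d: DistanceMatrix, groups: Mapping[str, str] | pd.Series,
              n_perm: int = 999, seed: int | None = None) -> PermanovaResult:
    """Anderson's PERMANOVA on a distance matrix.

    R² = SS_between / SS_total; p = (1 + #{perm F >= obs F}) / (1 + n_perm)
    from label permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray([groups[s] for s in d.sample_ids])
    uniq, inv = np.unique(labels, return_inverse=True)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    for g in range(k):
        if (inv == g).sum() < 2:
            raise ValidationError(f"group {uniq[g]!r} has fewer than 2 samples")
    D2 = d.matrix ** 2

    def f_and_r2(assignment: np.ndarray) -> tuple[float, float]:
        ss_total = D2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in range(k):
            idx = np.nonzero(assignment == g)[0]
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
        return f, ss_between / ss_total

    f_obs, r2 = f_and_r2(inv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = f_and_r2(rng.permutation(inv))
        if f_perm >= f_obs:
            hits += 1
    return PermanovaResult(float(f_obs), float(r2), (1 + hits) / (1 + n_perm), n_perm)


@dataclass(frozen=True)
class ProcrustesResult:
    m2: float
    residuals: pd.Series
    p_value: float
    n_perm: int


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Symmetric Procrustes: centre and unit-scale both, optimal rotation +
    scaling of Y onto X.  Returns (M2, per-row residuals)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.sqrt((Xc ** 2).sum())
    ny = np.sqrt((Yc ** 2).sum())
    if nx <= 0 or ny <= 0:
        raise ValidationError("degenerate configuration with zero spread")
    Xc, Yc = Xc / nx, Yc / ny
    U, S, Vt = np.linalg.svd(Xc.T @ Yc)
    R = Vt.T @ U.T           # rotation applied to Y
    c = S.sum()              # optimal scaling
    fitted = c * (Yc @ R)
    resid = np.sqrt(((Xc - fitted) ** 2).sum(axis=1))
    m2 = 1.0 - c ** 2
    return max(m2, 0.0), resid


def procrustes(x_coords: pd.DataFrame, y_coords: pd.DataFrame,
               n_perm: int = 999, seed: int | None = None) -> ProcrustesResult:
    """Procrustes superimposition of two sample ordinations with a
    permutation test (PROTEST-style: rows of Y permuted)."""
    if list(x_coords.index) != list(y_coords.index):
        y_coords = y_coords.reindex(x_coords.index)
        if y_coords.isna().any().any():
            raise ValidationError("x and y must cover the same samples")
    X = x_coords.to_numpy(dtype=float)
    Y = y_coords.to_numpy(dtype=float)
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValidationError("need at least 2 ordination axes")
    m2, resid = _procrustes_m2(X, Y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        m2_p, _ = _procrustes_m2(X, Y[rng.permutation(len(Y))])
        if m2_p <= m2:
            hits += 1
    return ProcrustesResult(float(m2), pd.Series(resid, index=x_coords.index),
                            (1 + hits) / (1 + n_perm), n_perm)


def pooled_presence(table, meta: SampleMetadata, period: str) -> set[str]:
    """Taxa present (count > 0) in any sample of the period."""
    df = _frame(table)
    samples = [s for s in meta.samples_in(period) if s in df.columns]
    if not samples:
        raise ValidationError(f"no samples for period {period!r}")
    sub = df[samples]
    return set(sub.index[(sub > 0).any(axis=1)])


@dataclass(frozen=True)
class TurnoverResult:
    label: str
    period_a: str
    period_b: str
    gained: int
    lost: int
    shared: int

    @property
    def rate(self) -> float:
        denom = self.gained + self.lost + self.shared
        return float("nan") if denom == 0 else (self.gained + self.lost) / denom


def turnover(table, meta: SampleMetadata, tax: TaxonomyTable, rank: str,
             period_a: str, period_b: str) -> dict[str, TurnoverResult]:
    """Per-rank-label presence/absence turnover between two periods.

    Samples of each period are pooled to presence sets; per label,
    rate = (gained + lost) / (gained + lost + shared), which equals the
    Sørensen dissimilarity of the two pooled sets.  Labels absent from both
    periods get rate NaN.
    """
    df = _frame(table)
    tax.require(list(df.index))
    pres_a = pooled_presence(df, meta, period_a)
    pres_b = pooled_presence(df, meta, period_b)
    labels = tax.lineages.loc[list(df.index), rank].astype(str)
    out = {}
    for label in dict.fromkeys(labels):
        members = set(labels.index[labels == label])
        a, b = pres_a & members, pres_b & members
        out[label] = TurnoverResult(label, period_a, period_b,
                                    gained=len(b - a), lost=len(a - b),
                                    shared=len(a & b))
    return out


def venn_partition(sets: Mapping[str, set]) -> dict[str, int]:
    """Counts of the 7 exclusive regions of three presence sets.

    Keys join the member set names with '&'; counts sum to |union|.
    """
    if len(sets) != 3:
        raise ValueError("exactly 3 sets required")
    names = list(sets)
    out: dict[str, int] = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def alpha_group_tests(values: pd.Series, meta: SampleMetadata) -> pd.DataFrame:
    """Two-sided Welch t-tests between all period pairs with BH-FDR."""
    rows = []
    periods = list(meta.period_order)
    for a, b in itertools.combinations(periods, 2):
        va = values[[s for s in meta.samples_in(a) if s in values.index]]
        vb = values[[s for s in meta.samples_in(b) if s in values.index]]
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append({"period_a": a, "period_b": b, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
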