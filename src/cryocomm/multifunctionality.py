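"""Nitrogen-metabolism multifunctionality index.

Each enzyme's abundances are z-scored across samples (sample sd, n-1) and
the per-sample index is the mean of those z-scores, so indices are centred
at zero by construction.  The focal phylum is excluded from the community
table *before* any function prediction to avoid the focal taxa driving the
index they are then regressed against.

The shipped default enzyme list holds 39 nitrogen-cycle identifiers as a
configurable placeholder panel (representative, not an authoritative
pathway export); any enzyme x sample table with matching sample ids works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountTable, TaxonomyTable, ValidationError

# Placeholder panel of 39 nitrogen-cycle enzyme identifiers (configurable).
DEFAULT_ENZYMES: tuple[str, ...] = tuple(
    ["EC:1.7.99.4", "EC:1.7.2.1", "EC:1.7.2.4", "EC:1.7.2.5", "EC:1.7.2.6",
     "EC:1.18.6.1", "EC:1.19.6.1", "EC:6.3.1.2", "EC:1.4.1.2", "EC:1.4.1.13",
     "EC:1.4.7.1", "EC:3.5.1.5", "EC:1.14.99.39", "EC:1.7.1.15", "EC:1.7.7.1",
     "EC:1.7.7.2", "EC:1.7.5.1", "EC:1.7.1.4", "EC:1.7.1.1", "EC:1.7.1.2",
     "EC:1.7.1.3", "EC:3.5.5.1", "EC:4.2.1.104", "EC:3.5.1.49", "EC:6.3.4.6",
     "EC:3.5.1.54", "EC:1.13.12.16", "EC:1.14.13.25", "EC:3.5.1.4", "EC:6.3.5.4",
     "EC:6.3.1.1", "EC:1.4.3.16", "EC:2.1.4.1", "EC:3.5.3.1", "EC:4.3.1.1",
     "EC:2.6.1.1", "EC:2.6.1.2", "EC:1.4.99.1", "EC:3.5.1.38"])


def read_function_table(path) -> pd.DataFrame:
    """Enzyme x sample abundance TSV (first column enzyme id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError("duplicate enzyme ids in function table")
    if (df.to_numpy() < 0).any():
        raise ValidationError("function abundances must be non-negative")
    return df.astype(float)


def exclude_focal_for_prediction(table: CountTable, tax: TaxonomyTable,
                                 focal_phylum: str) -> CountTable:
    """Remove all focal-phylum taxa before function-table computation."""
    tax.require(table.taxon_ids)
    focal = [t for t in table.taxon_ids if tax.rank_of(t, "phylum") == focal_phylum]
    if len(focal) == len(table.taxon_ids):
        raise ValidationError("excluding the focal phylum would empty the table")
    return table.drop_taxa(focal) if focal else table


@dataclass(frozen=True)
class MultifunctionalityResult:
    index: pd.Series        # per-sample multifunctionality index
    z_scores: pd.DataFrame  # enzyme x sample z-score matrix
    dropped: tuple[str, ...]  # zero-variance enzymes removed


def multifunctionality_index(fn: pd.DataFrame) -> MultifunctionalityResult:
    """Z-score each enzyme across samples (sd with n-1) and average.

    Zero-variance enzymes carry no ranking information and are dropped with
    a warning; dropping them never changes the remaining z-scores.
    """
    if fn.shape[1] < 2:
        raise ValidationError("multifunctionality needs at least 2 samples")
    sd = fn.std(axis=1, ddof=1)
    dropped = tuple(fn.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance enzymes: {list(dropped)}", stacklevel=2)
        fn = fn.loc[sd > 0]
        if fn.empty:
            raise ValidationError("all enzymes have zero variance")
        sd = sd[sd > 0]
    z = fn.sub(fn.mean(axis=1), axis=0).div(sd, axis=0)
    index = z.mean(axis=0)
    index.name = "multifunctionality"
    return MultifunctionalityResult(index=index, z_scores=z, dropped=dropped)


@dataclass(frozen=True)
class AssociationResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def associate(index: pd.Series, focal_abundance: pd.Series) -> AssociationResult:
    """OLS of the multifunctionality index on focal-phylum abundance."""
    common = [s for s in index.index if s in focal_abundance.index]
    if len(common) < 3:
        raise ValidationError("association needs at least 3 shared samples")
    x = focal_abundance[common].to_numpy(dtype=float)
    y = index[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("zero-variance predictor")
    res = stats.linregress(x, y)
    return AssociationResult(slope=float(res.slope), intercept=float(res.intercept),
                             r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                             n=len(common))
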