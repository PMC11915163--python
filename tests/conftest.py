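import numpy as np
import pandas as pd
import pytest

from cryocomm.core_io import CountTable, QpcrTable, SampleMetadata, TaxonomyTable
from cryocomm.core_io import RANKS
from cryocomm.phylo_metrics import Phylogeny
from cryocomm.synthetic_data import simulate_phylogeny


def make_taxonomy(assignments: dict[str, str], domain: str = "Bacteria") -> TaxonomyTable:
    """Taxonomy from taxon -> phylum, other ranks filled mechanically."""
    rows = [(domain, phy, f"{phy}_c", f"{phy}_o", f"{phy}_f", f"{phy}_g")
            for phy in assignments.values()]
    return TaxonomyTable(lineages=pd.DataFrame(rows, index=list(assignments),
                                               columns=list(RANKS)))


@pytest.fixture
def tiny_table() -> CountTable:
    data = pd.DataFrame([[3.0, 5.0], [1.0, 0.0], [0.0, 5.0]],
                        index=["z1", "z2", "z3"], columns=["s1", "s2"])
    return CountTable(data=data, unit="reads")


@pytest.fixture
def fixture_tree() -> Phylogeny:
    # 8-tip pure-birth tree, fixed seed; the frozen oracle values in
    # test_phylo_metrics were computed on exactly this tree.
    return simulate_phylogeny(8, seed=42, taxon_ids=[f"z{i}" for i in range(1, 9)])


@pytest.fixture
def star_tree() -> Phylogeny:
    return Phylogeny.from_newick("(a:1.0,b:1.0,c:1.0,d:1.0,e:1.0);")


@pytest.fixture
def three_period_meta() -> SampleMetadata:
    samples = {f"{p}_{i}": p for p in ("acc", "melt", "late") for i in (1, 2)}
    return SampleMetadata(periods=pd.Series(samples),
                          period_order=("acc", "melt", "late"))
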