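import io

import numpy as np
import pandas as pd
import pytest

from phenosets.examples import worm_example_collection
from phenosets.genesets import GeneSet, GeneSetCollection


@pytest.fixture
def worm_examples():
    """Curated small worm phenotype gene sets (fully enumerated)."""
    return worm_example_collection()


@pytest.fixture
def three_row_table():
    return io.StringIO("geneA\tphen1\ngeneB\tphen1\ngeneA\tphen2\n")


def make_collection(sizes: dict[str, int], prefix: str = "G",
                    disjoint: bool = True) -> GeneSetCollection:
    """Gene sets of prescribed sizes, disjoint by default."""
    sets = []
    start = 0
    for name, n in sizes.items():
        genes = [f"{prefix}{start + i}.1" for i in range(n)]
        if not disjoint:
            start = 0
        else:
            start += n
        sets.append(GeneSet(name, genes))
    return GeneSetCollection("fixture", sets)


@pytest.fixture
def null_scores():
    rng = np.random.default_rng(7)
    genes = [f"N{i}.1" for i in range(500)]
    return pd.Series(rng.normal(size=500), index=genes)
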