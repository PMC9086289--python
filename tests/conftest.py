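import numpy as np
import pandas as pd
import pytest

from desertscope import synthetic as sy
from desertscope.expression import ExpressionMatrix
from desertscope.regions import Annotation, GeneRecord, GenomicRegion, RegionSet


@pytest.fixture(scope="session")
def planted_fixture():
    """Default synthetic fixture: CBC shifted 2 SD at four postnatal stages
    on 12 desert-sweep genes."""
    return sy.make_full_fixture(seed=11)


@pytest.fixture(scope="session")
def null_fixture():
    return sy.make_full_fixture(seed=11, planted_structure=None)


@pytest.fixture
def toy_annotation():
    return Annotation(
        [
            GeneRecord("g1", "G1", "chr1", 0, 10),
            GeneRecord("g2", "G2", "chr1", 20, 30),
            GeneRecord("g3", "G3", "chr1", 28, 60),
        ]
    )


@pytest.fixture
def small_log_matrix():
    """Deterministic 5-gene x 6-sample log-scale matrix."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(4.0, 1.0, size=(5, 6)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(values, scale="log2")


def region(chrom, start, end, label=""):
    return GenomicRegion(chrom, start, end, label)


def regionset(name, *triples):
    return RegionSet(name, [GenomicRegion(*t) for t in triples])
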