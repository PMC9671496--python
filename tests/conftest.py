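import numpy as np
import pytest

from tnselect.genome import GeneRecord, GenomeAnnotation, InsertionCountTable
from tnselect.simulate import SelectionModel, simulate_experiment


@pytest.fixture
def toy_annotation():
    """Three non-overlapping genes on a 1 kb contig."""
    return GenomeAnnotation(
        contig_id="chr",
        contig_length=1000,
        genes=[
            GeneRecord("geneA", 101, 200, "+"),
            GeneRecord("geneB", 301, 600, "-"),
            GeneRecord("geneC", 701, 900, "+"),
        ],
    )


@pytest.fixture
def toy_table():
    return InsertionCountTable(
        sample_id="s1",
        condition="phage",
        contig_id="chr",
        counts={101: 3, 150: 5, 200: 2, 250: 7, 400: 1, 850: 4},
    )


@pytest.fixture(scope="session")
def default_experiment():
    """One full simulated two-replicate screen at default (study) scale.

    Session-scoped: the same experiment backs the recovery, monotonicity,
    and determinism checks.
    """
    return simulate_experiment(SelectionModel(seed=12345))


@pytest.fixture(scope="session")
def default_fit(default_experiment):
    from tnselect.enrichment import TnSeqScreenModel

    return TnSeqScreenModel.from_experiment(default_experiment).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(99)
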