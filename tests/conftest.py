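import numpy as np
import pytest

from xte.core_model import GeneSetCollection, TissuePanel


@pytest.fixture
def toy_panel():
    """4 genes x 2 tissues, fully observed."""
    return TissuePanel(
        genes=["A", "B", "C", "D"],
        tissues=["liver", "kidney"],
        p=np.array([[0.01, 0.5], [0.2, 0.9], [0.7, 0.05], [1.0, 1.0]]),
        log2fc=np.array([[1.0, -1.0], [0.3, 0.2], [-0.5, 0.4], [0.0, -0.1]]),
        mean_expr=np.array([[90.0, 10.0], [5.0, 5.0], [0.0, 20.0], [1.0, 1.0]]),
    )


@pytest.fixture
def tiny_sets():
    return GeneSetCollection(sets={
        "S1": frozenset({"A", "B"}),
        "S2": frozenset({"C", "D"}),
        "ABSENT": frozenset({"ZZZ1", "ZZZ2"}),
    })


@pytest.fixture
def de_table_file(tmp_path):
    path = tmp_path / "de_liver.tsv"
    path.write_text(
        "gene\tpvalue\tlog2fc\tbase_mean\n"
        "A\t0.01\t1.0\t90.0\n"
        "B\t0.2\t0.3\t5.0\n"
        "C\t0.7\t-0.5\t12.0\n"
    )
    return path
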