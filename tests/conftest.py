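import numpy as np
import pytest

from mfistates.data_io import BinaryMatrix, ExpressionMatrix
from mfistates.synthetic_data import BinaryBayesNet


@pytest.fixture
def small_expression():
    return ExpressionMatrix(
        values=np.array([[0.0, 1.0], [2.0, 0.0], [0.0, 0.0]]),
        gene_names=["g1", "g2"],
        cell_ids=["c1", "c2", "c3"],
    )


def binary(values, genes=None, cells=None) -> BinaryMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    return BinaryMatrix(values=values, gene_names=genes, cell_ids=cells)


@pytest.fixture
def make_binary():
    return binary


@pytest.fixture
def chain_net():
    """A -> B -> C with strong links."""
    return BinaryBayesNet(
        nodes=["A", "B", "C"],
        parents={"B": ("A",), "C": ("B",)},
        cpts={
            "A": {(): 0.5},
            "B": {(0,): 0.2, (1,): 0.8},
            "C": {(0,): 0.2, (1,): 0.8},
        },
    )


@pytest.fixture
def collider_net():
    """A -> C <- B, A and B marginally independent."""
    return BinaryBayesNet(
        nodes=["A", "B", "C"],
        parents={"C": ("A", "B")},
        cpts={
            "A": {(): 0.5},
            "B": {(): 0.5},
            "C": {(0, 0): 0.1, (0, 1): 0.8, (1, 0): 0.8, (1, 1): 0.95},
        },
    )
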