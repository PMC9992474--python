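import numpy as np
import pytest

from keygenes import ExpressionMatrix, PhenotypeTable


@pytest.fixture(scope="session")
def limma_fixture():
    """8-gene x 6-sample matrix (3 cases, 3 controls) with two shifted genes.

    Reference moderated-t values for this exact matrix were frozen from
    limma 3.58.1 (lmFit + eBayes) and live in the tests that use it.
    """
    values = np.array(
        [
            [10.3047, 8.9600, 10.7505, 8.9406, 6.0490, 6.6978],
            [6.6278, 6.1838, 6.4832, 7.1470, 8.8794, 8.7778],
            [8.0660, 9.1272, 8.4675, 7.1407, 8.3688, 7.0411],
            [8.8785, 7.9501, 7.8151, 7.3191, 9.2225, 7.8455],
            [7.5717, 7.6479, 8.5323, 8.3654, 8.4127, 8.4308],
            [10.1416, 7.5936, 7.4878, 7.1862, 8.6160, 9.1290],
            [7.8861, 7.1598, 7.1755, 8.6506, 8.7433, 8.5432],
            [7.3345, 8.2322, 8.1167, 8.2187, 8.8714, 8.2236],
        ]
    )
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{j}" for j in range(6)]
    X = ExpressionMatrix(genes, samples, values)
    labels = PhenotypeTable(samples, [1, 1, 1, 0, 0, 0])
    return X, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, prefix_g="g", prefix_s="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"{prefix_s}{j}" for j in range(values.shape[1])],
        values,
    )
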