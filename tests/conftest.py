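import numpy as np
import pytest

from genescreen import ClassVector, ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with simple hand-checkable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 5.0, 5.0, 5.0],
            [0.5, -1.5, 2.0, 0.0],
        ]
    )
    return ExpressionMatrix(("g1", "g2", "g3"), ("s1", "s2", "s3", "s4"), values)


@pytest.fixture
def balanced_labels() -> ClassVector:
    return ClassVector(np.array([1, 1, 0, 0]), ("s1", "s2", "s3", "s4"))


def write_matrix_file(path, gene_ids, sample_ids, values, sep="\t"):
    with open(path, "w") as fh:
        fh.write(sep.join(["gene_id", *sample_ids]) + "\n")
        for g, row in zip(gene_ids, values):
            fh.write(sep.join([g, *[repr(float(v)) for v in row]]) + "\n")
    return path


def write_labels_file(path, pairs, sep="\t"):
    with open(path, "w") as fh:
        for sid, cls in pairs:
            fh.write(f"{sid}{sep}{cls}\n")
    return path
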