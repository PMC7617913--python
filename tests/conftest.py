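import numpy as np
import pandas as pd
import pytest

import chemocoex as cc
from chemocoex.filtering import ExpressionMatrix


@pytest.fixture(scope="session")
def panel():
    return cc.default_panel()


@pytest.fixture(scope="session")
def lr_panel(panel):
    return cc.subset(panel, {"chemokine_ligand", "chemokine_receptor"})


@pytest.fixture(scope="session")
def default_corpus(panel):
    return cc.generate_corpus(cc.default_corpus_config(panel, seed=1))


@pytest.fixture(scope="session")
def filtered_matrix(default_corpus, lr_panel):
    matrix = cc.assemble_matrix(default_corpus, lr_panel)
    filtered, _ = cc.four_step_filter(matrix)
    return filtered


def make_matrix(values: np.ndarray, genes=None, assays=None) -> ExpressionMatrix:
    """Wrap a plain array as an ExpressionMatrix with generated identifiers."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    assays = assays or [f"a{j + 1}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=genes, columns=assays)
    meta = pd.DataFrame(index=frame.columns)
    return ExpressionMatrix(values=frame, assay_meta=meta)
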