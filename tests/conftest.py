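import numpy as np
import pandas as pd
import pytest

from conet.expression import ExpressionMatrix
from conet.simulate import design_frame


def make_design() -> pd.DataFrame:
    """The standard six-array design: two replicates of VC, PhaC, PhaBC."""
    return design_frame()


def make_matrix(values: np.ndarray, genes=None,
                meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    meta = make_design() if meta is None else meta
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=list(meta["sample_id"]))
    return ExpressionMatrix(data=data, meta=meta)


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_spots(rows) -> pd.DataFrame:
    """Build a spot table from (probe, gene, sample, intensity, flag) rows."""
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "sample_id",
                                       "intensity", "flag"])
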