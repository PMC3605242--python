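import numpy as np
import pandas as pd
import pytest

from boolerank import (
    ExpressionMatrix,
    SyntheticConfig,
    WeightTable,
    load_reference_patterns,
    load_reference_weights,
)

#: Published phi weights of the seven attributes (6-dp rounded).
REFERENCE_WEIGHTS = {
    "Meth": 0.021944,
    "SP": 0.036727,
    "PK": 0.037870,
    "TS": 0.038675,
    "PTM": 0.046598,
    "TF": 0.048745,
    "Hub": 0.072986,
}


@pytest.fixture(scope="session")
def reference_weights() -> WeightTable:
    return load_reference_weights()


@pytest.fixture(scope="session")
def reference_patterns() -> pd.DataFrame:
    return load_reference_patterns()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_weight_table(values: dict) -> WeightTable:
    """WeightTable from a plain attribute->weight dict (p-values set to 1)."""
    df = pd.DataFrame({"r_phi": pd.Series(values, dtype=float)})
    df["p_value"] = 1.0
    return WeightTable(df)


def tiny_expression(tumor: dict, normal: dict, is_log2: bool = True) -> ExpressionMatrix:
    """ExpressionMatrix from per-sample gene->value dicts.

    ``tumor`` / ``normal`` map sample name -> list of per-gene values;
    genes are integer IDs 1..n.
    """
    cols = {**tumor, **normal}
    n_genes = len(next(iter(cols.values())))
    values = pd.DataFrame(cols, index=pd.Index(range(1, n_genes + 1), name="gene"))
    classes = pd.Series(
        ["tumor"] * len(tumor) + ["normal"] * len(normal),
        index=list(tumor) + list(normal),
    )
    return ExpressionMatrix(values, classes, is_log2=is_log2)
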