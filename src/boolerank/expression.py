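"""Two-class expression matrix container.

A thin wrapper around a genes x samples :class:`pandas.DataFrame` carrying
the tumor/normal class label of each sample and a flag recording whether
values are on the log2 or linear scale. Downstream stages (differential
expression, signature scoring) always work on log2 values; ingesting
linear-scale data and converting exercises the same preprocessing path a
real microarray matrix goes through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample.
    classes
        Series mapping sample -> class label (``"tumor"`` / ``"normal"``).
        Must cover every column of ``values``.
    is_log2
        Whether ``values`` are on the log2 scale.
    """

    values: pd.DataFrame
    classes: pd.Series
    is_log2: bool = True

    def __post_init__(self) -> None:
        self.classes = pd.Series(self.classes)
        missing = [c for c in self.values.columns if c not in self.classes.index]
        if missing:
            raise ValueError(f"samples without class label: {missing[:5]}")
        self.classes = self.classes.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, label: str) -> list:
        return list(self.classes.index[self.classes == label])

    def to_log2(self) -> "ExpressionMatrix":
        if self.is_log2:
            return self
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("non-positive expression values cannot be log2-transformed")
        return ExpressionMatrix(np.log2(self.values), self.classes, is_log2=True)

    def to_linear(self) -> "ExpressionMatrix":
        if not self.is_log2:
            return self
        return ExpressionMatrix(2.0 ** self.values, self.classes, is_log2=False)

    # -- TSV round trip: header row carries "sample:class" ------------------

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{s}:{self.classes[s]}" for s in out.columns]
        out.index.name = f"gene[{'log2' if self.is_log2 else 'linear'}]"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        is_log2 = "log2" in str(df.index.name)
        samples, labels = zip(*(c.rsplit(":", 1) for c in df.columns))
        df.columns = list(samples)
        df.index.name = "gene"
        classes = pd.Series(labels, index=list(samples))
        return cls(df, classes, is_log2=is_log2)


def split_classes(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (tumor, normal) sub-matrices on the log2 scale."""
    log2 = expr.to_log2()
    t = log2.values[log2.samples_of(TUMOR)]
    n = log2.values[log2.samples_of(NORMAL)]
    return t, n
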