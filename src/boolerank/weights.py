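"""Phi-correlation weighting of binary functional attributes.

Each gene carries seven binary functional attributes: promoter methylation
(Meth), secreted protein (SP), protein kinase (PK), tissue specificity (TS),
post-translational modification (PTM), transcription factor (TF) and
interactome hub (Hub, degree >= 5 in the high-confidence interaction
network). The weight of an attribute is the magnitude of its
phi-correlation with the known cancer-gene label,

    r_phi = |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d)) = sqrt(chi2 / N),

computed from the 2x2 attribute-by-cancer-status contingency table. The
enrichment direction (whether the attribute is more prevalent among cancer
genes) is reported separately since the weight itself is unsigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

#: Fixed bit order of the 7-attribute Boolean pattern string.
ATTRIBUTES: tuple[str, ...] = ("Meth", "SP", "PK", "TS", "PTM", "TF", "Hub")


def phi_correlation(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Phi coefficient magnitude and chi-square p-value of a 2x2 table.

    The table is laid out as rows = attribute present/absent, columns =
    cancer/non-cancer::

                cancer  non-cancer
        attr+     a         b
        attr-     c         d

    Returns ``(r_phi, p_value)`` with ``r_phi = sqrt(chi2/N)`` (uncorrected
    chi-square, 1 df). Raises :class:`ValueError` on negative counts, an
    empty table, or any zero margin (phi is undefined there).
    """
    counts = np.asarray([a, b, c, d], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative cell counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("empty contingency table")
    margins = {
        "attribute-present row": a + b,
        "attribute-absent row": c + d,
        "cancer column": a + c,
        "non-cancer column": b + d,
    }
    zero = [name for name, m in margins.items() if m == 0]
    if zero:
        raise ValueError(f"phi undefined: zero margin in {', '.join(zero)}")
    denom = np.sqrt(
        float(a + b) * float(c + d) * float(a + c) * float(b + d)
    )
    r_phi = abs(float(a) * float(d) - float(b) * float(c)) / denom
    chi2 = r_phi**2 * n
    p_value = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(r_phi), p_value


def phi_direction(a: int, b: int, c: int, d: int) -> int:
    """Sign of the association: +1 if the attribute is enriched among
    cancer genes (ad > bc), -1 if depleted, 0 if independent."""
    return int(np.sign(float(a) * float(d) - float(b) * float(c)))


@dataclass
class WeightTable:
    """Attribute -> (phi weight, p-value), optionally with direction."""

    table: pd.DataFrame  # index=attribute, columns r_phi, p_value[, direction]

    def __post_init__(self) -> None:
        missing = [x for x in ATTRIBUTES if x not in self.table.index]
        if missing:
            raise ValueError(f"weight table missing attributes: {missing}")

    def __getitem__(self, attribute: str) -> float:
        return float(self.table.loc[attribute, "r_phi"])

    @property
    def weights(self) -> pd.Series:
        return self.table["r_phi"].astype(float)

    def p_value(self, attribute: str) -> float:
        return float(self.table.loc[attribute, "p_value"])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "attribute"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "WeightTable":
        return cls(pd.read_csv(path, sep="\t", index_col="attribute"))


def build_weight_table(
    attribute_table: pd.DataFrame, cancer_labels: pd.Series
) -> WeightTable:
    """Compute one phi weight per attribute against the cancer-gene label.

    Parameters
    ----------
    attribute_table
        Genes x attributes DataFrame of 0/1 values; must contain all seven
        attribute columns.
    cancer_labels
        0/1 (or bool) Series indexed like ``attribute_table``; 1 = known
        cancer gene.
    """
    missing = [x for x in ATTRIBUTES if x not in attribute_table.columns]
    if missing:
        raise ValueError(f"attribute table missing columns: {missing}")
    labels = cancer_labels.loc[attribute_table.index].astype(bool)
    rows = {}
    for attr in ATTRIBUTES:
        present = attribute_table[attr].astype(bool)
        a = int((present & labels).sum())
        b = int((present & ~labels).sum())
        c = int((~present & labels).sum())
        d = int((~present & ~labels).sum())
        r, p = phi_correlation(a, b, c, d)
        rows[attr] = {"r_phi": r, "p_value": p, "direction": phi_direction(a, b, c, d)}
    return WeightTable(pd.DataFrame.from_dict(rows, orient="index"))


def load_reference_weights() -> WeightTable:
    """Load the packaged reference phi weights for the seven attributes.

    These are the published weights computed on the curated cancer-gene
    annotation set; the underlying contingency tables are not distributed,
    so the weights are shipped as data."""
    with resources.files("boolerank.data").joinpath("reference_weights.tsv").open() as fh:
        return WeightTable.read_tsv(fh)
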