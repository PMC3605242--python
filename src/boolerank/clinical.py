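"""Clinical characterization: signature score, Welch test, survival.

The expression signature of a prioritized gene set is, per sample, the
sum of the up-regulated genes' expression minus the sum of the
down-regulated genes' expression; tumor and normal cohorts are compared
with the Welch two-sample t-test. For prognosis, samples are
dichotomized at the median of a gene's (or combined score's) expression
— lower 50% of ranks "low", rest "high" — and the two groups are
compared with the Cox-Mantel log-rank test on Kaplan-Meier survival.
A combined three-gene score (by default CHEK1 + AR - LYN) is scored the
same way. Kaplan-Meier and log-rank computations are delegated to
lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .boolean_rank import load_reference_patterns

DEFAULT_LOGRANK_ALPHA = 0.1
DEFAULT_COMBINED_GENES = ("CHEK1", "AR", "LYN")


@dataclass
class SignatureDefinition:
    """Disjoint sets of up- and down-regulated signature genes."""

    up_genes: set
    down_genes: set

    def __post_init__(self) -> None:
        self.up_genes = set(self.up_genes)
        self.down_genes = set(self.down_genes)
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)}")
        if not self.up_genes and not self.down_genes:
            raise ValueError("empty signature")


def default_signature(use_symbols: bool = True) -> SignatureDefinition:
    """The packaged 17-gene ovarian signature (7 up, 10 down)."""
    ref = load_reference_patterns()
    key = "gene_symbol" if use_symbols else "gene_id"
    return SignatureDefinition(
        up_genes=set(ref.loc[ref["up"] == 1, key]),
        down_genes=set(ref.loc[ref["down"] == 1, key]),
    )


def signature_score(expr: pd.DataFrame, sigdef: SignatureDefinition) -> pd.Series:
    """Per-sample signature score Σ up-gene expression − Σ down-gene
    expression.

    ``expr`` is genes x samples on whatever scale the caller chose (the
    scale is the caller's to record). Signature genes absent from the
    matrix are skipped with a warning; if none are present this is an
    error.
    """
    up = [g for g in sigdef.up_genes if g in expr.index]
    down = [g for g in sigdef.down_genes if g in expr.index]
    missing = (sigdef.up_genes | sigdef.down_genes) - set(up) - set(down)
    if not up and not down:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        warnings.warn(f"signature genes absent from matrix, skipped: {sorted(map(str, missing))}")
    score = expr.loc[up].sum(axis=0) - expr.loc[down].sum(axis=0)
    score.name = "signature_score"
    return score


def welch_t(group1, group2) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, df, two-sided p).

    t is oriented as group1 minus group2. Raises if either group has
    fewer than two values or both groups have zero variance.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups: Welch t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize samples at the median rank of ``values``.

    Samples are stably sorted by (value, sample ID); the lower
    ceil(n/2) are labelled "low" (the median sample goes to "low" when n
    is odd), the rest "high". Needs >= 4 samples.
    """
    values = pd.Series(values)
    if len(values) < 4:
        raise ValueError("need at least 4 samples for a median split")
    order = values.to_frame("v").assign(_id=values.index.astype(str))
    order = order.sort_values(["v", "_id"], kind="stable")
    n_low = (len(values) + 1) // 2
    labels = pd.Series("high", index=order.index, dtype=object)
    labels.iloc[:n_low] = "low"
    return labels.loc[values.index]


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct event/censoring time with columns
    ``at_risk``, ``events``, ``censored`` and ``survival`` (right-
    continuous step values). All-censored input gives survival ≡ 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.copy()
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "at_risk": table["at_risk"].astype(int),
            "events": table["observed"].astype(int),
            "censored": table["censored"].astype(int),
            "survival": surv.reindex(table.index).to_numpy(),
        }
    )
    out.index.name = "time"
    return out


def logrank(times, events, groups) -> tuple[float, float]:
    """Cox-Mantel log-rank test between exactly two groups.

    Returns (chi2, p) with 1 degree of freedom. Requires two distinct
    group labels and at least one observed event overall.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValueError("no observed events")
    mask = groups == labels[0]
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def combined_score(
    expr: pd.DataFrame, genes: tuple = DEFAULT_COMBINED_GENES
) -> pd.Series:
    """Per-sample combined prognostic score: first + second − third gene.

    With the default genes this is CHEK1 + AR − LYN. All three genes must
    be present in the matrix.
    """
    if len(genes) != 3:
        raise ValueError("combined score needs exactly 3 genes")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    a, b, c = genes
    score = expr.loc[a] + expr.loc[b] - expr.loc[c]
    score.name = f"{a}+{b}-{c}"
    return score


def survival_by_median_split(
    values: pd.Series, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, float, float]:
    """Median-split ``values`` (indexed by sample), join with clinical
    (columns sample, time, event) and run the log-rank test.

    Returns (annotated clinical table with a ``group`` column, chi2, p).
    """
    labels = median_split(values)
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    clin = clin.drop(columns=["group"], errors="ignore")
    joined = clin.join(labels.rename("group"), how="inner")
    if joined["group"].isna().any() or len(joined) < 4:
        raise ValueError("insufficient overlap between scores and clinical records")
    chi2, p = logrank(joined["time"], joined["event"], joined["group"])
    joined.index.name = "sample"
    return joined.reset_index(), chi2, p
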