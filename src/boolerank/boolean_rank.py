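"""Boolean root decomposition and probability scoring of attribute patterns.

A gene's state is a 7-bit Boolean pattern over the fixed attribute order
(Meth, SP, PK, TS, PTM, TF, Hub). With k attributes present there are
2^k states, of which 2^k - 1 are *roots*: the non-empty subsets of the
present attributes. Each root's probability is the arithmetic mean of the
phi weights of its member attributes, and the gene's score is the sum of
all root probabilities. Because each attribute occurs in C(k-1, j-1) of
the size-j roots, the sum collapses to the closed form

    score = ((2^k - 1) / k) * sum(weights of present attributes),

which the root-enumeration implementation is tested against. Genes scoring
strictly above an empirical cutoff (default 0.5) are shortlisted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import pandas as pd

from .weights import ATTRIBUTES, WeightTable

Pattern = str  # 7-char string of 0/1 in ATTRIBUTES order

DEFAULT_SCORE_CUTOFF = 0.5


def pattern_attributes(pattern: Pattern) -> tuple[str, ...]:
    """Attribute names whose bit is set in a 7-bit pattern string."""
    if len(pattern) != len(ATTRIBUTES) or set(pattern) - {"0", "1"}:
        raise ValueError(f"pattern must be a 7-character 0/1 string, got {pattern!r}")
    return tuple(a for a, bit in zip(ATTRIBUTES, pattern) if bit == "1")


def attributes_to_pattern(present) -> Pattern:
    """Inverse of :func:`pattern_attributes`."""
    present = set(present)
    unknown = present - set(ATTRIBUTES)
    if unknown:
        raise ValueError(f"unknown attributes: {sorted(unknown)}")
    return "".join("1" if a in present else "0" for a in ATTRIBUTES)


def enumerate_roots(pattern: Pattern) -> list[tuple[str, ...]]:
    """All non-empty subsets of the pattern's set attributes.

    Returned in lexicographic order of position (singletons first); the
    count is always 2^k - 1 for k set bits. A pattern with no set bits has
    no roots and raises :class:`ValueError`.
    """
    present = pattern_attributes(pattern)
    if not present:
        raise ValueError("pattern has no set attributes (all-zero state has no roots)")
    roots: list[tuple[str, ...]] = []
    for size in range(1, len(present) + 1):
        roots.extend(combinations(present, size))
    return roots


def root_probability(root, weights: WeightTable) -> float:
    """Probability of a root: the arithmetic mean of its attribute weights."""
    root = tuple(root)
    if not root:
        raise ValueError("empty root")
    return sum(weights[a] for a in root) / len(root)


@dataclass
class BooleanScore:
    gene: object
    pattern: Pattern
    k: int
    n_roots: int
    score: float
    shortlisted: bool


def boolean_score(
    pattern: Pattern,
    weights: WeightTable,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    gene=None,
) -> BooleanScore:
    """Score one attribute pattern by summing all root probabilities."""
    roots = enumerate_roots(pattern)
    score = sum(root_probability(r, weights) for r in roots)
    k = len(pattern_attributes(pattern))
    return BooleanScore(
        gene=gene,
        pattern=pattern,
        k=k,
        n_roots=len(roots),
        score=score,
        shortlisted=score > cutoff,
    )


def closed_form_score(pattern: Pattern, weights: WeightTable) -> float:
    """((2^k - 1)/k) * sum of set-attribute weights; equals the root sum."""
    present = pattern_attributes(pattern)
    k = len(present)
    if k == 0:
        raise ValueError("pattern has no set attributes")
    return (2**k - 1) / k * sum(weights[a] for a in present)


def score_genes(
    attribute_table: pd.DataFrame,
    weights: WeightTable,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> pd.DataFrame:
    """Score every gene of a genes x attributes 0/1 table.

    Genes with an all-zero pattern get score 0 (no roots exist) and are
    never shortlisted. Returns a DataFrame indexed by gene with columns
    pattern, k, n_roots, score, shortlisted.
    """
    missing = [a for a in ATTRIBUTES if a not in attribute_table.columns]
    if missing:
        raise ValueError(f"attribute table missing columns: {missing}")
    rows = {}
    for gene, bits in attribute_table[list(ATTRIBUTES)].iterrows():
        pattern = "".join(str(int(bool(v))) for v in bits)
        k = pattern.count("1")
        if k == 0:
            rows[gene] = {
                "pattern": pattern, "k": 0, "n_roots": 0,
                "score": 0.0, "shortlisted": False,
            }
        else:
            s = boolean_score(pattern, weights, cutoff=cutoff, gene=gene)
            rows[gene] = {
                "pattern": s.pattern, "k": s.k, "n_roots": s.n_roots,
                "score": s.score, "shortlisted": s.shortlisted,
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


def shortlist(
    scores: pd.DataFrame,
    de_calls: pd.Series | None = None,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> dict[str, list]:
    """Split genes scoring strictly above ``cutoff`` by their DE call.

    ``de_calls`` maps gene -> {"up", "down", "none"}; genes absent from it
    count as "none". Returns {"de": [...], "non_de": [...]} with gene order
    by descending score.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    passed = scores[scores["score"] > cutoff].sort_values("score", ascending=False)
    if de_calls is None:
        de_calls = pd.Series(dtype=object)
    out: dict[str, list] = {"de": [], "non_de": []}
    for gene in passed.index:
        call = de_calls.get(gene, "none")
        out["de" if call in ("up", "down") else "non_de"].append(gene)
    return out


def load_reference_patterns() -> pd.DataFrame:
    """Packaged 17-gene shortlist: symbols, Entrez IDs, DE direction,
    7-bit patterns and the published probability scores."""
    with resources.files("boolerank.data").joinpath("reference_patterns.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"pattern": str})
    return df


def reference_score_report(weights: WeightTable | None = None) -> pd.DataFrame:
    """Recompute the published 17-gene scores and compare with the printed
    values.

    The four patterns without the Meth bit reproduce to within 1e-4 of the
    printed scores (the weights are published rounded to 6 dp). The two
    Meth-containing patterns (1011001, 1011010) do not reproduce under this
    scoring model for any assignment of attributes to bit positions; both
    the computed and the printed value are reported, with ``reproduced``
    False, rather than guessing at the source of the difference.
    """
    if weights is None:
        from .weights import load_reference_weights

        weights = load_reference_weights()
    df = load_reference_patterns().copy()
    df["computed_score"] = [
        boolean_score(p, weights).score for p in df["pattern"]
    ]
    df["reproduced"] = (df["computed_score"] - df["printed_rank"]).abs() <= 1e-4
    return df
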