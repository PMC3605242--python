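"""Validation-set preprocessing, co-expression networks and centralities.

Raw probe-level expression is log2-transformed and collapsed to one row
per gene by keeping, for each gene, the probe with the highest variance
across samples; probes without a gene assignment or mapping to several
genes are dropped. Co-expression edges connect gene pairs whose Pearson
correlation (signed) strictly exceeds a threshold, 0.5 by default.

For a signalling (or any) network, node importance is summarized by
betweenness centrality (raw shortest-path bridge counts, each unordered
pair counted once), influence by eigenvector centrality (computed per
connected component, max-normalized to 1), and the residual of the
least-squares regression of betweenness on eigenvector highlights nodes
whose bridging role exceeds what their influence predicts.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_R_THRESHOLD = 0.5

_MULTI_GENE_SEPARATORS = (";", "///", ",")


def preprocess_validation(probe_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level table to a gene-level log2 matrix.

    ``probe_table`` columns: ``probe``, ``gene`` and one column per sample
    with raw (linear, positive) expression values. Probes with empty/NaN
    gene IDs or multi-gene assignments (separator ``;``, ``///`` or ``,``)
    are removed; among a gene's remaining probes the one with maximal
    variance of the log2 values is kept. Returns a genes x samples
    DataFrame of log2 values.
    """
    df = probe_table.copy()
    for col in ("probe", "gene"):
        if col not in df.columns:
            raise ValueError(f"probe table needs a '{col}' column")
    sample_cols = [c for c in df.columns if c not in ("probe", "gene")]
    gene = df["gene"].astype(object)
    bad = gene.isna() | (gene.astype(str).str.strip() == "")
    multi = gene.astype(str).apply(
        lambda s: any(sep in s for sep in _MULTI_GENE_SEPARATORS)
    )
    df = df[~(bad | multi)]
    values = df[sample_cols].astype(float)
    if (values.to_numpy() <= 0).any():
        raise ValueError("non-positive expression values cannot be log2-transformed")
    log2 = np.log2(values)
    log2.insert(0, "gene", df["gene"].values)
    log2.insert(1, "probe", df["probe"].values)

    keep = (
        log2.assign(_var=log2[sample_cols].var(axis=1, ddof=1))
        .sort_values(["gene", "_var", "probe"])
        .groupby("gene", sort=True)
        .tail(1)
    )
    out = keep.set_index("gene")[sample_cols]
    out.index.name = "gene"
    return out


def build_coexpression(
    expr: pd.DataFrame, r_threshold: float = DEFAULT_R_THRESHOLD
) -> pd.DataFrame:
    """All unordered gene pairs with Pearson r strictly above threshold.

    The threshold applies to the signed correlation, so strong
    anti-correlation never creates an edge. Genes with zero variance are
    excluded (with a warning). Needs >= 3 samples. Returns a DataFrame
    with columns gene_a, gene_b, r.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    variances = expr.var(axis=1, ddof=1)
    flat = variances[variances == 0].index.tolist()
    if flat:
        warnings.warn(f"excluding {len(flat)} zero-variance gene(s) from co-expression")
        expr = expr.drop(index=flat)
    genes = expr.index.to_list()
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    corr = np.corrcoef(expr.to_numpy())
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = corr[iu, ju] > r_threshold
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[mask]],
            "gene_b": [genes[j] for j in ju[mask]],
            "r": corr[iu, ju][mask],
        }
    )


def coexpression_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], r=float(row["r"]))
    return g


def centralities(network: nx.Graph) -> pd.DataFrame:
    """Betweenness, eigenvector centrality and regression residuals.

    Betweenness uses raw shortest-path counts (unordered pairs counted
    once), so a star centre with m leaves scores C(m,2). Eigenvector
    centrality is computed within each connected component and scaled so
    the component maximum is 1 (an isolated node scores 1). The residual
    column is from the ordinary least-squares fit betweenness ~ a + b *
    eigenvector over all nodes; residuals sum to zero.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty graph")
    btw = nx.betweenness_centrality(network, normalized=False)
    eig: dict = {}
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        if sub.number_of_nodes() <= 2 or sub.number_of_edges() == 0:
            # isolated node or single edge: symmetric, all scores maximal
            for n in comp:
                eig[n] = 1.0
            continue
        scores = nx.eigenvector_centrality_numpy(sub)
        top = max(scores.values())
        for n, v in scores.items():
            eig[n] = abs(v) / top
    nodes = list(network.nodes())
    b = np.array([btw[n] for n in nodes], dtype=float)
    e = np.array([eig[n] for n in nodes], dtype=float)
    if len(nodes) >= 2 and np.ptp(e) > 0:
        slope, intercept = np.polyfit(e, b, 1)
    else:
        slope, intercept = 0.0, float(b.mean())
    residual = b - (intercept + slope * e)
    out = pd.DataFrame(
        {"betweenness": b, "eigenvector": e, "residual": residual}, index=nodes
    )
    out.index.name = "node"
    return out


def prune_non_proteins(network: nx.Graph, protein_nodes) -> nx.Graph:
    """Restrict a curated signalling network to protein nodes (drops small
    molecules etc. before centrality analysis)."""
    return network.subgraph(set(protein_nodes)).copy()
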