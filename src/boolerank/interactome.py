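"""High-confidence interactome construction and hub calling.

Interaction evidence from multiple source databases is merged into one
record per unordered protein pair (evidence sets are unioned). A pair is
kept in the high-confidence (HC) set if any of four criteria holds:

1. reported by more than one source database;
2. verified by more than one detection-method class (biochemical,
   biophysical, imaging, protein complementation assay);
3. supported by a known domain-domain interaction;
4. confirmed by more than one independent publication (PMID).

The rules are combined disjunctively; which rules fired is recorded per
edge so a stricter conjunctive re-filter remains possible. Hubs are nodes
of the HC network with degree >= 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

HUB_DEGREE_THRESHOLD = 5

RULE_NAMES = ("multi_database", "multi_method", "domain_support", "multi_pmid")


@dataclass
class InteractionEvidence:
    """Evidence for one unordered protein pair."""

    pair: frozenset
    databases: set = field(default_factory=set)
    methods: set = field(default_factory=set)
    pmids: set = field(default_factory=set)
    domain_support: bool = False

    def __post_init__(self) -> None:
        self.pair = frozenset(self.pair)
        if len(self.pair) != 2:
            raise ValueError(f"pair must have two distinct members: {set(self.pair)}")


def merge_evidence(records) -> list[InteractionEvidence]:
    """One record per unordered pair; evidence sets unioned across
    duplicates. Self-interaction records are dropped with a warning."""
    merged: dict[frozenset, InteractionEvidence] = {}
    n_self = 0
    for rec in records:
        pair = frozenset(rec.pair)
        if len(pair) != 2:
            n_self += 1
            continue
        if pair in merged:
            m = merged[pair]
            m.databases |= rec.databases
            m.methods |= rec.methods
            m.pmids |= rec.pmids
            m.domain_support = m.domain_support or rec.domain_support
        else:
            merged[pair] = InteractionEvidence(
                pair=pair,
                databases=set(rec.databases),
                methods=set(rec.methods),
                pmids=set(rec.pmids),
                domain_support=bool(rec.domain_support),
            )
    if n_self:
        warnings.warn(f"dropped {n_self} self-interaction record(s)")
    return list(merged.values())


def rule_provenance(record: InteractionEvidence) -> dict[str, bool]:
    """Which of the four HC rules an evidence record satisfies."""
    return {
        "multi_database": len(record.databases) >= 2,
        "multi_method": len(record.methods) >= 2,
        "domain_support": bool(record.domain_support),
        "multi_pmid": len(record.pmids) >= 2,
    }


def hc_filter(
    records,
) -> tuple[list[InteractionEvidence], pd.DataFrame]:
    """High-confidence subset plus a per-record rule provenance table.

    A record passes if at least one rule fires. The provenance DataFrame
    has one row per *input* record (columns: protein_a, protein_b, the four
    rule flags, passed), so failures are inspectable too.
    """
    passed = []
    rows = []
    for rec in records:
        prov = rule_provenance(rec)
        ok = any(prov.values())
        if ok:
            passed.append(rec)
        a, b = sorted(rec.pair)
        rows.append({"protein_a": a, "protein_b": b, **prov, "passed": ok})
    return passed, pd.DataFrame(rows, columns=["protein_a", "protein_b", *RULE_NAMES, "passed"])


def build_network(records) -> nx.Graph:
    """Undirected graph over the record pairs (evidence kept on edges)."""
    g = nx.Graph()
    for rec in records:
        a, b = sorted(rec.pair)
        g.add_edge(a, b, databases=rec.databases, methods=rec.methods,
                   pmids=rec.pmids, domain_support=rec.domain_support)
    return g


def call_hubs(network: nx.Graph, threshold: int = HUB_DEGREE_THRESHOLD) -> set:
    """Nodes with degree >= threshold (default 5)."""
    return {n for n, d in network.degree() if d >= threshold}


def attach_hub_attribute(
    attribute_table: pd.DataFrame,
    hubs: set,
    gene_to_protein=None,
) -> pd.DataFrame:
    """Set each gene's Hub bit from the HC-network hub calls.

    ``gene_to_protein`` maps gene IDs to protein node IDs; identity by
    default. Genes whose protein is absent from the network get Hub=0.
    """
    out = attribute_table.copy()
    if gene_to_protein is None:
        gene_to_protein = {g: g for g in out.index}
    out["Hub"] = [int(gene_to_protein.get(g) in hubs) for g in out.index]
    return out
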