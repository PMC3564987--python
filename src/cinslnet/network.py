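"""CIN-centred negative genetic-interaction network and hub extraction.

Starting from raw SGA interaction records (query, array, score, p-value),
this module applies the reproducibility/strength filter (p < 0.05 and score
at most -0.20 by default), restricts to interactions whose query is a CIN
gene, and summarises each array-side gene by its degree to the CIN query
set. Genes whose CIN degree clears a threshold (40 by default, mirroring the
">= 40 negative interactions with CIN genes" hub filter; 5 is the analogous
filter against a cancer-ortholog query subset) are reported as hubs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "call_interactions",
    "build_cin_network",
    "CINNetwork",
    "degree_to_set",
    "filter_hubs",
    "group_by_function",
]

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_SCORE_THRESHOLD = -0.20
UNANNOTATED = "unannotated"


def _validate_records(records: pd.DataFrame) -> None:
    required = {"query", "array", "score", "p_value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"interaction records missing columns: {sorted(missing)}")
    if (records["query"] == records["array"]).any():
        raise ValueError("self-interactions (query == array) are not allowed")
    p = records["p_value"]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_value outside [0, 1]")


def call_interactions(records: pd.DataFrame,
                      p_threshold: float = DEFAULT_P_THRESHOLD,
                      score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                      ) -> pd.DataFrame:
    """Filter for reproducible, strong negative interactions.

    Retains records with p_value strictly below ``p_threshold`` and score at
    most ``score_threshold`` (boundary inclusive on the score: the
    conventional reading of a stated score cut-off; the p-value boundary is
    exclusive as written "P < 0.05").
    """
    _validate_records(records)
    keep = (records["p_value"] < p_threshold) & (records["score"] <= score_threshold)
    return records.loc[keep].reset_index(drop=True)


@dataclass
class CINNetwork:
    """Bipartite-style negative-interaction network: CIN queries vs partners.

    ``edges`` has columns query, array, score with one row per (query, array)
    pair (duplicates collapsed to the most negative score). The query side is
    restricted to CIN genes; asymmetry is deliberate — the CIN genes are the
    screen queries.
    """

    edges: pd.DataFrame
    cin_queries: frozenset[str]
    _adj: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        grouped = self.edges.groupby("array", sort=False)["query"]
        self._adj = {a: frozenset(qs) for a, qs in grouped.apply(frozenset).items()}

    @property
    def partners(self) -> frozenset[str]:
        """Array-side genes with at least one retained CIN interaction."""
        return frozenset(self._adj)

    def queries_of(self, gene: str) -> frozenset[str]:
        """Distinct CIN queries adjacent to an array-side gene."""
        return self._adj.get(gene, frozenset())

    def degree(self, gene: str) -> int:
        return len(self.queries_of(gene))

    def to_networkx(self) -> nx.Graph:
        """Bipartite graph with node attribute ``side`` and edge ``score``."""
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_node(row.query, side="query")
            g.add_node(row.array, side="array")
            g.add_edge(row.query, row.array, score=row.score)
        return g

    def write_sif(self, path: str | Path, relation: str = "gi") -> None:
        """Export edges in SIF format for network viewers."""
        with open(path, "w") as fh:
            for row in self.edges.itertuples(index=False):
                fh.write(f"{row.query}\t{relation}\t{row.array}\n")


def build_cin_network(records: pd.DataFrame,
                      cin_queries: Iterable[str],
                      score_cutoff: float | None = None) -> CINNetwork:
    """Restrict filtered interaction records to CIN queries.

    ``records`` should already have passed :func:`call_interactions`.
    Duplicate (query, array) measurements are collapsed, keeping the most
    negative score. ``score_cutoff`` optionally applies an extra score filter
    (score <= cutoff) on top of the upstream call, for pooled public data
    where only the sign convention is known.
    """
    cin = frozenset(cin_queries)
    sub = records[records["query"].isin(cin)]
    if score_cutoff is not None:
        sub = sub[sub["score"] <= score_cutoff]
    collapsed = (sub.groupby(["query", "array"], as_index=False, sort=True)["score"]
                    .min())
    return CINNetwork(edges=collapsed.reset_index(drop=True), cin_queries=cin)


def degree_to_set(network: CINNetwork, gene: str) -> int:
    """Number of distinct CIN queries interacting with ``gene`` (0 if absent)."""
    return network.degree(gene)


def filter_hubs(network: CINNetwork, min_degree: int,
                annotation: pd.DataFrame) -> pd.DataFrame:
    """Array-side genes with at least ``min_degree`` CIN interactions.

    The boundary is inclusive (a degree-40 gene passes min_degree=40).
    Returns columns gene, cin_degree, is_cin, functional_group, sorted by
    descending degree with ties broken by gene ID.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    ann = annotation.set_index("gene")
    rows = []
    for gene in sorted(network.partners):
        deg = network.degree(gene)
        if deg < min_degree:
            continue
        if gene in ann.index:
            is_cin = bool(ann.at[gene, "is_cin"])
            group = ann.at[gene, "functional_group"]
            if pd.isna(group):
                group = UNANNOTATED
        else:
            is_cin, group = False, UNANNOTATED
        rows.append((gene, deg, is_cin, group))
    out = pd.DataFrame(rows, columns=["gene", "cin_degree", "is_cin",
                                      "functional_group"])
    return (out.sort_values(["cin_degree", "gene"],
                            ascending=[False, True], kind="mergesort")
               .reset_index(drop=True))


def group_by_function(genes: Iterable[str],
                      annotation: pd.DataFrame) -> dict[str, list[str]]:
    """Partition genes by their annotated functional group.

    Genes missing from the annotation (or with a null group) fall into
    ``"unannotated"``. Group lists are sorted; group sizes sum to the number
    of distinct input genes.
    """
    ann = annotation.set_index("gene")["functional_group"]
    out: dict[str, list[str]] = {}
    for gene in sorted(set(genes)):
        group = ann.get(gene, UNANNOTATED)
        if pd.isna(group):
            group = UNANNOTATED
        out.setdefault(str(group), []).append(gene)
    return out
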