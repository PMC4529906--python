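"""Assemble significant subpathways into a per-dataset disease network.

The disease network is simply the union graph of every chain that survives
the significance filter: one node per gene, one signed edge per distinct
``(source, target, sign)``, each edge tagged with the KEGG pathway ids and
the number of member chains that contributed it. Networks are built per
dataset — comparing diseases means comparing their networks, never pooling
their chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .pathway_io import format_subpathway_notation
from .subpathway_stats import DEFAULT_ALPHA, ScoredSubpathway, significant_subpathways

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 100


@dataclass
class DiseaseNetwork:
    """Union graph of one dataset's significant subpathways.

    ``union_graph`` is a :class:`networkx.MultiDiGraph` keyed by edge sign;
    each edge carries ``sign``, ``pathways`` (originating pathway ids) and
    ``support`` (number of member chains using it).
    """

    dataset_id: str
    alpha: float
    subpathways: list[ScoredSubpathway] = field(default_factory=list)
    union_graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    @property
    def genes(self) -> set[str]:
        return set(self.union_graph.nodes)

    @property
    def pathway_ids(self) -> set[str]:
        return {s.subpathway.pathway_id for s in self.subpathways}

    def pathways_containing(self, gene: str) -> set[str]:
        """Pathway ids of member subpathways that contain ``gene``."""
        gene = gene.upper()
        return {
            s.subpathway.pathway_id
            for s in self.subpathways
            if gene in s.subpathway.nodes
        }


def build_network(
    scored: list[ScoredSubpathway], alpha: float = DEFAULT_ALPHA
) -> DiseaseNetwork:
    """Filter chains at ``alpha`` and union the survivors into one graph.

    All chains must come from a single dataset; an empty result is a valid
    (logged) outcome.
    """
    dataset_ids = {s.dataset_id for s in scored}
    if len(dataset_ids) > 1:
        raise ValueError(
            f"chains from multiple datasets: {', '.join(sorted(dataset_ids))}"
        )
    dataset_id = dataset_ids.pop() if dataset_ids else "empty"
    members = significant_subpathways(scored, alpha)
    graph = nx.MultiDiGraph(dataset_id=dataset_id)
    for s in members:
        for u, v, sign in s.subpathway.edges():
            if graph.has_edge(u, v, key=sign):
                data = graph.edges[u, v, sign]
                data["pathways"].add(s.subpathway.pathway_id)
                data["support"] += 1
            else:
                graph.add_edge(
                    u, v, key=sign, sign=sign,
                    pathways={s.subpathway.pathway_id}, support=1,
                )
    if not members:
        logger.info("no significant subpathways at alpha=%g for %s", alpha, dataset_id)
    else:
        logger.info(
            "%s network: %d subpathways (p < %g), %d genes, %d edges",
            dataset_id, len(members), alpha,
            graph.number_of_nodes(), graph.number_of_edges(),
        )
    return DiseaseNetwork(dataset_id, alpha, members, graph)


def _rank_key(s: ScoredSubpathway) -> tuple[float, str, str]:
    return (
        s.p_value,
        s.subpathway.pathway_id,
        format_subpathway_notation(s.subpathway, s.fold_changes),
    )


def top_k_summary(network: DiseaseNetwork, k: int = DEFAULT_TOP_K) -> list[ScoredSubpathway]:
    """The ``min(k, available)`` most significant member chains.

    Sorted by ascending P-value; ties broken lexicographically by
    ``(pathway_id, formatted chain string)`` so the ranking is a total order
    and identical across runs.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return sorted(network.subpathways, key=_rank_key)[:k]


def report_table(
    subpathways: list[ScoredSubpathway], fcs: dict[str, float] | None = None
) -> pd.DataFrame:
    """Tabulate chains as (KEGG pathway, chain notation with fold-changes, P).

    ``fcs`` optionally overrides the per-chain stored fold-changes (e.g. to
    print a shared dataset-wide table).
    """
    rows = []
    for s in subpathways:
        chain_fcs = fcs if fcs is not None else s.fold_changes
        rows.append(
            {
                "kegg_pathway": s.subpathway.pathway_id,
                "subpathway": format_subpathway_notation(s.subpathway, chain_fcs),
                "consistent_edges": s.consistent_edges,
                "total_edges": s.total_edges,
                "p_value": s.p_value,
                "dataset_id": s.dataset_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kegg_pathway", "subpathway", "consistent_edges",
            "total_edges", "p_value", "dataset_id",
        ],
    )
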