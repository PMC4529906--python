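"""Decompose a signed pathway graph into all simple directed paths.

A "subpathway" is a linear, repeat-free chain of genes traversed along
directed edges inside a single pathway; enumeration never crosses pathway
boundaries. The number of simple paths grows exponentially with the length
cap, so enumeration is bounded both by ``max_nodes`` (default 10, which
covers the longest chain the method reports) and by a total path-count
budget.
"""

from __future__ import annotations

import logging

from .errors import BudgetExceededError
from .pathway_io import SignedPathwayGraph, Subpathway

logger = logging.getLogger(__name__)

DEFAULT_MAX_NODES = 10
DEFAULT_PATH_BUDGET = 1_000_000


def enumerate_subpathways(
    graph: SignedPathwayGraph,
    min_nodes: int = 2,
    max_nodes: int = DEFAULT_MAX_NODES,
    path_budget: int = DEFAULT_PATH_BUDGET,
) -> list[Subpathway]:
    """Enumerate every simple directed path with ``min_nodes..max_nodes`` nodes.

    Each path carries the signs of the edges it traverses. The output order
    is deterministic: lexicographic by ``(pathway_id, node chain)``, i.e. by
    start gene and then by the successive genes of the path.

    Raises
    ------
    ValueError
        If ``max_nodes < 2`` or ``min_nodes`` is outside ``[2, max_nodes]``.
    BudgetExceededError
        If the graph yields more than ``path_budget`` paths; lower
        ``max_nodes`` or raise the budget.
    """
    if max_nodes < 2:
        raise ValueError(f"max_nodes must be >= 2, got {max_nodes}")
    if not 2 <= min_nodes <= max_nodes:
        raise ValueError(
            f"need 2 <= min_nodes <= max_nodes, got min={min_nodes} max={max_nodes}"
        )

    adjacency: dict[str, list[tuple[str, int]]] = {n: [] for n in graph.nodes}
    for u, v, s in graph.edges:
        adjacency[u].append((v, s))
    for succ in adjacency.values():
        succ.sort()

    paths: list[Subpathway] = []
    # Iterative DFS; the stack holds (node, sign-into-node) frames per depth.
    node_stack: list[str] = []
    sign_stack: list[int] = []
    on_path: set[str] = set()

    def visit(node: str) -> None:
        node_stack.append(node)
        on_path.add(node)
        if min_nodes <= len(node_stack) <= max_nodes:
            if len(paths) >= path_budget:
                raise BudgetExceededError(
                    f"more than {path_budget} subpathways in {graph.pathway_id}; "
                    "lower max_nodes or raise the path budget"
                )
            paths.append(
                Subpathway(graph.pathway_id, tuple(node_stack), tuple(sign_stack))
            )
        if len(node_stack) < max_nodes:
            for succ, sign in adjacency[node]:
                if succ not in on_path:
                    sign_stack.append(sign)
                    visit(succ)
                    sign_stack.pop()
        on_path.discard(node)
        node_stack.pop()

    for start in sorted(graph.nodes):
        visit(start)
    paths.sort(key=lambda p: (p.pathway_id, p.nodes))
    logger.info(
        "enumerated %d subpathways (%d..%d nodes) in %s",
        len(paths), min_nodes, max_nodes, graph.pathway_id,
    )
    return paths


def enumerate_all(
    graphs: list[SignedPathwayGraph],
    min_nodes: int = 2,
    max_nodes: int = DEFAULT_MAX_NODES,
    path_budget: int = DEFAULT_PATH_BUDGET,
) -> list[Subpathway]:
    """Enumerate subpathways per pathway and concatenate in pathway-id order."""
    out: list[Subpathway] = []
    for graph in sorted(graphs, key=lambda g: g.pathway_id):
        out.extend(
            enumerate_subpathways(graph, min_nodes, max_nodes, path_budget)
        )
    return out
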