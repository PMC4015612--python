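"""Hub identification and network-module extraction.

A hub is a node whose number of interaction partners *covered by the
expression data* reaches a threshold (default 5); the hub plus those
partners form a network module.  Modules may overlap: a hub can appear
as a partner in another hub's module.
"""
from __future__ import annotations

import logging

from .data_model import ExpressionMatrix, Network, NetworkModule

logger = logging.getLogger(__name__)

DEFAULT_MIN_PARTNERS = 5


def clean_network(raw_edges, directed: bool = False) -> Network:
    """Canonicalise an edge list: drop self-loops, merge duplicates.

    For undirected networks orientation-reversed duplicates are merged
    into a single lexicographically ordered pair.  Removal counts are
    logged; an empty input yields an empty network.
    """
    seen = set()
    n_self = 0
    n_dup = 0
    for a, b in raw_edges:
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            n_self += 1
            continue
        edge = (a, b) if directed or a < b else (b, a)
        if edge in seen:
            n_dup += 1
        else:
            seen.add(edge)
    if n_self or n_dup:
        logger.info("clean_network: removed %d self-loops, %d duplicate edges",
                    n_self, n_dup)
    return Network(frozenset(seen), directed=directed)


def identify_hubs(network: Network, expr: ExpressionMatrix,
                  min_partners: int = DEFAULT_MIN_PARTNERS) -> list[NetworkModule]:
    """Extract one module per hub with >= ``min_partners`` covered partners.

    Partners absent from the expression matrix are dropped before the
    degree is counted; a candidate hub whose own expression row is
    missing is silently excluded (with a warning).  For directed
    (microRNA -> target) networks only source nodes are hub candidates.
    Modules are returned sorted by hub ID, independent of edge order.
    """
    if min_partners < 1:
        raise ValueError("min_partners must be >= 1")
    genes = set(expr.gene_ids)
    adjacency: dict[str, set] = {}
    for a, b in network.edges:
        adjacency.setdefault(a, set()).add(b)
        if not network.directed:
            adjacency.setdefault(b, set()).add(a)
    if network.edges and not (network.nodes & genes):
        logger.warning("no overlap between network nodes and expression genes")
        return []
    n_hub_no_expr = 0
    modules: list[NetworkModule] = []
    for hub in sorted(adjacency):
        partners = sorted((adjacency[hub] - {hub}) & genes)
        if len(partners) < min_partners:
            continue
        if hub not in genes:
            n_hub_no_expr += 1
            continue
        modules.append(NetworkModule(hub=hub, partners=tuple(partners)))
    if n_hub_no_expr:
        logger.warning("excluded %d hub candidates lacking an expression row",
                       n_hub_no_expr)
    if not modules:
        logger.warning("no modules found at min_partners=%d", min_partners)
    return modules
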