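"""Whole-network and node-level measures on confirmed binary networks.

All measures follow the Freeman conventions for undirected binary
graphs and are reported as percentages:

* density            = ties / (n(n-1)/2)
* degree centrality  = degree / (n-1)
* betweenness        = sum over pairs (s, t) of the share of geodesics
                       through the node, / ((n-1)(n-2)/2); pairs in
                       different components contribute 0
* centralization     = sum of (max centrality - centrality) over nodes,
                       scaled by the maximum attainable sum (the star):
                       (n-2) for degree, (n-1) for betweenness, with
                       centralities as fractions

Internal computation is full precision; round only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .build import ConfirmedNetwork
from .errors import UndefinedMeasureError, ValidationError


def _require_binary(net: ConfirmedNetwork, min_n: int, what: str) -> None:
    if net.n < min_n:
        raise UndefinedMeasureError(f"{what} undefined for n={net.n} < {min_n}")
    if not net.is_binary:
        raise ValidationError(f"{what} requires a binarized network")


def density(net: ConfirmedNetwork) -> float:
    """Realized undirected ties over possible ties, in percent."""
    _require_binary(net, 2, "density")
    ties = int(np.triu(net.values).sum())
    possible = net.n * (net.n - 1) // 2
    return 100.0 * ties / possible


def degree_centrality(net: ConfirmedNetwork) -> dict[str, float]:
    """Normalized degree centrality per node: degree / (n-1), in percent."""
    _require_binary(net, 2, "degree centrality")
    deg = net.values.sum(axis=1)
    return {
        node: 100.0 * int(d) / (net.n - 1) for node, d in zip(net.nodes, deg)
    }


def degree_centralization(net: ConfirmedNetwork) -> float:
    """Freeman degree centralization in percent; 100 for a star, 0 when
    all degrees are equal."""
    _require_binary(net, 3, "degree centralization")
    c = net.values.sum(axis=1) / (net.n - 1)  # fractions
    return 100.0 * float((c.max() - c).sum()) / (net.n - 2)


def betweenness_centrality(net: ConfirmedNetwork) -> dict[str, float]:
    """Normalized geodesic betweenness centrality per node, in percent.

    All shortest paths count; contributions accrue only within connected
    components.
    """
    _require_binary(net, 3, "betweenness centrality")
    bc = nx.betweenness_centrality(net.to_graph(), normalized=True)
    return {node: 100.0 * bc[node] for node in net.nodes}


def betweenness_centralization(net: ConfirmedNetwork) -> float:
    """Freeman betweenness centralization in percent (star graph = 100)."""
    _require_binary(net, 3, "betweenness centralization")
    b = np.array(
        list(nx.betweenness_centrality(net.to_graph(), normalized=True).values())
    )
    return 100.0 * float((b.max() - b).sum()) / (net.n - 1)


def isolates(net: ConfirmedNetwork) -> list[str]:
    """Nodes with no ties, in roster order."""
    _require_binary(net, 2, "isolates")
    deg = net.values.sum(axis=1)
    return [node for node, d in zip(net.nodes, deg) if d == 0]


@dataclass(frozen=True)
class NetworkMeasures:
    """Whole-network summary for one layer."""

    layer: str
    n_nodes: int
    density: float
    degree_centralization: float
    betweenness_centralization: float
    isolates: tuple[str, ...]


def node_measures(net: ConfirmedNetwork) -> pd.DataFrame:
    """Per-node table with columns ``normalized_degree`` and
    ``normalized_betweenness`` (percent), indexed by org_id in roster
    order."""
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    return pd.DataFrame(
        {
            "normalized_degree": [deg[v] for v in net.nodes],
            "normalized_betweenness": [btw[v] for v in net.nodes],
        },
        index=pd.Index(net.nodes, name="org_id"),
    )


def network_measures(net: ConfirmedNetwork) -> NetworkMeasures:
    layer = net.layer.name if net.layer else ""
    return NetworkMeasures(
        layer=layer,
        n_nodes=net.n,
        density=density(net),
        degree_centralization=degree_centralization(net),
        betweenness_centralization=betweenness_centralization(net),
        isolates=tuple(isolates(net)),
    )
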