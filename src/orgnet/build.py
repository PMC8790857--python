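"""Directed valued matrices per layer and the confirmation procedure.

Survey reports are one-sided perceptions, so a dyad only counts as a
relationship when both organizations acknowledge it.  For binary layers a
confirmed tie requires both directed reports to be positive; for ordinal
layers (intensity, contact frequency) the confirmed value is the minimum
of the two directed reports, which collapses to the binary rule when the
scale has a single positive level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import DyadicReport, RelationLayer, Roster, get_layer
from .errors import ValidationError

log = logging.getLogger(__name__)


def _check_matrix(values: np.ndarray, n: int, layer: RelationLayer | None) -> None:
    if values.shape != (n, n):
        raise ValidationError(f"matrix shape {values.shape} != ({n}, {n})")
    if np.diag(values).any():
        raise ValidationError("matrix diagonal must be zero")
    if (values < 0).any():
        raise ValidationError("matrix values must be non-negative")
    if layer is not None and (values > layer.scale.max_level).any():
        raise ValidationError(
            f"matrix values exceed {layer.scale.name} scale "
            f"maximum {layer.scale.max_level}"
        )


@dataclass(frozen=True)
class DirectedValuedNetwork:
    """Pre-confirmation state: entry (i, j) is i's report about j.

    ``nonrespondents`` marks nodes whose entire row is missing (no survey
    returned) rather than genuinely zero; their dyads are unconfirmable.
    """

    nodes: tuple[str, ...]
    values: np.ndarray
    layer: RelationLayer | None = None
    nonrespondents: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        object.__setattr__(self, "values", values)
        _check_matrix(values, len(self.nodes), self.layer)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node labels")
        unknown = self.nonrespondents - set(self.nodes)
        if unknown:
            raise ValidationError(f"nonrespondents not in node set: {sorted(unknown)}")
        rows = [k for k, v in enumerate(self.nodes) if v in self.nonrespondents]
        if values[rows, :].any():
            raise ValidationError("non-respondent rows must be empty (missing)")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def missing_mask(self) -> np.ndarray:
        """n x n boolean mask: True where the directed report is missing
        (the reporting row belongs to a non-respondent)."""
        row_missing = np.array(
            [v in self.nonrespondents for v in self.nodes], dtype=bool
        )
        mask = np.repeat(row_missing[:, None], self.n, axis=1)
        np.fill_diagonal(mask, False)
        return mask

    def density_pct(self) -> float:
        """Directed-report density: positive arcs / possible arcs, in %.

        Possible arcs count only those a respondent could have reported.
        """
        reportable = ~self.missing_mask
        np.fill_diagonal(reportable, False)
        possible = int(reportable.sum())
        if possible == 0:
            return 0.0
        return 100.0 * float((self.values > 0).sum()) / possible


@dataclass(frozen=True)
class ConfirmedNetwork:
    """Symmetric ordinal matrix produced by mutual acknowledgement.

    Every positive entry is bounded above by both underlying directed
    reports. ``n_unconfirmable`` counts positive directed reports that
    were discarded because the other side of the dyad was missing.
    """

    nodes: tuple[str, ...]
    values: np.ndarray
    layer: RelationLayer | None = None
    n_unconfirmable: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=int)
        object.__setattr__(self, "values", values)
        _check_matrix(values, len(self.nodes), self.layer)
        if not np.array_equal(values, values.T):
            raise ValidationError("confirmed matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def is_binary(self) -> bool:
        return bool((self.values <= 1).all())

    def to_graph(self) -> nx.Graph:
        """Undirected networkx graph with tie values as the ``value``
        edge attribute; isolates are kept as nodes."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        ii, jj = np.nonzero(np.triu(self.values))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(self.nodes[i], self.nodes[j], value=int(self.values[i, j]))
        return g

    def edges(self) -> list[tuple[str, str, int]]:
        ii, jj = np.nonzero(np.triu(self.values))
        return [
            (self.nodes[i], self.nodes[j], int(self.values[i, j]))
            for i, j in zip(ii.tolist(), jj.tolist())
        ]


def build_directed(
    reports: list[DyadicReport],
    layer: RelationLayer | str,
    roster: Roster,
) -> DirectedValuedNetwork:
    """Assemble the directed valued matrix of one layer from reports.

    Entry (i, j) is i's reported value about j; unreported dyads of
    respondents are 0 (reported absence), non-respondent rows are flagged
    missing.  Duplicate reports for the same directed dyad keep the
    maximum value.
    """
    if isinstance(layer, str):
        layer = get_layer(layer)
    n = len(roster)
    values = np.zeros((n, n), dtype=int)
    relevant = [r for r in reports if r.layer == layer.name]
    if reports and not relevant:
        log.warning("no reports for layer %r; returning zero matrix", layer.name)
    nonresp = frozenset(roster.nonrespondents)
    for r in relevant:
        if r.source in nonresp:
            raise ValidationError(
                f"report from non-respondent {r.source!r} on layer {layer.name!r}"
            )
        i, j = roster.index(r.source), roster.index(r.target)
        values[i, j] = max(values[i, j], r.value)
    return DirectedValuedNetwork(roster.ids, values, layer, nonresp)


def _restrict(
    net: DirectedValuedNetwork, node_policy: str
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Return (nodes, values, confirmable-mask) under the node policy."""
    if node_policy not in ("respondents", "all-as-isolates"):
        raise ValidationError(
            f"unknown node policy {node_policy!r}; "
            "expected 'respondents' or 'all-as-isolates'"
        )
    missing_row = np.array([v in net.nonrespondents for v in net.nodes], dtype=bool)
    if node_policy == "respondents":
        keep = ~missing_row
        idx = np.where(keep)[0]
        nodes = tuple(net.nodes[k] for k in idx)
        values = net.values[np.ix_(idx, idx)]
        confirmable = np.ones_like(values, dtype=bool)
    else:
        nodes = net.nodes
        values = net.values
        confirmable = ~(missing_row[:, None] | missing_row[None, :])
    return nodes, values, confirmable


def confirm_ordinal(
    net: DirectedValuedNetwork, node_policy: str = "respondents"
) -> ConfirmedNetwork:
    """Minimum-confirmation: confirmed value(i, j) = min(report i->j,
    report j->i).

    A report of 'often' against a reciprocal 'sometimes' confirms at
    'sometimes'; any unreciprocated report confirms at 0.  Dyads with a
    missing (non-respondent) side are unconfirmable: they are removed
    (``node_policy='respondents'``, the default) or zeroed while the
    nodes are retained as structural isolates
    (``node_policy='all-as-isolates'``), and every positive report lost
    this way is counted in ``n_unconfirmable``.
    """
    nodes, values, confirmable = _restrict(net, node_policy)
    n_unconf = int((net.values > 0).sum()) - int((values > 0)[confirmable].sum())
    confirmed = np.minimum(values, values.T)
    confirmed[~confirmable] = 0
    if n_unconf:
        log.info(
            "%s: %d positive directed reports unconfirmable (missing side)",
            net.layer.name if net.layer else "?",
            n_unconf,
        )
    return ConfirmedNetwork(nodes, confirmed, net.layer, n_unconf)


def confirm_binary(
    net: DirectedValuedNetwork, node_policy: str = "respondents"
) -> ConfirmedNetwork:
    """Mutual-acknowledgement rule: tie(i, j) = 1 iff both directed
    reports are positive.  Equivalent to minimum-confirmation followed by
    binarization at the lowest positive level."""
    nodes, values, confirmable = _restrict(net, node_policy)
    n_unconf = int((net.values > 0).sum()) - int((values > 0)[confirmable].sum())
    tie = ((values > 0) & (values.T > 0) & confirmable).astype(int)
    layer = net.layer
    return ConfirmedNetwork(nodes, tie, layer, n_unconf)


def binarize(net: ConfirmedNetwork, threshold: int = 1) -> ConfirmedNetwork:
    """Binary tie iff confirmed value >= threshold (threshold must be a
    positive scale level; 0 would produce the complete graph)."""
    max_level = net.layer.scale.max_level if net.layer else int(net.values.max(initial=1))
    if not 1 <= threshold <= max_level:
        raise ValidationError(
            f"binarization threshold {threshold} outside 1..{max_level}"
        )
    return ConfirmedNetwork(
        net.nodes,
        (net.values >= threshold).astype(int),
        net.layer,
        net.n_unconfirmable,
    )
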