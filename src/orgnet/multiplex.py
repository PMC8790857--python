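"""Multiplexity: how many nutrition working relationships connect a dyad.

The four confirmed nutrition-layer networks (policy, capacity, knowledge,
implementation) are stacked on an identical node set; the multiplexity
score of a dyad is the number of layers on which it holds a confirmed
tie, ranging 0-4 (score-0 dyads are absent from the multiplex edge list).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .build import ConfirmedNetwork
from .core import NUTRITION_LAYERS
from .errors import AlignmentError, ValidationError

#: Canonical layer order for all multiplex outputs.
LAYER_ORDER: tuple[str, ...] = NUTRITION_LAYERS


@dataclass(frozen=True)
class MultiplexNetwork:
    nodes: tuple[str, ...]
    layers: dict[str, ConfirmedNetwork]
    scores: np.ndarray

    @property
    def n(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[str, str, int, dict[str, int]]]:
        """Dyads with score >= 1: (source, target, score, per-layer flags)."""
        out = []
        ii, jj = np.nonzero(np.triu(self.scores))
        for i, j in zip(ii.tolist(), jj.tolist()):
            flags = {
                name: int(self.layers[name].values[i, j] > 0)
                for name in self.layers
            }
            out.append((self.nodes[i], self.nodes[j], int(self.scores[i, j]), flags))
        return out


def multiplexity_matrix(
    layers: dict[str, ConfirmedNetwork] | list[ConfirmedNetwork],
) -> MultiplexNetwork:
    """Elementwise sum of the binary layer matrices.

    Layers must be binarized and share an identical ordered node set;
    otherwise an :class:`AlignmentError` lists the differences.
    """
    if not isinstance(layers, dict):
        layers = {
            (net.layer.name if net.layer else f"layer{k}"): net
            for k, net in enumerate(layers)
        }
    ordered = [name for name in LAYER_ORDER if name in layers]
    ordered += [name for name in layers if name not in ordered]
    if not ordered:
        raise ValidationError("no layers supplied")
    ref = layers[ordered[0]]
    for name in ordered[1:]:
        net = layers[name]
        if net.nodes != ref.nodes:
            only_ref = sorted(set(ref.nodes) - set(net.nodes))
            only_net = sorted(set(net.nodes) - set(ref.nodes))
            raise AlignmentError(
                f"layer {name!r} node set differs from {ordered[0]!r}: "
                f"missing {only_ref}, extra {only_net}"
                if (only_ref or only_net)
                else f"layer {name!r} node order differs from {ordered[0]!r}"
            )
    for name in ordered:
        if not layers[name].is_binary:
            raise ValidationError(f"layer {name!r} is not binarized")
    scores = np.zeros((ref.n, ref.n), dtype=int)
    for name in ordered:
        scores += layers[name].values
    return MultiplexNetwork(ref.nodes, {n: layers[n] for n in ordered}, scores)


def multiplex_summary(mx: MultiplexNetwork) -> dict:
    """Dyad counts at each score 1..k and per-node tie statistics.

    Returns ``{"dyad_counts": {score: count}, "node_stats": DataFrame}``
    where node_stats has the per-node maximum and mean multiplexity over
    that node's multiplex ties (NaN mean for nodes with none).
    """
    k = len(mx.layers)
    upper = np.triu(mx.scores)
    dyad_counts = {s: int((upper == s).sum()) for s in range(1, k + 1)}
    max_mx, mean_mx = [], []
    for i in range(mx.n):
        row = mx.scores[i]
        tied = row[row > 0]
        max_mx.append(int(tied.max()) if tied.size else 0)
        mean_mx.append(float(tied.mean()) if tied.size else float("nan"))
    node_stats = pd.DataFrame(
        {"max_multiplexity": max_mx, "mean_multiplexity": mean_mx},
        index=pd.Index(mx.nodes, name="org_id"),
    )
    return {"dyad_counts": dyad_counts, "node_stats": node_stats}
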