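"""Measure report tables: one row per organization, degree and
betweenness columns per network, percentages at one decimal place, plus
a whole-network summary block (density, centralizations, isolates)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .build import ConfirmedNetwork
from .measures import network_measures, node_measures
from .multiplex import MultiplexNetwork

log = logging.getLogger(__name__)

SENTINEL = "NA"


def measures_report(
    networks: dict[str, ConfirmedNetwork],
    layer_order: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the per-node and per-network measure tables.

    ``networks`` maps layer name to a confirmed *binary* network; all
    layers must share one node set (the analysed respondents).  Returns
    ``(nodes_df, summary_df)`` with percentages rounded to one decimal.
    A requested layer absent from ``networks`` yields sentinel columns
    and a warning rather than an error.
    """
    order = list(layer_order) if layer_order is not None else list(networks)
    present = [name for name in order if name in networks]
    if not present:
        raise ValueError("no layer networks supplied")
    ref = networks[present[0]]
    nodes_df = pd.DataFrame(index=pd.Index(ref.nodes, name="org_id"))
    summary_rows = []
    for name in order:
        if name not in networks:
            log.warning("layer %r missing from report input", name)
            nodes_df[f"degree_{name}"] = SENTINEL
            nodes_df[f"betweenness_{name}"] = SENTINEL
            continue
        nm = node_measures(networks[name])
        nodes_df[f"degree_{name}"] = nm["normalized_degree"].round(1)
        nodes_df[f"betweenness_{name}"] = nm["normalized_betweenness"].round(1)
        s = network_measures(networks[name])
        summary_rows.append(
            {
                "layer": name,
                "n_nodes": s.n_nodes,
                "density": round(s.density, 1),
                "degree_centralization": round(s.degree_centralization, 1),
                "betweenness_centralization": round(s.betweenness_centralization, 1),
                "n_isolates": len(s.isolates),
                "isolates": ";".join(s.isolates),
            }
        )
    return nodes_df, pd.DataFrame(summary_rows)


def write_measures_report(
    nodes_df: pd.DataFrame, summary_df: pd.DataFrame, path: str | Path
) -> None:
    """Write both blocks to one delimited text file, separated by a
    blank line.  Byte-identical across reruns on identical inputs."""
    text = nodes_df.to_csv(float_format="%.1f")
    text += "\n" + summary_df.to_csv(index=False, float_format="%.1f")
    Path(path).write_text(text)


def write_multiplex_edges(mx: MultiplexNetwork, path: str | Path) -> None:
    """Multiplex edge list: source, target, score, one 0/1 flag column
    per layer.  Score-0 dyads are absent."""
    layer_names = list(mx.layers)
    rows = []
    for s, t, score, flags in mx.edges():
        rows.append([s, t, score] + [flags[name] for name in layer_names])
    df = pd.DataFrame(rows, columns=["source", "target", "score"] + layer_names)
    df.to_csv(path, index=False)
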