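"""Styled network plots.

Visual encodings follow sociometric convention for these networks: node
shape bins the number of countries of operation, node colour is the
organization type, node size scales with betweenness centrality (with a
floor so isolates stay visible), and edge colour encodes the tie value
(intensity level, contact frequency, or multiplexity score).  Layout is
force-directed with a fixed seed; isolates are parked along the bottom
margin instead of drifting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.lines import Line2D

from .build import ConfirmedNetwork
from .core import ORG_TYPES, Roster
from .errors import ValidationError
from .measures import betweenness_centrality
from .multiplex import MultiplexNetwork

#: Country-count shape bins (inclusive ranges) and their markers.
COUNTRY_BINS: tuple[tuple[int, int], ...] = ((0, 2), (3, 5), (6, 8))
_BIN_MARKERS = ("o", "s", "^")

_TYPE_COLORS = {t: plt.get_cmap("tab10")(k) for k, t in enumerate(ORG_TYPES)}

#: Ordinal edge palettes keyed by the maximum level.
_EDGE_PALETTES = {
    1: {1: "#555555"},
    3: {1: "#9ecae1", 2: "#3182bd", 3: "#08519c"},  # intensity ladder
    4: {1: "#bdd7e7", 2: "#6baed6", 3: "#31a354", 4: "#de2d26"},  # frequency / multiplexity
}

_VALID_STYLE_KEYS = {
    "node_shape_by",
    "node_color_by",
    "node_size_by",
    "edge_color_by",
    "layout_seed",
    "size_floor",
    "size_scale",
}


@dataclass(frozen=True)
class PlotStyle:
    node_shape_by: str = "countries"
    node_color_by: str = "org_type"
    node_size_by: str = "betweenness"
    edge_color_by: str = "value"
    layout_seed: int = 0
    size_floor: float = 60.0
    size_scale: float = 12.0

    def __post_init__(self) -> None:
        allowed = {
            "node_shape_by": {"countries", "none"},
            "node_color_by": {"org_type", "none"},
            "node_size_by": {"betweenness", "none"},
            "edge_color_by": {"value", "none"},
        }
        for key, ok in allowed.items():
            if getattr(self, key) not in ok:
                raise ValidationError(
                    f"style {key}={getattr(self, key)!r}; valid: {sorted(ok)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PlotStyle":
        unknown = set(d) - _VALID_STYLE_KEYS
        if unknown:
            raise ValidationError(
                f"unknown style keys {sorted(unknown)}; "
                f"valid keys: {sorted(_VALID_STYLE_KEYS)}"
            )
        return cls(**d)


def _country_bin(n: int) -> int:
    for k, (lo, hi) in enumerate(COUNTRY_BINS):
        if lo <= n <= hi:
            return k
    raise ValidationError(f"country count {n} outside all bins")


def _layout(g: nx.Graph, seed: int) -> dict[str, np.ndarray]:
    """Force-directed layout for the connected part; isolates evenly
    spaced along a bottom margin."""
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    connected = [v for v in g.nodes if g.degree(v) > 0]
    pos = (
        nx.spring_layout(g.subgraph(connected), seed=seed)
        if connected
        else {}
    )
    if pos:
        xs = [p[0] for p in pos.values()]
        ys = [p[1] for p in pos.values()]
        x0, x1, y0 = min(xs), max(xs), min(ys)
    else:
        x0, x1, y0 = -1.0, 1.0, 0.0
    for k, v in enumerate(sorted(isolated)):
        frac = (k + 0.5) / len(isolated)
        pos[v] = np.array([x0 + frac * (x1 - x0), y0 - 0.35 * (x1 - x0 or 1.0)])
    return pos


def plot_network(
    net: ConfirmedNetwork | MultiplexNetwork,
    out_path: str | Path,
    roster: Roster | None = None,
    style: PlotStyle | None = None,
    title: str | None = None,
) -> dict[str, np.ndarray]:
    """Render a confirmed network or a multiplex network to SVG or PNG.

    Returns the node layout coordinates (deterministic given
    ``style.layout_seed``).  The input network is never mutated.
    """
    style = style or PlotStyle()
    out_path = Path(out_path)
    if out_path.suffix.lower() not in (".svg", ".png"):
        raise ValidationError(f"unsupported image format {out_path.suffix!r}")

    if isinstance(net, MultiplexNetwork):
        nodes, values = net.nodes, net.scores
        binary = ConfirmedNetwork(nodes, (values > 0).astype(int))
        max_level = len(net.layers)
        edge_label = "multiplexity"
    else:
        nodes, values = net.nodes, net.values
        binary = ConfirmedNetwork(nodes, (values > 0).astype(int), net.layer)
        max_level = net.layer.scale.max_level if net.layer else int(values.max(initial=1))
        edge_label = net.layer.scale.name if net.layer else "value"

    g = binary.to_graph()
    pos = _layout(g, style.layout_seed)

    sizes = {v: style.size_floor for v in nodes}
    if style.node_size_by == "betweenness" and len(nodes) >= 3:
        btw = betweenness_centrality(binary)
        sizes = {v: style.size_floor + style.size_scale * btw[v] for v in nodes}

    fig, ax = plt.subplots(figsize=(9, 7))
    palette = _EDGE_PALETTES.get(max_level, _EDGE_PALETTES[4])
    used_levels = sorted(
        {int(values[i, j]) for i, j in zip(*np.nonzero(np.triu(values)))}
    )
    idx = {v: k for k, v in enumerate(nodes)}
    for u, v in g.edges:
        level = int(values[idx[u], idx[v]])
        color = palette.get(level, "#999999")
        ax.plot(
            [pos[u][0], pos[v][0]],
            [pos[u][1], pos[v][1]],
            color=color,
            linewidth=0.8 + 0.5 * level,
            zorder=1,
            alpha=0.85,
        )

    used_types: list[str] = []
    for v in nodes:
        org = roster[v] if roster is not None and v in roster else None
        marker = (
            _BIN_MARKERS[_country_bin(org.n_countries)]
            if style.node_shape_by == "countries" and org is not None
            else "o"
        )
        if style.node_color_by == "org_type" and org is not None:
            color = _TYPE_COLORS[org.org_type]
            if org.org_type not in used_types:
                used_types.append(org.org_type)
        else:
            color = "#888888"
        ax.scatter(
            *pos[v], s=sizes[v], marker=marker, color=color,
            edgecolors="black", linewidths=0.5, zorder=2,
        )
        ax.annotate(
            v, pos[v], fontsize=6, ha="center", va="bottom",
            xytext=(0, 4), textcoords="offset points", zorder=3,
        )

    handles = [
        Line2D([], [], color=palette.get(lv, "#999999"), lw=2,
               label=f"{edge_label} {lv}")
        for lv in used_levels
    ]
    handles += [
        Line2D([], [], marker="o", linestyle="", color=_TYPE_COLORS[t], label=t)
        for t in used_types
    ]
    if style.node_shape_by == "countries" and roster is not None:
        handles += [
            Line2D([], [], marker=m, linestyle="", color="#888888",
                   label=f"{lo}-{hi} countries")
            for (lo, hi), m in zip(COUNTRY_BINS, _BIN_MARKERS)
        ]
    if handles:
        ax.legend(handles=handles, loc="upper left", fontsize=7, frameon=False)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return pos
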