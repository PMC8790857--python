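"""End-to-end pipeline: build -> confirm -> binarize -> measures ->
multiplex -> reports and plots, with a run manifest recording the exact
configuration and every dropped row, unconfirmable report and excluded
node."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .build import binarize, build_directed, confirm_binary, confirm_ordinal
from .core import NUTRITION_LAYERS, get_layer
from .io import parse_reports, parse_roster, write_dl, write_edge_list
from .multiplex import multiplex_summary, multiplexity_matrix
from .reporting import measures_report, write_measures_report, write_multiplex_edges
from .viz import PlotStyle, plot_network


@dataclass(frozen=True)
class RunConfig:
    roster: str
    reports: str
    out: str
    layers: tuple[str, ...] = ("overall",) + NUTRITION_LAYERS
    threshold: int = 1
    node_policy: str = "respondents"
    seed: int = 0
    plots: bool = True
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "layers" in data:
            data["layers"] = tuple(data["layers"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the artifact directory.

    Writes confirmed DL matrices and edge lists per layer, the measure
    report (Table-3 shape), the multiplex edge list and summary, plots,
    and ``manifest.json``.
    """
    roster = parse_roster(config.roster)
    parsed = parse_reports(config.reports, roster, strict=config.strict)

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "dl").mkdir(exist_ok=True)

    confirmed_binary = {}
    counts = {
        "reports_accepted": len(parsed.reports),
        "reports_dropped": parsed.n_dropped,
        "unconfirmable_reports": {},
    }
    for layer_name in config.layers:
        layer = get_layer(layer_name)
        directed = build_directed(list(parsed.reports), layer, roster)
        if layer.scale.max_level == 1:
            confirmed = confirm_binary(directed, config.node_policy)
            binary = confirmed
        else:
            confirmed = confirm_ordinal(directed, config.node_policy)
            binary = binarize(confirmed, config.threshold)
        counts["unconfirmable_reports"][layer_name] = confirmed.n_unconfirmable
        write_dl(confirmed, out / "dl" / f"confirmed_{layer_name}.dl")
        write_edge_list(confirmed, out / f"confirmed_{layer_name}_edges.csv")
        confirmed_binary[layer_name] = binary
        if config.plots:
            plot_network(
                confirmed,
                out / f"network_{layer_name}.png",
                roster=roster,
                style=PlotStyle(layout_seed=config.seed),
                title=f"Confirmed {layer_name} network",
            )

    nodes_df, summary_df = measures_report(confirmed_binary, tuple(config.layers))
    write_measures_report(nodes_df, summary_df, out / "measures.csv")

    nutrition = {
        name: confirmed_binary[name]
        for name in NUTRITION_LAYERS
        if name in confirmed_binary
    }
    if len(nutrition) == len(NUTRITION_LAYERS):
        mx = multiplexity_matrix(nutrition)
        write_multiplex_edges(mx, out / "multiplex_edges.csv")
        summary = multiplex_summary(mx)
        counts["multiplex_dyad_counts"] = summary["dyad_counts"]
        if config.plots:
            plot_network(
                mx,
                out / "network_multiplex.png",
                roster=roster,
                style=PlotStyle(layout_seed=config.seed),
                title="Confirmed multiplexity",
            )

    excluded = list(roster.nonrespondents) if config.node_policy == "respondents" else []
    manifest = {
        "orgnet_version": __version__,
        "config": asdict(config),
        "counts": counts,
        "excluded_nonrespondents": excluded,
        "dropped_rows": [list(d) for d in parsed.dropped],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
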