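"""Synthetic multi-layer dyadic survey generator.

Emulates the statistical structure the analysis assumes in regional
organizational networks: a roster of ~50 organizations of 8 types,
type-homophilous sparse ordinal layers (a planted-partition blockmodel
per layer), a small set of broker organizations with elevated
cross-type tie probability, contact frequencies concentrated on
"rarely"/"sometimes", asymmetric dyadic reporting (the reason the
confirmation rule exists), and survey non-response.

The generator also returns the latent ground truth so recovery tests can
check that the pipeline finds what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import (
    NUTRITION_LAYERS,
    ORG_TYPES,
    DyadicReport,
    Organization,
    Roster,
    get_layer,
)
from .errors import ValidationError
from . import io as survey_io

#: Organization counts per type for the default roster (sums to 50).
DEFAULT_N_PER_TYPE: dict[str, int] = {
    "UN": 8,
    "multilateral": 3,
    "bilateral": 4,
    "NGO": 9,
    "academic/research": 6,
    "intergovernmental": 1,
    "foundation": 5,
    "network": 14,
}

#: Contact frequency distribution conditional on a latent tie
#: (rarely, sometimes, often, very often) — most joint work is
#: occasional.
DEFAULT_FREQUENCY_DIST: tuple[float, ...] = (0.45, 0.35, 0.13, 0.07)

#: Intensity distribution conditional on an overall tie
#: (communication, coordination, collaboration).
DEFAULT_INTENSITY_DIST: tuple[float, ...] = (0.50, 0.30, 0.20)

#: Per-layer (within-type, between-type) tie probabilities.  Chosen so
#: confirmed layer densities land in the sparse single-digit-percent
#: range typical of inter-organizational working relationships, with the
#: overall any-purpose layer several times denser.
DEFAULT_LAYER_PROBS: dict[str, tuple[float, float]] = {
    "overall": (0.45, 0.16),
    "policy": (0.20, 0.040),
    "capacity": (0.15, 0.028),
    "knowledge": (0.30, 0.060),
    "implementation": (0.18, 0.032),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    ``p_in``/``p_out`` may be single probabilities applied to every
    layer or per-layer ``{layer: p}`` mappings.  ``brokers`` designates
    nodes whose cross-type dyads are tied with probability ``p_broker``
    instead of ``p_out``.  ``discordance`` is the probability that a
    directed report deviates from the dyad's latent value — half that
    mass omits the report, half shifts it one ordinal level down (never
    up).  ``nonresponse`` is the fraction of organizations returning no
    survey.
    """

    n_per_type: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_TYPE)
    )
    layers: tuple[str, ...] = ("overall", "intensity") + NUTRITION_LAYERS
    p_in: float | dict[str, float] | None = None
    p_out: float | dict[str, float] | None = None
    n_brokers: int = 2
    p_broker: float = 0.35
    frequency_dist: tuple[float, ...] = DEFAULT_FREQUENCY_DIST
    intensity_dist: tuple[float, ...] = DEFAULT_INTENSITY_DIST
    discordance: float = 0.10
    nonresponse: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.n_per_type:
            if t not in ORG_TYPES:
                raise ValidationError(f"unknown org type {t!r}")
        for name, p in (
            ("p_broker", self.p_broker),
            ("discordance", self.discordance),
            ("nonresponse", self.nonresponse),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        for dist, k in ((self.frequency_dist, 4), (self.intensity_dist, 3)):
            if len(dist) != k or any(p < 0 for p in dist):
                raise ValidationError("malformed level distribution")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValidationError("level distribution must sum to 1")
        for layer in self.layers:
            pi, po = self.layer_probs(layer)
            if not (0.0 <= po <= 1.0 and 0.0 <= pi <= 1.0):
                raise ValidationError(f"layer {layer!r}: probabilities outside [0, 1]")

    def layer_probs(self, layer: str) -> tuple[float, float]:
        """(p_in, p_out) for one layer, falling back to the defaults."""
        base = DEFAULT_LAYER_PROBS.get(layer, (0.2, 0.04))
        pi = self.p_in.get(layer, base[0]) if isinstance(self.p_in, dict) else (
            base[0] if self.p_in is None else self.p_in
        )
        po = self.p_out.get(layer, base[1]) if isinstance(self.p_out, dict) else (
            base[1] if self.p_out is None else self.p_out
        )
        return pi, po


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind one synthetic dataset."""

    roster: Roster
    latent: dict[str, np.ndarray]  # layer -> symmetric valued matrix
    brokers: tuple[str, ...]
    types: dict[str, str]


_TYPE_PREFIX = {
    "UN": "UN",
    "multilateral": "ML",
    "bilateral": "BL",
    "NGO": "NGO",
    "academic/research": "ACA",
    "intergovernmental": "IGO",
    "foundation": "FDN",
    "network": "NET",
}


def make_roster(spec: SyntheticSpec, rng: np.random.Generator) -> Roster:
    """Synthetic roster: ids encode the type (UN01, NGO03, ...); country
    coverage is drawn uniformly from 1-8; non-respondents are an exact
    ``round(nonresponse * n)``-sized random subset."""
    orgs = []
    for org_type in ORG_TYPES:
        for k in range(spec.n_per_type.get(org_type, 0)):
            org_id = f"{_TYPE_PREFIX[org_type]}{k + 1:02d}"
            orgs.append(
                Organization(
                    org_id=org_id,
                    acronym=org_id,
                    full_name=f"Synthetic {org_type} organization {k + 1}",
                    org_type=org_type,
                    n_countries=int(rng.integers(1, 9)),
                    respondent=True,
                )
            )
    n_nonresp = int(round(spec.nonresponse * len(orgs)))
    nonresp_idx = set(
        rng.choice(len(orgs), size=n_nonresp, replace=False).tolist()
    )
    orgs = [
        replace(o, respondent=(k not in nonresp_idx)) for k, o in enumerate(orgs)
    ]
    return Roster.from_organizations(orgs)


def _draw_layer(
    spec: SyntheticSpec,
    layer: str,
    roster: Roster,
    brokers: set[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """One undirected planted-partition draw with broker shortcuts."""
    scale = get_layer(layer).scale
    p_in, p_out = spec.layer_probs(layer)
    if scale.max_level == 1:
        levels, probs = [1], [1.0]
    elif scale.name == "intensity":
        levels, probs = [1, 2, 3], list(spec.intensity_dist)
    else:
        levels, probs = [1, 2, 3, 4], list(spec.frequency_dist)
    n = len(roster)
    ids = roster.ids
    types = {o.org_id: o.org_type for o in roster}
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            same = types[ids[i]] == types[ids[j]]
            if same:
                p = p_in
            elif ids[i] in brokers or ids[j] in brokers:
                p = spec.p_broker
            else:
                p = p_out
            if rng.random() < p:
                v = int(rng.choice(levels, p=probs))
                values[i, j] = values[j, i] = v
    return values


def generate_latent(spec: SyntheticSpec) -> GroundTruth:
    """Draw the latent symmetric valued matrices for every layer.

    Brokers are the first ``n_brokers`` organizations of the largest
    types (one per type), giving them cross-type tie probability
    ``p_broker`` on every layer.  The intensity layer is a relabelling
    of the overall layer's tied dyads (the survey only asks intensity
    where an overall relationship exists); nutrition layers are drawn
    independently.  Deterministic given ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_roster, ss_layers = root.spawn(2)
    roster = make_roster(spec, np.random.default_rng(ss_roster))
    # brokers are drawn from the types that broker in practice (UN
    # agencies and multilateral donors first), one per type
    preference = ("UN", "multilateral", "NGO", "foundation", "network",
                  "bilateral", "academic/research", "intergovernmental")
    broker_types = [t for t in preference if spec.n_per_type.get(t, 0) > 0]
    brokers = tuple(
        f"{_TYPE_PREFIX[t]}01" for t in broker_types[: spec.n_brokers]
    )
    latent: dict[str, np.ndarray] = {}
    layer_seeds = ss_layers.spawn(len(spec.layers))
    for layer, seed in zip(spec.layers, layer_seeds):
        rng = np.random.default_rng(seed)
        if layer == "intensity" and "overall" in latent:
            n = len(roster)
            values = np.zeros((n, n), dtype=int)
            ii, jj = np.nonzero(np.triu(latent["overall"]))
            for i, j in zip(ii.tolist(), jj.tolist()):
                v = int(rng.choice([1, 2, 3], p=list(spec.intensity_dist)))
                values[i, j] = values[j, i] = v
            latent[layer] = values
        else:
            latent[layer] = _draw_layer(spec, layer, roster, set(brokers), rng)
    types = {o.org_id: o.org_type for o in roster}
    return GroundTruth(roster, latent, brokers, types)


def emit_reports(gt: GroundTruth, spec: SyntheticSpec) -> list[DyadicReport]:
    """Flatten the latent state into directed survey reports.

    Each direction of every latent tie is reported independently: with
    probability ``1 - discordance`` the latent value, else omitted
    (``discordance / 2``) or shifted one level down (``discordance /
    2``; a shift from level 1 is an omission).  Non-respondents emit
    nothing.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    respondents = set(gt.roster.respondents)
    ids = gt.roster.ids
    reports: list[DyadicReport] = []
    d = spec.discordance
    for layer in spec.layers:
        values = gt.latent[layer]
        ii, jj = np.nonzero(values)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if ids[i] not in respondents:
                continue
            v = int(values[i, j])
            u = rng.random()
            if u < 1.0 - d:
                pass
            elif u < 1.0 - d / 2.0:
                v -= 1  # one level down; level 1 becomes an omission
            else:
                v = 0  # omitted outright
            if v > 0:
                reports.append(DyadicReport(ids[i], ids[j], layer, v))
    return reports


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[GroundTruth, list[DyadicReport]]:
    """Generate latent truth + reports; optionally write the survey
    bundle (roster.csv, reports.csv, latent DL matrices) to ``out_dir``."""
    gt = generate_latent(spec)
    reports = emit_reports(gt, spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        survey_io.write_roster(gt.roster, out / "roster.csv")
        survey_io.write_reports(reports, out / "reports.csv")
        truth = out / "ground_truth"
        truth.mkdir(exist_ok=True)
        from .build import ConfirmedNetwork

        for layer, values in gt.latent.items():
            net = ConfirmedNetwork(gt.roster.ids, values, get_layer(layer))
            survey_io.write_dl(net, truth / f"latent_{layer}.dl")
        (truth / "brokers.txt").write_text("\n".join(gt.brokers) + "\n")
    return gt, reports
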