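"""Core domain types for organizational network surveys.

The survey instrument asks each responding organization about its
relationship with every other organization in the roster, across several
relation layers: an overall any-purpose relationship (binary), the
intensity of that relationship (communication < coordination <
collaboration), and four nutrition working relationships (policy,
capacity development, knowledge management, implementation) rated on a
five-point contact-frequency Likert scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Closed category set for organization types.
ORG_TYPES: tuple[str, ...] = (
    "UN",
    "multilateral",
    "bilateral",
    "NGO",
    "academic/research",
    "intergovernmental",
    "foundation",
    "network",
)

#: The eight South Asian countries an organization may operate in.
SOUTH_ASIAN_COUNTRIES: tuple[str, ...] = (
    "Afghanistan",
    "Bangladesh",
    "Bhutan",
    "India",
    "Maldives",
    "Nepal",
    "Pakistan",
    "Sri Lanka",
)


@dataclass(frozen=True)
class Scale:
    """An ordered categorical response scale with fixed integer codes.

    ``labels[k]`` is the textual label of code ``k``; code 0 always means
    "no tie". Label lookup is case-insensitive and tolerant of
    underscore/space variation, but otherwise exact — no fuzzy matching.
    """

    name: str
    labels: tuple[str, ...]

    @property
    def max_level(self) -> int:
        return len(self.labels) - 1

    def _canon(self, text: str) -> str:
        return text.strip().lower().replace("_", " ")

    def code(self, value: object) -> int:
        """Map a label or integer-like value to its integer code.

        Raises :class:`ValidationError` for unknown labels or
        out-of-range integers.
        """
        if isinstance(value, bool):
            value = int(value)
        if isinstance(value, int):
            if not 0 <= value <= self.max_level:
                raise ValidationError(
                    f"value {value} outside {self.name} scale 0..{self.max_level}"
                )
            return value
        text = self._canon(str(value))
        try:
            return self.code(int(text))
        except ValueError:
            pass
        for k, lab in enumerate(self.labels):
            if self._canon(lab) == text:
                return k
        raise ValidationError(f"unknown {self.name} level {value!r}")

    def label(self, code: int) -> str:
        return self.labels[code]


BINARY = Scale("binary", ("no", "yes"))
INTENSITY = Scale(
    "intensity", ("none", "communication", "coordination", "collaboration")
)
FREQUENCY = Scale(
    "frequency", ("not at all", "rarely", "sometimes", "often", "very often")
)


@dataclass(frozen=True)
class RelationLayer:
    """A named relation layer together with its response scale."""

    name: str
    scale: Scale


#: The four nutrition working-relationship layers, in survey order.
NUTRITION_LAYERS: tuple[str, ...] = (
    "policy",
    "capacity",
    "knowledge",
    "implementation",
)

LAYERS: dict[str, RelationLayer] = {
    "overall": RelationLayer("overall", BINARY),
    "intensity": RelationLayer("intensity", INTENSITY),
    **{name: RelationLayer(name, FREQUENCY) for name in NUTRITION_LAYERS},
}


def get_layer(name: str) -> RelationLayer:
    try:
        return LAYERS[name.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown layer {name!r}; expected one of {sorted(LAYERS)}"
        ) from None


@dataclass(frozen=True)
class Organization:
    """One organization in the roster.

    ``countries`` is the set of South Asian countries of operation when
    known; ``n_countries`` is always available (0-8) and drives node
    shape binning in plots. ``respondent`` records whether the
    organization returned the survey.
    """

    org_id: str
    acronym: str
    full_name: str
    org_type: str
    n_countries: int
    countries: tuple[str, ...] | None = None
    respondent: bool = True

    def __post_init__(self) -> None:
        if self.org_type not in ORG_TYPES:
            raise ValidationError(
                f"{self.org_id}: unknown org_type {self.org_type!r}; "
                f"expected one of {ORG_TYPES}"
            )
        if not 0 <= self.n_countries <= len(SOUTH_ASIAN_COUNTRIES):
            raise ValidationError(
                f"{self.org_id}: country count {self.n_countries} outside 0..8"
            )
        if self.countries is not None:
            bad = [c for c in self.countries if c not in SOUTH_ASIAN_COUNTRIES]
            if bad:
                raise ValidationError(f"{self.org_id}: unknown countries {bad}")
            if len(set(self.countries)) != len(self.countries):
                raise ValidationError(f"{self.org_id}: duplicate country entries")
            if len(self.countries) != self.n_countries:
                raise ValidationError(
                    f"{self.org_id}: n_countries inconsistent with country list"
                )


@dataclass(frozen=True)
class Roster:
    """An ordered, validated collection of organizations.

    The ordering is the canonical node indexing for every matrix built
    downstream; it is deterministic (sorted by ``org_id`` unless an
    explicit order was supplied at construction).
    """

    organizations: tuple[Organization, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for k, org in enumerate(self.organizations):
            if org.org_id in seen:
                raise ValidationError(f"duplicate org_id {org.org_id!r} in roster")
            seen[org.org_id] = k
        object.__setattr__(self, "_index", seen)

    @classmethod
    def from_organizations(
        cls, orgs, *, sort: bool = True
    ) -> "Roster":
        orgs = list(orgs)
        if sort:
            orgs.sort(key=lambda o: o.org_id)
        return cls(tuple(orgs))

    def __len__(self) -> int:
        return len(self.organizations)

    def __iter__(self):
        return iter(self.organizations)

    def __contains__(self, org_id: str) -> bool:
        return org_id in self._index

    def __getitem__(self, org_id: str) -> Organization:
        return self.organizations[self._index[org_id]]

    def index(self, org_id: str) -> int:
        return self._index[org_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(o.org_id for o in self.organizations)

    @property
    def respondents(self) -> tuple[str, ...]:
        return tuple(o.org_id for o in self.organizations if o.respondent)

    @property
    def nonrespondents(self) -> tuple[str, ...]:
        return tuple(o.org_id for o in self.organizations if not o.respondent)

    def subset(self, org_ids) -> "Roster":
        """Roster restricted to ``org_ids``, preserving this roster's order."""
        keep = set(org_ids)
        return Roster(tuple(o for o in self.organizations if o.org_id in keep))


@dataclass(frozen=True)
class DyadicReport:
    """One directed survey answer: ``source`` reports ``value`` about
    ``target`` on ``layer``."""

    source: str
    target: str
    layer: str
    value: int

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError(
                f"self-report {self.source!r} -> {self.target!r} rejected"
            )
        layer = get_layer(self.layer)
        if not 0 <= self.value <= layer.scale.max_level:
            raise ValidationError(
                f"value {self.value} outside {layer.scale.name} scale "
                f"for layer {self.layer!r}"
            )
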