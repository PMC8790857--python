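"""Reading and writing survey tables and network files.

Input tables are delimited text (comma default, tab auto-detected):

* roster:  org_id, acronym, full_name, org_type, countries, respondent
* reports: source, target, layer, value

Networks travel as UCINET DL full-matrix files with embedded labels
(``dl n=<n>`` / ``format = fullmatrix`` / ``labels embedded``) or as
plain edge lists.  ``read_dl(write_dl(net))`` reproduces values and
labels exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .build import ConfirmedNetwork, DirectedValuedNetwork
from .core import (
    SOUTH_ASIAN_COUNTRIES,
    DyadicReport,
    Organization,
    RelationLayer,
    Roster,
    get_layer,
)
from .errors import DLParseError, SchemaError, ValidationError

log = logging.getLogger(__name__)

ROSTER_COLUMNS = ("org_id", "acronym", "full_name", "org_type", "countries", "respondent")
REPORT_COLUMNS = ("source", "target", "layer", "value")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", "nr"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_bool(text: str, where: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValidationError(f"{where}: cannot interpret {text!r} as boolean")


def _parse_countries(text: str, where: str) -> tuple[int, tuple[str, ...] | None]:
    t = text.strip()
    if t == "":
        return 0, None
    if re.fullmatch(r"\d+", t):
        return int(t), None
    by_lower = {c.lower(): c for c in SOUTH_ASIAN_COUNTRIES}
    names = []
    for part in t.split(";"):
        part = part.strip()
        if part.lower() not in by_lower:
            raise ValidationError(f"{where}: unknown country {part!r}")
        names.append(by_lower[part.lower()])
    return len(names), tuple(names)


def parse_roster(path: str | Path) -> Roster:
    """Read and validate a roster table into a deterministically ordered
    :class:`Roster` (sorted by org_id)."""
    df = _read_table(path)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"roster {path}: missing columns {missing}")
    orgs = []
    for row in df.itertuples(index=False):
        where = f"roster org_id={row.org_id!r}"
        n_countries, countries = _parse_countries(row.countries, where)
        orgs.append(
            Organization(
                org_id=row.org_id.strip(),
                acronym=row.acronym.strip(),
                full_name=row.full_name.strip(),
                org_type=row.org_type.strip(),
                n_countries=n_countries,
                countries=countries,
                respondent=_parse_bool(row.respondent, where),
            )
        )
    return Roster.from_organizations(orgs)


@dataclass(frozen=True)
class ParsedReports:
    """Accepted reports plus an account of every rejected row."""

    reports: tuple[DyadicReport, ...]
    dropped: tuple[tuple[int, str], ...]  # (1-based data row number, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def parse_reports(
    path: str | Path, roster: Roster, *, strict: bool = False
) -> ParsedReports:
    """Read dyadic survey reports, mapping textual Likert labels to
    integer codes.

    Invalid rows (unresolvable org ids, self-reports, values outside the
    layer's scale) are dropped and counted; with ``strict=True`` the
    first invalid row raises instead, naming its row number.
    """
    df = _read_table(path)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"reports {path}: missing columns {missing}")
    reports: list[DyadicReport] = []
    dropped: list[tuple[int, str]] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        try:
            source, target = row.source.strip(), row.target.strip()
            for org in (source, target):
                if org not in roster:
                    raise ValidationError(f"org_id {org!r} not in roster")
            layer = get_layer(row.layer)
            reports.append(
                DyadicReport(source, target, layer.name, layer.scale.code(row.value))
            )
        except ValidationError as exc:
            if strict:
                raise ValidationError(f"reports row {rownum}: {exc}") from None
            dropped.append((rownum, str(exc)))
    if dropped:
        log.warning("dropped %d invalid report rows", len(dropped))
    return ParsedReports(tuple(reports), tuple(dropped))


def write_dl(
    net: ConfirmedNetwork | DirectedValuedNetwork, path: str | Path
) -> None:
    """Write a network as a UCINET DL full-matrix file with embedded
    labels."""
    for label in net.nodes:
        if re.search(r"\s", label):
            raise ValidationError(f"node label {label!r} contains whitespace")
    lines = [f"dl n={net.n}", "format = fullmatrix", "labels embedded", "data:"]
    lines.append(" ".join(net.nodes))
    for label, row in zip(net.nodes, net.values):
        lines.append(label + " " + " ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dl(
    path: str | Path,
    roster: Roster | None = None,
    layer: RelationLayer | str | None = None,
) -> DirectedValuedNetwork | ConfirmedNetwork:
    """Parse a DL full-matrix file.

    Returns a :class:`ConfirmedNetwork` when the matrix is symmetric,
    else a :class:`DirectedValuedNetwork`.  If a roster is supplied,
    labels must resolve in it; non-respondent rows are flagged missing
    on directed matrices.
    """
    if isinstance(layer, str):
        layer = get_layer(layer)
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise DLParseError("empty file", line=1)
    m = re.match(r"\s*dl\s+n\s*=\s*(\d+)\s*$", lines[0], flags=re.IGNORECASE)
    if not m:
        raise DLParseError(f"expected 'dl n=<n>' header, got {lines[0]!r}", line=1)
    n = int(m.group(1))
    k, embedded, saw_format = 1, False, False
    while k < len(lines) and not re.match(r"\s*data\s*:", lines[k], re.IGNORECASE):
        stmt = lines[k].strip().lower()
        if re.fullmatch(r"format\s*=\s*fullmatrix", stmt):
            saw_format = True
        elif stmt == "labels embedded":
            embedded = True
        elif stmt != "":
            raise DLParseError(f"unrecognized DL statement {lines[k]!r}", line=k + 1)
        k += 1
    if k == len(lines):
        raise DLParseError("missing 'data:' section", line=len(lines))
    if not saw_format:
        raise DLParseError("missing 'format = fullmatrix' statement", line=k + 1)
    body = [ln for ln in lines[k + 1 :] if ln.strip()]
    if embedded:
        if len(body) != n + 1:
            raise DLParseError(
                f"expected label row + {n} matrix rows, got {len(body)}", line=k + 2
            )
        labels = tuple(body[0].split())
        body = body[1:]
    else:
        labels = tuple(str(i + 1) for i in range(n))
    if len(labels) != n:
        raise DLParseError(f"expected {n} labels, got {len(labels)}", line=k + 2)
    values = np.zeros((n, n), dtype=int)
    for i, ln in enumerate(body):
        parts = ln.split()
        if embedded:
            if parts[0] != labels[i]:
                raise DLParseError(
                    f"row label {parts[0]!r} != column label {labels[i]!r}",
                    line=k + 3 + i,
                )
            parts = parts[1:]
        if len(parts) != n:
            raise DLParseError(
                f"expected {n} values, got {len(parts)}", line=k + 3 + i
            )
        try:
            values[i] = [int(p) for p in parts]
        except ValueError:
            raise DLParseError("non-integer matrix entry", line=k + 3 + i) from None
    nonresp: frozenset[str] = frozenset()
    if roster is not None:
        unknown = [v for v in labels if v not in roster]
        if unknown:
            raise ValidationError(f"DL labels not in roster: {unknown}")
        nonresp = frozenset(v for v in labels if not roster[v].respondent)
    if np.array_equal(values, values.T):
        return ConfirmedNetwork(labels, values, layer)
    return DirectedValuedNetwork(labels, values, layer, nonresp)


def write_edge_list(
    net: ConfirmedNetwork | DirectedValuedNetwork, path: str | Path
) -> None:
    """Plain edge-list export: source, target, layer, value (positive
    entries only; symmetric networks list each dyad once)."""
    layer = net.layer.name if net.layer else ""
    rows = []
    if isinstance(net, ConfirmedNetwork):
        for s, t, v in net.edges():
            rows.append((s, t, layer, v))
    else:
        ii, jj = np.nonzero(net.values)
        for i, j in zip(ii.tolist(), jj.tolist()):
            rows.append((net.nodes[i], net.nodes[j], layer, int(net.values[i, j])))
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, index=False)


def write_roster(roster: Roster, path: str | Path) -> None:
    rows = []
    for o in roster:
        countries = (
            ";".join(o.countries) if o.countries is not None else str(o.n_countries)
        )
        rows.append(
            (o.org_id, o.acronym, o.full_name, o.org_type, countries, o.respondent)
        )
    pd.DataFrame(rows, columns=list(ROSTER_COLUMNS)).to_csv(path, index=False)


def write_reports(reports, path: str | Path, *, labels: bool = True) -> None:
    """Write dyadic reports; with ``labels=True`` ordinal codes are
    written as their textual scale labels."""
    rows = []
    for r in reports:
        value = get_layer(r.layer).scale.label(r.value) if labels else r.value
        rows.append((r.source, r.target, r.layer, value))
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(path, index=False)
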