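"""Curated ion-channel annotation table: membrane segments, pore domains, units.

The curated channelome table records, for every human ion channel (IC), its
identifiers, classification, functional labels and — central to everything
downstream — the list of membrane-embedded segments and the derived
"pore-containing functional domain": the span that covers the pore region and
every transmembrane (TM) segment of the protein.  Proteins with such a domain
are *pore-containing* ICs (or *two-pore* when curators flag two tandem
pore-conducting regions); proteins without one but with experimental evidence
of membership in an IC complex are *auxiliary* subunits; proteins with neither
are excluded from the curated list.

Coordinates are 1-based inclusive (UniProt convention) throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "SegmentKind",
    "MembraneSegment",
    "PoreDomain",
    "Unit",
    "ChannelAnnotation",
    "SegmentParseError",
    "NoPoreDomainError",
    "AnnotationTableError",
    "parse_segment_list",
    "format_segment_list",
    "derive_pore_domain",
    "classify_unit",
    "read_annotation_table",
    "write_annotation_table",
    "check_annotation_invariants",
    "unit_counts",
]


class SegmentKind(str, enum.Enum):
    """Membrane segment kind: TM crosses the bilayer fully, IM partially."""

    TM = "TM"
    IM = "IM"


#: Single-letter codes used in the segment-list dialect ("T:8-36,I:71-76").
_KIND_CODES = {"T": SegmentKind.TM, "I": SegmentKind.IM}
_CODE_OF_KIND = {SegmentKind.TM: "T", SegmentKind.IM: "I"}

#: Accepted range separators: ASCII hyphen and en-dash.
_DASHES = ("–", "-")


class SegmentParseError(ValueError):
    """A malformed token in a segment-list string."""


class NoPoreDomainError(ValueError):
    """Raised when no pore-containing domain is derivable (no TM segment)."""


class AnnotationTableError(ValueError):
    """Malformed annotation table (e.g. missing mandatory columns)."""


@dataclass(frozen=True, order=True)
class MembraneSegment:
    kind: SegmentKind
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"segment start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"segment end {self.end} precedes start {self.start}"
            )


@dataclass(frozen=True)
class PoreDomain:
    """Pore-containing functional domain span.

    ``reported_length`` follows the curated table's printed convention
    (end − start); the inclusive residue count is exposed as ``span``.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"pore domain end {self.end} must exceed start {self.start}"
            )

    @property
    def reported_length(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> int:
        return self.end - self.start + 1


class Unit(str, enum.Enum):
    pore_containing = "pore_containing"
    two_pore = "two_pore"
    auxiliary = "auxiliary"
    excluded = "excluded"


@dataclass
class ChannelAnnotation:
    """One row of the curated channelome table."""

    accession: str
    name: str = ""
    symbol: str = ""
    tdl: str = ""  # Tclin / Tchem / Tbio / Tdark
    length: Optional[int] = None
    family: str = ""
    group: str = ""  # VGIC / LGIC / Chloride / Other
    unit: Unit = Unit.pore_containing
    segments: list[MembraneSegment] = field(default_factory=list)
    pore_domain: Optional[PoreDomain] = None
    complex_evidence: bool = False
    ion: str = ""
    gating: str = ""
    verified_by_litmine: bool = True
    extra: dict[str, str] = field(default_factory=dict)

    @property
    def n_tm(self) -> int:
        return sum(1 for s in self.segments if s.kind is SegmentKind.TM)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Segment-list dialect
# ---------------------------------------------------------------------------

def parse_segment_list(text: str) -> list[MembraneSegment]:
    """Parse a comma-separated ``K:start-end`` segment list.

    ``K`` is ``T`` (transmembrane) or ``I`` (intramembrane); the range
    separator may be an ASCII hyphen or an en-dash.  An empty/blank string
    yields an empty list.  Segments are returned in file order.
    """
    text = text.strip()
    if not text:
        return []
    segments: list[MembraneSegment] = []
    for token in text.split(","):
        token = token.strip()
        if ":" not in token:
            raise SegmentParseError(f"malformed segment token {token!r}")
        code, _, rng = token.partition(":")
        code = code.strip()
        if code not in _KIND_CODES:
            raise SegmentParseError(
                f"unknown segment kind code {code!r} in token {token!r}"
            )
        for dash in _DASHES:
            if dash in rng:
                lo, _, hi = rng.partition(dash)
                break
        else:
            raise SegmentParseError(f"missing range separator in {token!r}")
        try:
            start, end = int(lo), int(hi)
        except ValueError as exc:
            raise SegmentParseError(
                f"non-integer coordinate in token {token!r}"
            ) from exc
        if start < 1 or end < start:
            raise SegmentParseError(
                f"invalid coordinates in token {token!r}: "
                f"require 1 <= start <= end"
            )
        segments.append(MembraneSegment(_KIND_CODES[code], start, end))
    return segments


def format_segment_list(segments: Iterable[MembraneSegment]) -> str:
    """Inverse of :func:`parse_segment_list`; emits ASCII hyphens."""
    return ",".join(
        f"{_CODE_OF_KIND[s.kind]}:{s.start}-{s.end}" for s in segments
    )


# ---------------------------------------------------------------------------
# Pore-domain derivation and unit classification
# ---------------------------------------------------------------------------

def derive_pore_domain(segments: Iterable[MembraneSegment]) -> PoreDomain:
    """Smallest span containing every TM segment.

    The pore-containing functional domain spans the pore region and includes
    all TM segments, so its bounds are the minimum start and maximum end over
    the TM subset.  Raises :class:`NoPoreDomainError` if there is no TM
    segment; the caller decides auxiliary vs excluded.
    """
    tms = [s for s in segments if s.kind is SegmentKind.TM]
    if not tms:
        raise NoPoreDomainError("no pore-containing domain derivable: no TM segment")
    return PoreDomain(min(s.start for s in tms), max(s.end for s in tms))


def classify_unit(
    pore_domain: Optional[PoreDomain],
    complex_evidence: bool,
    curated_two_pore: bool = False,
) -> Unit:
    """Classify a protein's role in the channel complex.

    A pore domain makes the protein pore-containing (two_pore when curators
    flag two tandem pore-conducting regions — a curated input, not computed).
    Without one, experimental complex-membership evidence makes it auxiliary;
    otherwise it is excluded from the curated list.
    """
    if pore_domain is not None:
        return Unit.two_pore if curated_two_pore else Unit.pore_containing
    return Unit.auxiliary if complex_evidence else Unit.excluded


# ---------------------------------------------------------------------------
# Table I/O (TSV, header with the curated table's column labels)
# ---------------------------------------------------------------------------

_COLUMNS = {
    "UniProt": "accession",
    "Name": "name",
    "Symbol": "symbol",
    "Target Development Level": "tdl",
    "Length": "length",
    "Family designation": "family",
    "Group": "group",
    "Unit": "unit",
    "Ion": "ion",
    "Gate mechanism": "gating",
    "TMsList": "segments",
    "Pore domain start": "pore_start",
    "Pore domain end": "pore_end",
    "Complex evidence": "complex_evidence",
    "Verified": "verified",
}
_MANDATORY = ("UniProt", "Unit")

_UNIT_LABELS = {
    "pore-containing": Unit.pore_containing,
    "pore_containing": Unit.pore_containing,
    "two-pore": Unit.two_pore,
    "two_pore": Unit.two_pore,
    "auxiliary": Unit.auxiliary,
    "excluded": Unit.excluded,
}
_UNIT_OUT = {
    Unit.pore_containing: "Pore-containing",
    Unit.two_pore: "Two-pore",
    Unit.auxiliary: "Auxiliary",
    Unit.excluded: "Excluded",
}


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"yes", "true", "1"}


def read_annotation_table(path) -> list[ChannelAnnotation]:
    """Load a curated annotation TSV into :class:`ChannelAnnotation` records.

    Unknown columns are preserved verbatim in ``record.extra``.  Missing
    mandatory columns raise :class:`AnnotationTableError` listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise AnnotationTableError(
            f"annotation table missing mandatory columns: {', '.join(missing)}"
        )
    known = set(_COLUMNS)
    records: list[ChannelAnnotation] = []
    for _, row in df.iterrows():
        unit_label = row["Unit"].strip().lower()
        if unit_label not in _UNIT_LABELS:
            raise AnnotationTableError(f"unknown Unit value {row['Unit']!r}")
        segments = parse_segment_list(row.get("TMsList", ""))
        pore = None
        ps, pe = row.get("Pore domain start", ""), row.get("Pore domain end", "")
        if ps.strip() and pe.strip():
            pore = PoreDomain(int(ps), int(pe))
        length = row.get("Length", "").strip()
        records.append(
            ChannelAnnotation(
                accession=row["UniProt"],
                name=row.get("Name", ""),
                symbol=row.get("Symbol", ""),
                tdl=row.get("Target Development Level", ""),
                length=int(length) if length else None,
                family=row.get("Family designation", ""),
                group=row.get("Group", ""),
                unit=_UNIT_LABELS[unit_label],
                segments=segments,
                pore_domain=pore,
                complex_evidence=_parse_bool(row.get("Complex evidence", "")),
                ion=row.get("Ion", ""),
                gating=row.get("Gate mechanism", ""),
                verified_by_litmine=_parse_bool(row.get("Verified", "yes")),
                extra={c: row[c] for c in df.columns if c not in known},
            )
        )
    return records


def write_annotation_table(records: Iterable[ChannelAnnotation], path) -> None:
    rows = []
    extra_cols: list[str] = []
    for r in records:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
        rows.append(r)
    out = {
        "UniProt": [r.accession for r in rows],
        "Name": [r.name for r in rows],
        "Symbol": [r.symbol for r in rows],
        "Target Development Level": [r.tdl for r in rows],
        "Length": ["" if r.length is None else r.length for r in rows],
        "Family designation": [r.family for r in rows],
        "Group": [r.group for r in rows],
        "Unit": [_UNIT_OUT[r.unit] for r in rows],
        "Ion": [r.ion for r in rows],
        "Gate mechanism": [r.gating for r in rows],
        "TMsList": [format_segment_list(r.segments) for r in rows],
        "Pore domain start": [
            "" if r.pore_domain is None else r.pore_domain.start for r in rows
        ],
        "Pore domain end": [
            "" if r.pore_domain is None else r.pore_domain.end for r in rows
        ],
        "Complex evidence": ["yes" if r.complex_evidence else "no" for r in rows],
        "Verified": ["yes" if r.verified_by_litmine else "no" for r in rows],
    }
    for c in extra_cols:
        out[c] = [r.extra.get(c, "") for r in rows]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def check_annotation_invariants(record: ChannelAnnotation) -> list[str]:
    """Return human-readable invariant violations (empty list = consistent)."""
    problems: list[str] = []
    if record.unit is Unit.auxiliary:
        if record.pore_domain is not None:
            problems.append(
                f"{record.accession}: auxiliary unit but pore domain present"
            )
        if not record.complex_evidence:
            problems.append(
                f"{record.accession}: auxiliary unit without complex evidence"
            )
    if record.pore_domain is not None:
        pd_ = record.pore_domain
        for s in record.segments:
            if s.kind is SegmentKind.TM and not (
                pd_.start <= s.start and s.end <= pd_.end
            ):
                problems.append(
                    f"{record.accession}: pore domain [{pd_.start},{pd_.end}] "
                    f"does not contain TM segment [{s.start},{s.end}]"
                )
    if record.tdl and record.tdl not in {"Tclin", "Tchem", "Tbio", "Tdark"}:
        problems.append(f"{record.accession}: unknown TDL level {record.tdl!r}")
    return problems


def unit_counts(records: Iterable[ChannelAnnotation]) -> dict[str, int]:
    """Tallies by unit plus total / distinct-family / TDL counts."""
    records = list(records)
    counts: dict[str, int] = {
        "total": len(records),
        "pore_containing": 0,
        "two_pore": 0,
        "auxiliary": 0,
        "excluded": 0,
        "families": len({r.family for r in records if r.family}),
    }
    for r in records:
        counts[r.unit.value] += 1
    for level in ("Tclin", "Tchem", "Tbio", "Tdark"):
        counts[level] = sum(1 for r in records if r.tdl == level)
    return counts
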