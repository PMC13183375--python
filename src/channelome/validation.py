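"""Three-step ortholog validation cascade over UniProt-style metadata.

Candidate ortholog sequences are screened for annotation quality before they
enter the final catalogue.  Reviewed entries pass outright (step 1).
Unreviewed entries with dependable protein-existence evidence (protein level,
transcript level, or inferred from homology — flags 1-3) pass at step 2.
The remainder must pass five integrity checks (step 3): sequence version not
unusually high, no dominant compositional bias, a low fraction of
non-standard residues, length within [30, 5000], and at least some
cross-referenced metadata (domain annotations or other cross-references).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "ProteinMetadata",
    "ValidationParams",
    "ValidationVerdict",
    "low_complexity_fraction",
    "validate_record",
    "validate_batch",
    "write_verdicts",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Step-3 check labels, in report order.
STEP3_CHECKS = ("version", "compositional_bias", "nonstandard_aa", "length", "crossrefs")


@dataclass
class ProteinMetadata:
    accession: str
    entry_type: str = "Reviewed"  # Reviewed | Unreviewed
    protein_existence: int = 1  # 1..5
    sequence_version: int = 1
    sequence: str = ""
    domain_count: int = 0
    xref_count: int = 0

    def __post_init__(self) -> None:
        if self.entry_type not in ("Reviewed", "Unreviewed"):
            raise ValueError(f"unknown entry_type {self.entry_type!r}")


@dataclass(frozen=True)
class ValidationParams:
    """Thresholds for the step-3 integrity checks (all configurable)."""

    max_version: int = 100
    bias_max: float = 0.5
    bias_window: int = 12
    bias_entropy_min: float = 2.2  # bits
    ns_max: float = 0.05
    min_length: int = 30
    max_length: int = 5000
    # independent toggles for each step-3 check
    enabled: tuple[str, ...] = STEP3_CHECKS


@dataclass(frozen=True)
class ValidationVerdict:
    accession: str
    passed: bool
    deciding_step: int  # 1, 2 or 3
    failed_checks: frozenset[str] = frozenset()


def low_complexity_fraction(
    sequence: str, window: int = 12, entropy_min: float = 2.2
) -> float:
    """Fraction of residues covered by a low-entropy sliding window.

    A window is low-complexity when the Shannon entropy (log2) of its
    empirical residue distribution falls below ``entropy_min`` bits.  For
    sequences shorter than the window the whole sequence is the one window.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(sequence)
    if n == 0:
        return 0.0
    w = min(window, n)
    covered = [False] * n
    counts = Counter(sequence[:w])
    def entropy(c: Counter) -> float:
        h = 0.0
        for v in c.values():
            if v:
                p = v / w
                h -= p * math.log2(p)
        return h
    for start in range(0, n - w + 1):
        if start > 0:
            counts[sequence[start - 1]] -= 1
            counts[sequence[start + w - 1]] += 1
        if entropy(counts) < entropy_min:
            for i in range(start, start + w):
                covered[i] = True
    return sum(covered) / n


def nonstandard_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    return sum(1 for c in sequence if c.upper() not in STANDARD_AA) / len(sequence)


def validate_record(
    record: ProteinMetadata, params: ValidationParams | None = None
) -> ValidationVerdict:
    """Run the three-step cascade on one metadata record."""
    params = params or ValidationParams()
    if not 1 <= record.protein_existence <= 5:
        raise ValueError(
            f"{record.accession}: protein_existence must be 1-5, "
            f"got {record.protein_existence}"
        )
    if record.entry_type == "Reviewed":
        return ValidationVerdict(record.accession, True, 1)
    if record.protein_existence in (1, 2, 3):
        return ValidationVerdict(record.accession, True, 2)

    failed: set[str] = set()
    seq = record.sequence.upper()
    if "version" in params.enabled and record.sequence_version > params.max_version:
        failed.add("version")
    if "compositional_bias" in params.enabled:
        frac = low_complexity_fraction(
            seq, params.bias_window, params.bias_entropy_min
        )
        if frac > params.bias_max:
            failed.add("compositional_bias")
    if "nonstandard_aa" in params.enabled and nonstandard_fraction(seq) > params.ns_max:
        failed.add("nonstandard_aa")
    if "length" in params.enabled and not (
        params.min_length <= len(seq) <= params.max_length
    ):
        failed.add("length")
    if (
        "crossrefs" in params.enabled
        and record.domain_count == 0
        and record.xref_count == 0
    ):
        failed.add("crossrefs")
    return ValidationVerdict(record.accession, not failed, 3, frozenset(failed))


def validate_batch(
    records: Iterable[ProteinMetadata], params: ValidationParams | None = None
) -> dict[str, ValidationVerdict]:
    return {r.accession: validate_record(r, params) for r in records}


def read_metadata_tsv(path) -> list[ProteinMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ProteinMetadata(
            accession=row["accession"],
            entry_type=row["entry_type"],
            protein_existence=int(row["protein_existence"]),
            sequence_version=int(row["sequence_version"]),
            sequence=row["sequence"],
            domain_count=int(row["domain_count"]),
            xref_count=int(row["xref_count"]),
        )
        for _, row in df.iterrows()
    ]


def write_metadata_tsv(records: Iterable[ProteinMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "accession": r.accession,
                "entry_type": r.entry_type,
                "protein_existence": r.protein_existence,
                "sequence_version": r.sequence_version,
                "sequence": r.sequence,
                "domain_count": r.domain_count,
                "xref_count": r.xref_count,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_verdicts(verdicts: Iterable[ValidationVerdict], path) -> None:
    rows = [
        {
            "accession": v.accession,
            "passed": "yes" if v.passed else "no",
            "deciding_step": v.deciding_step,
            "failed_checks": ",".join(sorted(v.failed_checks)),
        }
        for v in verdicts
    ]
    pd.DataFrame(rows, columns=["accession", "passed", "deciding_step", "failed_checks"]).to_csv(
        path, sep="\t", index=False
    )
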