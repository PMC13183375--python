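"""Scored local-alignment search with e-values, and tabular-hit ingestion.

The orthology pipeline only needs a search stage that produces e-valued,
rankable query-target hits.  This module provides one built on optimal local
alignment (affine gaps, BLOSUM62 by default) with Karlin-Altschul e-value
scaling, plus readers/writers for the 12-column tabular hit format so that
externally computed hits (e.g. BLAST outfmt 6) can drive the pipeline
instead.  Orthology results are identical either way for identical hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ScoringScheme",
    "SimilarityHit",
    "SearchInputError",
    "TabularParseError",
    "local_align",
    "search_all",
    "read_fasta",
    "ingest_tabular_hits",
    "write_tabular_hits",
    "sort_hits",
]

#: NCBI-style fallbacks for letters absent from the BLOSUM62 alphabet.
_LETTER_FALLBACK = {"U": "C", "O": "K", "J": "L"}
_ACCEPTED = set("ACDEFGHIKLMNPQRSTVWY" + "BZX" + "UOJ")


class SearchInputError(ValueError):
    """Bad search input: empty sequence, illegal residue, duplicate id."""


class TabularParseError(ValueError):
    """Malformed 12-column tabular hit file."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    ``lambda_`` and ``k_param`` are the gapped-BLOSUM62 defaults; e-values
    here only need to be monotone in score and threshold-comparable.  ``m``
    (database letters) and ``n`` (query length) are supplied per search.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k_param: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.lambda_ <= 0 or self.k_param <= 0:
            raise ValueError("Karlin-Altschul parameters must be > 0")

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k_param)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        # log-space to avoid underflow to exactly 0 for strong hits
        log_e = math.log(self.k_param) + math.log(m) + math.log(n) - self.lambda_ * raw
        return math.exp(max(log_e, -745.0)) if log_e > -745.0 else 5e-324

    def raw_from_bit(self, bit: float) -> float:
        return (bit * math.log(2.0) + math.log(self.k_param)) / self.lambda_


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    target: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]  # 1-based inclusive
    target_span: tuple[int, int]
    identity_pct: float = 0.0
    align_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0


def _clean(seq: str, name: str) -> str:
    s = seq.upper()
    if not s:
        raise SearchInputError(f"empty sequence for {name!r}")
    bad = set(s) - _ACCEPTED
    if bad:
        raise SearchInputError(
            f"illegal residue(s) {sorted(bad)} in sequence {name!r}"
        )
    for src, dst in _LETTER_FALLBACK.items():
        s = s.replace(src, dst)
    return s


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    # Biopython charges open_gap_score on the first gap residue; BLAST's
    # open+k*extend therefore maps to open = -(gap_open + gap_extend).
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
    m: int | None = None,
) -> SimilarityHit:
    """Optimal local alignment of ``a`` (query) against ``b`` (target).

    ``m`` is the database letter count used for the e-value; by default the
    target length (single-sequence database).
    """
    scheme = scheme or ScoringScheme()
    sa, sb = _clean(a, query_id), _clean(b, target_id)
    aligner = _make_aligner(scheme)
    alignments = aligner.align(sa, sb)
    raw = float(alignments.score)
    n = len(sa)
    db_letters = m if m is not None else len(sb)
    if raw <= 0:  # no positive-scoring local alignment exists
        return SimilarityHit(
            query=query_id,
            target=target_id,
            raw_score=0.0,
            bit_score=scheme.bit_score(0.0),
            evalue=scheme.evalue(0.0, db_letters, n),
            query_span=(0, 0),
            target_span=(0, 0),
        )
    aln = alignments[0]
    blocks_q, blocks_t = aln.aligned
    q_span = (int(blocks_q[0][0]) + 1, int(blocks_q[-1][1]))
    t_span = (int(blocks_t[0][0]) + 1, int(blocks_t[-1][1]))
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gaps = counts.gaps
    align_length = identities + mismatches + gaps
    return SimilarityHit(
        query=query_id,
        target=target_id,
        raw_score=raw,
        bit_score=scheme.bit_score(raw),
        evalue=scheme.evalue(raw, db_letters, n),
        query_span=q_span,
        target_span=t_span,
        identity_pct=100.0 * identities / align_length if align_length else 0.0,
        align_length=align_length,
        mismatches=mismatches,
        gap_opens=counts.open_internal_insertions + counts.open_internal_deletions,
    )


def read_fasta(path) -> dict[str, str]:
    """FASTA → ordered {id: sequence}; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise SearchInputError(f"duplicate identifier {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def sort_hits(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    """Deterministic ranking: bit score desc, evalue asc, target id asc."""
    return sorted(hits, key=lambda h: (-h.bit_score, h.evalue, h.target))


def search_all(
    queries: dict[str, str],
    database: dict[str, str],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
) -> list[SimilarityHit]:
    """All query-target hits with evalue <= evalue_max, ranked per query."""
    scheme = scheme or ScoringScheme()
    m = sum(len(s) for s in database.values())
    out: list[SimilarityHit] = []
    for qid in queries:
        per_query = []
        for tid, tseq in database.items():
            hit = local_align(
                queries[qid], tseq, scheme, query_id=qid, target_id=tid, m=m
            )
            if hit.evalue <= evalue_max:
                per_query.append(hit)
        out.extend(sort_hits(per_query))
    return out


# ---------------------------------------------------------------------------
# 12-column tabular dialect (BLAST outfmt-6 compatible)
# ---------------------------------------------------------------------------

def ingest_tabular_hits(path, scheme: ScoringScheme | None = None) -> list[SimilarityHit]:
    """Parse 12-column tabular hits; raw score recovered from the bit score."""
    scheme = scheme or ScoringScheme()
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TabularParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            (q, t, pid, alen, mm, go, qs, qe, ss, se, ev, bits) = fields
            try:
                hits.append(
                    SimilarityHit(
                        query=q,
                        target=t,
                        raw_score=scheme.raw_from_bit(float(bits)),
                        bit_score=float(bits),
                        evalue=float(ev),
                        query_span=(int(qs), int(qe)),
                        target_span=(int(ss), int(se)),
                        identity_pct=float(pid),
                        align_length=int(alen),
                        mismatches=int(mm),
                        gap_opens=int(go),
                    )
                )
            except ValueError as exc:
                raise TabularParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.target,
                        f"{h.identity_pct:.3f}",
                        str(h.align_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_span[0]),
                        str(h.query_span[1]),
                        str(h.target_span[0]),
                        str(h.target_span[1]),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.6g}",
                    ]
                )
                + "\n"
            )
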