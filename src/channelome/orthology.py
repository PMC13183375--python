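"""Graph-based orthology inference with dual full-length/domain evidence.

The pipeline mirrors the reciprocal-best-hit (RBH) strategy used for
cataloguing channel orthologs across proteomes: a forward similarity search
of the query (reference-organism) sequences against the target proteomes at
a permissive e-value cutoff, a reciprocal search of candidate targets back
against the query proteome at a stringent cutoff, retention of pairs where
each member is the other's top hit, Markov clustering (MCL) of the retained
relationship graph, filtering to within-cluster relationships, and finally
the intersection of two independent runs — one on full-length sequences and
one restricted to the pore-containing functional domain — so that a retained
ortholog must satisfy both overall similarity and conservation of the
functionally critical domain.  Retained pairs are then typed one-to-one vs
co-ortholog and screened by the metadata validation cascade.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .search import ScoringScheme, SimilarityHit, search_all, sort_hits
from .validation import ProteinMetadata, ValidationParams, validate_batch

__all__ = [
    "Relation",
    "OrthologPair",
    "OrthologyParams",
    "reciprocal_best_pairs",
    "markov_cluster",
    "filter_within_cluster",
    "intersect_evidence",
    "classify_relation",
    "run_orthology",
    "write_pairs_tsv",
]


class Relation(str, enum.Enum):
    one_to_one = "one_to_one"
    co_ortholog = "co_ortholog"


@dataclass(frozen=True)
class OrthologPair:
    query: str
    organism: str
    target: str
    evidence: frozenset[str] = frozenset()
    relation: Optional[Relation] = None
    cluster_id: Optional[int] = None


@dataclass(frozen=True)
class OrthologyParams:
    """Thresholds and modes for the orthology pipeline.

    The shipped defaults are the catalogue-scale settings (forward 1e-5,
    reciprocal 1e-200); short synthetic sequences cannot reach 1e-200, so
    simulations use relaxed values — both are plain config.  ``forward_mode``
    'top' keeps only the top forward hit per (query, organism) before the
    reciprocal step; 'all' keeps every forward hit under the cutoff, which
    lets lineage-specific duplicates surface as co-orthologs.
    """

    forward_evalue_max: float = 1e-5
    reciprocal_evalue_max: float = 1e-200
    inflation: float = 1.5
    forward_mode: str = "top"  # "top" | "all"

    def __post_init__(self) -> None:
        if self.forward_evalue_max <= 0 or self.reciprocal_evalue_max <= 0:
            raise ValueError("e-value thresholds must be > 0")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.forward_mode not in ("top", "all"):
            raise ValueError("forward_mode must be 'top' or 'all'")


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def reciprocal_best_pairs(
    forward_hits: Sequence[SimilarityHit],
    reciprocal_hits: Sequence[SimilarityHit],
    organism_of: Mapping[str, str],
    params: OrthologyParams | None = None,
) -> list[tuple[str, str]]:
    """RBH pairing from pre-filtered forward and reciprocal hit lists.

    A pair (q, t) is retained when t is q's top forward hit within t's
    organism (or any forward hit, in 'all' mode) and q is t's top reciprocal
    hit against the query proteome.  Ties are broken by (bit score desc,
    evalue asc, target id asc) — fixed in :func:`channelome.search.sort_hits`.
    """
    params = params or OrthologyParams()
    fwd = [h for h in forward_hits if h.evalue <= params.forward_evalue_max]
    rec = [h for h in reciprocal_hits if h.evalue <= params.reciprocal_evalue_max]

    # top forward hit per (query, organism)
    by_q_org: dict[tuple[str, str], list[SimilarityHit]] = {}
    for h in fwd:
        by_q_org.setdefault((h.query, organism_of[h.target]), []).append(h)
    if params.forward_mode == "top":
        forward_ok = {
            (q, sort_hits(hs)[0].target) for (q, _org), hs in by_q_org.items()
        }
    else:
        forward_ok = {(h.query, h.target) for h in fwd}

    # top reciprocal hit per target gene (query side of the reciprocal search)
    by_t: dict[str, list[SimilarityHit]] = {}
    for h in rec:
        by_t.setdefault(h.query, []).append(h)
    top_reciprocal = {t: sort_hits(hs)[0].target for t, hs in by_t.items()}

    pairs = sorted(
        (q, t) for (q, t) in forward_ok if top_reciprocal.get(t) == q
    )
    return pairs


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def markov_cluster(
    edges: Iterable[tuple[str, str, float]],
    inflation: float = 1.5,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    self_loops: bool = True,
) -> dict[str, int]:
    """MCL partition of an undirected weighted graph.

    Alternates expansion (matrix square) and inflation (entrywise power
    followed by column renormalisation) on the column-stochastic transition
    matrix until the maximum entry change drops below ``tol`` (or
    ``max_iter``).  Clusters are read off the attractor structure of the
    converged matrix.  Deterministic; cluster ids are assigned in order of
    each cluster's lexicographically smallest node.
    """
    edge_list = list(edges)
    nodes = sorted({u for u, _, _ in edge_list} | {v for _, v, _ in edge_list})
    if not nodes:
        return {}
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, w in edge_list:
        if w < 0:
            raise ValueError("edge weights must be >= 0")
        i, j = index[u], index[v]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    if self_loops:
        # standard loop addition: each node's loop = its max incident weight
        diag = M.max(axis=0)
        diag[diag == 0] = 1.0
        np.fill_diagonal(M, diag)
    col = M.sum(axis=0)
    col[col == 0] = 1.0
    M = M / col

    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        colsum = M.sum(axis=0)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            break

    # attractor extraction: rows with mass on the diagonal define clusters
    thr = 1e-7
    members: list[set[int]] = []
    for i in range(n):
        if M[i, i] > thr:
            members.append({j for j in range(n) if M[i, j] > thr})
    # merge overlapping attractor systems
    merged: list[set[int]] = []
    for s in members:
        hit = [m for m in merged if m & s]
        for m in hit:
            merged.remove(m)
            s = s | m
        merged.append(s)
    assigned: set[int] = set()
    for s in merged:
        assigned |= s
    for i in range(n):  # isolated / unattracted nodes become singletons
        if i not in assigned:
            merged.append({i})
    merged.sort(key=lambda s: min(s))
    out: dict[str, int] = {}
    for cid, s in enumerate(merged):
        for i in sorted(s):
            out[nodes[i]] = cid
    return out


# ---------------------------------------------------------------------------
# Filtering, intersection, relation typing
# ---------------------------------------------------------------------------

def filter_within_cluster(
    pairs: Iterable[tuple[str, str]], clusters: Mapping[str, int]
) -> list[tuple[str, str]]:
    """Keep only pairs whose endpoints share a cluster."""
    out = []
    for q, t in pairs:
        if q not in clusters:
            raise KeyError(f"no cluster assignment for endpoint {q!r}")
        if t not in clusters:
            raise KeyError(f"no cluster assignment for endpoint {t!r}")
        if clusters[q] == clusters[t]:
            out.append((q, t))
    return out


def intersect_evidence(
    full_length_pairs: Iterable[tuple[str, str]],
    domain_pairs: Iterable[tuple[str, str]],
    organism_of: Mapping[str, str],
    clusters: Mapping[str, int] | None = None,
) -> list[OrthologPair]:
    """Pairs supported by both the full-length and the domain analyses."""
    full = set(full_length_pairs)
    dom = set(domain_pairs)
    both = sorted(full & dom)
    return [
        OrthologPair(
            query=q,
            organism=organism_of[t],
            target=t,
            evidence=frozenset({"full_length", "domain"}),
            cluster_id=None if clusters is None else clusters.get(q),
        )
        for q, t in both
    ]


def classify_relation(pairs: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Type each pair one-to-one vs co-ortholog.

    (q, t) is one-to-one iff q has exactly one retained target in t's
    organism and t has exactly one retained query; any multiplicity on
    either side marks all pairs of that (query, organism) group, and of the
    shared target, as co-orthologs.
    """
    per_q_org: dict[tuple[str, str], int] = {}
    per_target: dict[str, int] = {}
    for p in pairs:
        per_q_org[(p.query, p.organism)] = per_q_org.get((p.query, p.organism), 0) + 1
        per_target[p.target] = per_target.get(p.target, 0) + 1
    out = []
    for p in pairs:
        unique = per_q_org[(p.query, p.organism)] == 1 and per_target[p.target] == 1
        out.append(replace(p, relation=Relation.one_to_one if unique else Relation.co_ortholog))
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

class _WithinOrganismBits:
    """Lazy cache of within-organism alignment bit scores."""

    def __init__(self, sequences: Mapping[str, str], scheme: ScoringScheme):
        self._seqs = sequences
        self._scheme = scheme
        self._cache: dict[tuple[str, str], float] = {}

    def bit(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._cache:
            from .search import local_align

            hit = local_align(self._seqs[key[0]], self._seqs[key[1]], self._scheme)
            self._cache[key] = hit.bit_score
        return self._cache[key]


def _inparalog_completion(
    rbh: Sequence[tuple[str, str]],
    fwd_bit: Mapping[tuple[str, str], float],
    rec_bit: Mapping[tuple[str, str], float],
    query_ids: Sequence[str],
    genes_by_org: Mapping[str, Sequence[str]],
    organism_of: Mapping[str, str],
    within: _WithinOrganismBits,
) -> tuple[set[tuple[str, str]], list[tuple[str, str, float]]]:
    """Expand RBH seed pairs with recent (post-speciation) duplicates.

    For a seed pair (q, t): a same-proteome gene q' is an in-paralog of q
    when it is at least as similar to q as the seed members are to each
    other; such duplicates arose after the speciation the seed witnesses,
    so they inherit the orthologous relationship (co-orthology).  Applied
    on both sides.  Returns the added pairs and the in-paralog edges used
    (for the clustering graph).
    """
    added: set[tuple[str, str]] = set()
    edges: list[tuple[str, str, float]] = []
    for q, t in rbh:
        seed_fwd = fwd_bit[(q, t)]
        seed_rec = rec_bit.get((t, q), seed_fwd)
        q_in = [q]
        for q2 in query_ids:
            if q2 == q:
                continue
            w = within.bit(q, q2)
            if w >= seed_fwd:
                q_in.append(q2)
                edges.append((q, q2, w))
        t_in = [t]
        for t2 in genes_by_org[organism_of[t]]:
            if t2 == t:
                continue
            w = within.bit(t, t2)
            if w >= seed_rec:
                t_in.append(t2)
                edges.append((t, t2, w))
        for q2 in q_in:
            for t2 in t_in:
                if (q2, t2) != (q, t):
                    added.add((q2, t2))
    return added, edges


def _one_direction(
    queries: dict[str, str],
    proteomes: dict[str, dict[str, str]],
    reciprocal_db: dict[str, str],
    organism_of: Mapping[str, str],
    scheme: ScoringScheme,
    params: OrthologyParams,
) -> list[tuple[str, str]]:
    """Forward + reciprocal search, RBH, co-ortholog completion, MCL filter."""
    database: dict[str, str] = {}
    for org in proteomes:
        database.update(proteomes[org])
    forward = search_all(queries, database, scheme, params.forward_evalue_max)
    candidates = sorted({h.target for h in forward})
    reciprocal = search_all(
        {t: database[t] for t in candidates},
        reciprocal_db,
        scheme,
        params.reciprocal_evalue_max,
    )
    pairs = reciprocal_best_pairs(forward, reciprocal, organism_of, params)
    if not pairs:
        return []
    fwd_bit = {(h.query, h.target): h.bit_score for h in forward}
    rec_bit = {(h.query, h.target): h.bit_score for h in reciprocal}

    genes_by_org: dict[str, list[str]] = {}
    for org in proteomes:
        genes_by_org[org] = list(proteomes[org])
    all_seqs = dict(database)
    all_seqs.update(queries)
    within = _WithinOrganismBits(all_seqs, scheme)
    added, inparalog_edges = _inparalog_completion(
        pairs, fwd_bit, rec_bit, list(queries), genes_by_org, organism_of, within
    )

    relationships = sorted(set(pairs) | added)
    # the clustering graph carries every relationship edge (RBH seeds,
    # completed co-ortholog pairs, in-paralog pairs), as in OrthoMCL
    edges = []
    for q, t in relationships:
        w = fwd_bit.get((q, t))
        if w is None:
            w = rec_bit.get((t, q))
        if w is None:
            w = within.bit(q, t)
        edges.append((q, t, w))
    edges += inparalog_edges
    # normalise weights by the organism-pair mean so that near-identical
    # recent duplicates do not fragment family clusters under inflation
    ref_org = "__query__"
    pair_of = lambda a, b: tuple(
        sorted((organism_of.get(a, ref_org), organism_of.get(b, ref_org)))
    )
    sums: dict[tuple[str, str], list[float]] = {}
    for a, b, w in edges:
        sums.setdefault(pair_of(a, b), []).append(w)
    means = {k: sum(v) / len(v) for k, v in sums.items()}
    edges = [(a, b, w / means[pair_of(a, b)]) for a, b, w in edges]
    clusters = markov_cluster(edges, params.inflation)
    relationships = [
        (q, t) for q, t in relationships if q in clusters and t in clusters
    ]
    return filter_within_cluster(relationships, clusters)


def run_orthology(
    queries: dict[str, str],
    query_domains: Mapping[str, tuple[int, int]],
    proteomes: dict[str, dict[str, str]],
    metadata: Mapping[str, ProteinMetadata] | None = None,
    params: OrthologyParams | None = None,
    scheme: ScoringScheme | None = None,
    validation_params: ValidationParams | None = None,
) -> tuple[list[OrthologPair], list[tuple[str, str, str]]]:
    """Full dual-evidence pipeline; returns (validated pairs, drop ledger).

    ``query_domains`` gives 1-based inclusive pore-domain coordinates for
    each query; queries without a domain are excluded from the domain run
    (and therefore from the intersection), mirroring the restriction of the
    orthology analysis to pore-containing sequences.  The drop ledger lists
    (query, target, reason) for every pair removed after the intersection.
    """
    params = params or OrthologyParams()
    scheme = scheme or ScoringScheme()
    organism_of = {
        gene: org for org in proteomes for gene in proteomes[org]
    }

    full_pairs = _one_direction(
        queries, proteomes, queries, organism_of, scheme, params
    )

    domain_queries = {
        q: queries[q][start - 1 : end]
        for q, (start, end) in query_domains.items()
        if q in queries
    }
    domain_pairs = _one_direction(
        domain_queries, proteomes, domain_queries, organism_of, scheme, params
    )

    graph_edges = [(q, t, 1.0) for q, t in set(full_pairs) & set(domain_pairs)]
    clusters = markov_cluster(graph_edges, params.inflation) if graph_edges else {}
    pairs = intersect_evidence(full_pairs, domain_pairs, organism_of, clusters)
    pairs = classify_relation(pairs)

    ledger: list[tuple[str, str, str]] = []
    if metadata is not None:
        verdicts = validate_batch(
            [metadata[p.target] for p in pairs if p.target in metadata],
            validation_params,
        )
        kept = []
        for p in pairs:
            if p.target not in metadata:
                ledger.append((p.query, p.target, "validation: missing metadata"))
                continue
            v = verdicts[p.target]
            if v.passed:
                kept.append(p)
            else:
                reason = "validation: " + ",".join(sorted(v.failed_checks))
                ledger.append((p.query, p.target, reason))
        pairs = kept
    return pairs, ledger


def write_pairs_tsv(pairs: Iterable[OrthologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\torganism\ttarget\trelation\tcluster_id\tevidence\n")
        for p in pairs:
            fh.write(
                f"{p.query}\t{p.organism}\t{p.target}\t"
                f"{p.relation.value if p.relation else ''}\t"
                f"{'' if p.cluster_id is None else p.cluster_id}\t"
                f"{','.join(sorted(p.evidence))}\n"
            )
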