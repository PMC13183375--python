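"""Phylogenetic profiling: state matrix, percentages, clustering, enrichment.

Validated ortholog pairs are summarised as a query x organism state matrix
(one-to-one / co-ortholog / absent).  Family-by-lineage percentages follow
the published formula: 100 x (orthologs found for all members of a family in
a lineage) / (organisms in the lineage x family size).  Profiles are grouped
by agglomerative Ward clustering on Euclidean distances of the binary
presence encoding (co-orthologs count as present), and each cluster's genes
are tested for term over-representation with a one-sided hypergeometric test
under joint Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .orthology import OrthologPair, Relation

__all__ = [
    "STATE_ABSENT",
    "STATE_CO_ORTHOLOG",
    "STATE_ONE_TO_ONE",
    "ProfileMatrix",
    "LineageFamilySummary",
    "EnrichmentResult",
    "build_profile_matrix",
    "lineage_family_percentage",
    "cluster_profiles",
    "enrich_terms",
]

STATE_ABSENT = 0
STATE_CO_ORTHOLOG = 1
STATE_ONE_TO_ONE = 2


@dataclass
class ProfileMatrix:
    """Query x organism state matrix with per-organism lineage paths."""

    states: pd.DataFrame  # rows: queries, columns: organisms, values {0,1,2}
    lineages: dict[str, list[str]]  # organism -> lineage path from root

    @property
    def queries(self) -> list[str]:
        return list(self.states.index)

    @property
    def organisms(self) -> list[str]:
        return list(self.states.columns)

    def organisms_in_lineage(self, lineage: str) -> list[str]:
        return [
            o for o in self.organisms if lineage in self.lineages.get(o, [])
        ]

    def presence(self) -> pd.DataFrame:
        """Binary encoding: 1 where an ortholog (of either kind) was found."""
        return (self.states > STATE_ABSENT).astype(int)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# states: 2=one_to_one, 1=co_ortholog, 0=absent\n")
            self.states.to_csv(fh, sep="\t", index_label="query")


@dataclass(frozen=True)
class LineageFamilySummary:
    family: str
    lineage: str
    percentage: float
    found: int
    n_organisms: int
    family_size: int


@dataclass(frozen=True)
class EnrichmentResult:
    cluster: str
    term: str
    overlap: int  # k
    term_size: int  # K
    cluster_size: int  # n
    universe_size: int  # N
    p_value: float
    fdr: float


def build_profile_matrix(
    pairs: Sequence[OrthologPair],
    queries: Sequence[str],
    organisms: Sequence[str],
    lineages: Mapping[str, list[str]] | None = None,
) -> ProfileMatrix:
    """State matrix over every query x organism cell.

    Cells default to absent; a retained pair sets its cell to the pair's
    relation state (a co-ortholog state wins over one-to-one if both are
    present for the same cell, which happens exactly when the cell has
    multiple targets).
    """
    states = pd.DataFrame(
        STATE_ABSENT, index=list(queries), columns=list(organisms), dtype=int
    )
    for p in pairs:
        if p.organism not in states.columns:
            raise KeyError(f"pair references unknown organism {p.organism!r}")
        if p.query not in states.index:
            raise KeyError(f"pair references unknown query {p.query!r}")
        value = (
            STATE_ONE_TO_ONE if p.relation is Relation.one_to_one else STATE_CO_ORTHOLOG
        )
        current = states.at[p.query, p.organism]
        if current == STATE_ABSENT:
            states.at[p.query, p.organism] = value
        elif value == STATE_CO_ORTHOLOG or current == STATE_CO_ORTHOLOG:
            states.at[p.query, p.organism] = STATE_CO_ORTHOLOG
    return ProfileMatrix(states, dict(lineages or {}))


def lineage_family_percentage(
    matrix: ProfileMatrix,
    family_map: Mapping[str, str],
    lineage: str,
    family: str,
) -> LineageFamilySummary:
    """Percentage of detected orthologs for one family in one lineage.

    percentage = 100 x (non-absent cells over the family's rows and the
    lineage's organisms) / (n_organisms x family_size).  Co-orthologs count
    once per (query, organism) cell.
    """
    rows = [q for q in matrix.queries if family_map.get(q) == family]
    if not rows:
        raise ValueError(f"family {family!r} selects no profiled queries")
    cols = matrix.organisms_in_lineage(lineage)
    if not cols:
        raise ValueError(f"lineage {lineage!r} selects no organisms")
    sub = matrix.states.loc[rows, cols]
    found = int((sub.to_numpy() > STATE_ABSENT).sum())
    denom = len(cols) * len(rows)
    return LineageFamilySummary(
        family=family,
        lineage=lineage,
        percentage=100.0 * found / denom,
        found=found,
        n_organisms=len(cols),
        family_size=len(rows),
    )


def cluster_profiles(
    matrix: ProfileMatrix,
    k: int,
    *,
    lineage: str | None = "Eukaryota",
) -> tuple[dict[str, int], np.ndarray]:
    """Ward/Euclidean hierarchical clustering of presence profiles.

    Profiles are the binary presence rows restricted to organisms of
    ``lineage`` (pass None to use every organism); the dendrogram is cut to
    exactly ``k`` clusters.  Returns (row -> cluster label in 1..k, the
    scipy linkage matrix).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    presence = matrix.presence()
    if lineage is not None:
        cols = matrix.organisms_in_lineage(lineage)
        if cols:
            presence = presence[cols]
    X = presence.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")
    if n == 1:
        return {presence.index[0]: 1}, np.empty((0, 4))
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(presence.index, (int(l) for l in labels))), Z


def enrich_terms(
    clusters: Mapping[str, Sequence[str]],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_max: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of terms in each cluster.

    For each (cluster, term): p = P(X >= k) with X ~ Hypergeom(N, K, n),
    N the universe size, K the term's genes in the universe, n the cluster
    size, k the overlap.  BH-FDR is applied across all cluster x term tests
    jointly.  All tested results are returned (sorted by fdr then p);
    callers retain fdr < ``fdr_max`` via :func:`retained`.
    """
    universe_set = set(universe)
    N = len(universe_set)
    for label, genes in clusters.items():
        outside = set(genes) - universe_set
        if outside:
            raise ValueError(
                f"cluster {label!r} contains genes outside the universe: "
                f"{sorted(outside)[:5]}"
            )
    tests: list[tuple[str, str, int, int, int]] = []
    for label in sorted(clusters):
        members = set(clusters[label])
        n = len(members)
        for term in sorted(term_map):
            term_genes = set(term_map[term]) & universe_set
            K = len(term_genes)
            k = len(term_genes & members)
            tests.append((label, term, k, K, n))
    if not tests:
        return []
    # survival function at k-1 gives P(X >= k); computed in log space by scipy
    pvals = np.array(
        [hypergeom.sf(k - 1, N, K, n) for (_, _, k, K, n) in tests]
    )
    pvals = np.clip(pvals, 0.0, 1.0)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(label, term, k, K, n, N, float(p), float(f))
        for (label, term, k, K, n), p, f in zip(tests, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.cluster, r.term))
    return results


def retained(results: Iterable[EnrichmentResult], fdr_max: float = 0.01) -> list[EnrichmentResult]:
    return [r for r in results if r.fdr < fdr_max]


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path) -> None:
    rows = [
        {
            "cluster": r.cluster,
            "term": r.term,
            "overlap": r.overlap,
            "term_size": r.term_size,
            "cluster_size": r.cluster_size,
            "universe_size": r.universe_size,
            "p_value": r.p_value,
            "fdr": r.fdr,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "cluster", "term", "overlap", "term_size",
            "cluster_size", "universe_size", "p_value", "fdr",
        ],
    ).to_csv(path, sep="\t", index=False)
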