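"""Synthetic inputs with recorded ground truth for the whole pipeline.

Everything the pipeline consumes can be generated here at toy scale:
proteomes related by a known taxonomy with planted ortholog groups
(duplication, loss, divergence, and a slowly-evolving pore subregion),
UniProt-style metadata with planted integrity defects, pre-aligned MSAs with
planted foreground-conserved columns, and term annotations with planted
enrichment.  Every planted event is recorded in a :class:`TruthSet` so
downstream inference can be scored against known truth.

Sequence evolution model: sites are independent; along a branch of length t
(expected substitutions/site) each site substitutes with probability
1 - e^(-t), multiplied by ``pore_rate_multiplier`` (rho <= 1) inside the
pore subregion, with the replacement drawn uniformly from the other 19
residues.  Gene duplication and loss are Poisson events at rates delta and
ell per unit branch length; a duplicate copies the current sequence and both
copies evolve independently thereafter.  This is deliberately the simplest
model in which reciprocal-best-hit recovery is tunable by branch length.

Each generator stage draws from its own RNG stream derived from the master
seed, so stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from .validation import ProteinMetadata

__all__ = [
    "AMINO_ACIDS",
    "Taxonomy",
    "SimulationConfig",
    "TruthSet",
    "balanced_taxonomy",
    "read_taxonomy",
    "write_taxonomy",
    "simulate_proteomes",
    "corrupt_metadata",
    "simulate_pattern_msa",
    "simulate_term_annotations",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed spawn keys: one RNG stream per generator stage
_STREAM_PROTEOMES = 0
_STREAM_METADATA = 1
_STREAM_MSA = 2
_STREAM_TERMS = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Rooted, branch-lengthed tree with per-tip lineage paths.

    ``lineage_path[tip]`` is the ordered list of labelled clades from the
    root down to (excluding) the tip itself.
    """

    tree: dendropy.Tree
    lineage_path: dict[str, list[str]]

    @property
    def organisms(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def validate(self) -> None:
        orgs = self.organisms
        if len(set(orgs)) != len(orgs):
            raise ValueError("tip organism identifiers must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be >= 0")
        for org in orgs:
            if not self.lineage_path.get(org):
                raise ValueError(f"organism {org!r} has an empty lineage path")


def balanced_taxonomy(
    n_organisms: int,
    branch_length: float = 0.3,
    root_label: str = "Eukaryota",
) -> Taxonomy:
    """Balanced binary tree over ``org01..orgNN`` with equal branch lengths.

    Internal nodes carry clade labels ``{root_label}``, ``CladeA``/``CladeB``
    etc.; tips inherit the path of labels above them as their lineage.
    """
    if n_organisms < 2:
        raise ValueError("need at least 2 organisms")
    names = [f"org{i + 1:02d}" for i in range(n_organisms)]

    counter = [0]

    def build(leaves: list[str], depth: int) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{branch_length}"
        mid = len(leaves) // 2
        counter[0] += 1
        label = root_label if depth == 0 else f"Clade{counter[0]}"
        left = build(leaves[:mid], depth + 1)
        right = build(leaves[mid:], depth + 1)
        return f"({left},{right}){label}:{branch_length}"

    newick = build(names, 0)[: -len(f":{branch_length}")] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return Taxonomy(tree, _lineages_from_tree(tree))


def _lineages_from_tree(tree: dendropy.Tree) -> dict[str, list[str]]:
    lineage: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf.parent_node
        while node is not None:
            if node.label:
                path.append(node.label)
            node = node.parent_node
        if not path:
            path = ["root"]
        lineage[leaf.taxon.label] = list(reversed(path))
    return lineage


def read_taxonomy(path) -> Taxonomy:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tax = Taxonomy(tree, _lineages_from_tree(tree))
    tax.validate()
    return tax


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    taxonomy.tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All generator knobs; defaults define the standard study conditions."""

    seed: int = 0
    n_families: int = 20
    seq_length: int = 150
    # pore-containing functional domains span most of a channel sequence
    # (the curated exemplar covers 220 of 269 residues), hence 0.8
    pore_fraction: float = 0.8
    pore_rate_multiplier: float = 0.5  # rho: substitution slowdown inside the pore
    duplication_rate: float = 0.05  # events per unit branch length
    loss_rate: float = 0.05
    background_freqs: Optional[Sequence[float]] = None  # default uniform over 20
    # metadata corruption probabilities
    p_unreviewed: float = 0.3
    p_low_pe: float = 0.5  # among unreviewed: PE in {4,5}
    p_fragment: float = 0.1
    p_nonstandard: float = 0.1
    p_low_complexity: float = 0.1
    p_high_version: float = 0.1
    p_no_xrefs: float = 0.1
    # MSA parameters
    msa_n_fg: int = 50
    msa_n_bg: int = 200
    msa_length: int = 120
    msa_n_pattern: int = 5
    msa_strength: float = 0.95
    msa_gap_rate: float = 0.02
    # term annotations
    term_p0: float = 0.05
    term_p1: float = 0.8
    n_background_terms: int = 20

    def validate(self) -> None:
        if not 0 < self.pore_rate_multiplier <= 1:
            raise ValueError("pore_rate_multiplier must be in (0, 1]")
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        for name in (
            "p_unreviewed", "p_low_pe", "p_fragment", "p_nonstandard",
            "p_low_complexity", "p_high_version", "p_no_xrefs",
            "msa_gap_rate", "term_p0", "term_p1",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_freqs is not None:
            if abs(sum(self.background_freqs) - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")

    def freqs(self) -> np.ndarray:
        if self.background_freqs is None:
            return np.full(20, 1.0 / 20.0)
        return np.asarray(self.background_freqs, dtype=float)


@dataclass
class TruthSet:
    """Ground truth recorded by the generators."""

    # family -> organism -> gene ids (empty list = planted loss)
    orthogroups: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    co_ortholog_events: list[tuple[str, str]] = field(default_factory=list)  # (organism, family)
    pore_regions: dict[str, tuple[int, int]] = field(default_factory=dict)  # 1-based inclusive
    invalid_records: dict[str, list[str]] = field(default_factory=dict)
    pattern_columns: list[tuple[int, str, float]] = field(default_factory=list)
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)
    # duplication ancestry per gene: list of (event id, child tag) pairs.
    # Two genes are orthologs iff their gene-tree MRCA is a speciation,
    # i.e. their ancestries agree on every duplication event they share.
    gene_signatures: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "orthogroups": self.orthogroups,
            "co_ortholog_events": self.co_ortholog_events,
            "pore_regions": {k: list(v) for k, v in self.pore_regions.items()},
            "invalid_records": self.invalid_records,
            "pattern_columns": [list(t) for t in self.pattern_columns],
            "enriched_terms": self.enriched_terms,
            "gene_signatures": {
                k: [list(e) for e in v] for k, v in self.gene_signatures.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            orthogroups=d["orthogroups"],
            co_ortholog_events=[tuple(t) for t in d["co_ortholog_events"]],
            pore_regions={k: tuple(v) for k, v in d["pore_regions"].items()},
            invalid_records=d["invalid_records"],
            pattern_columns=[tuple(t) for t in d["pattern_columns"]],
            enriched_terms=d["enriched_terms"],
            gene_signatures={
                k: [tuple(e) for e in v]
                for k, v in d.get("gene_signatures", {}).items()
            },
        )

    def _orthologous(self, a: str, b: str) -> bool:
        """True iff genes a, b diverged at a speciation, not a duplication.

        Ancestries are compared event by event: while the event ids match,
        a differing child tag means the genes split at that duplication
        (paralogs / wrong-copy pairs); once the ids differ the remaining
        events are lineage-specific (post-speciation duplications), which
        leave the genes (co-)orthologous.
        """
        sig_a = self.gene_signatures.get(a, [])
        sig_b = self.gene_signatures.get(b, [])
        for (ea, ta), (eb, tb) in zip(sig_a, sig_b):
            if ea != eb:
                return True
            if ta != tb:
                return False
        return True

    def true_pairs(self, reference: str) -> set[tuple[str, str, str]]:
        """(query_gene, organism, target_gene) ortholog triples.

        A pair is included only when the two genes' duplication ancestries
        are compatible (gene-tree MRCA is a speciation); copies split by a
        pre-speciation duplication are paralogs and excluded.
        """
        pairs: set[tuple[str, str, str]] = set()
        for fam, per_org in self.orthogroups.items():
            for q in per_org.get(reference, []):
                for org, genes in per_org.items():
                    if org == reference:
                        continue
                    for g in genes:
                        if self._orthologous(q, g):
                            pairs.add((q, org, g))
        return pairs


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------

def _evolve(
    seq: np.ndarray,
    t: float,
    pore: tuple[int, int],
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of site-independent evolution (see module docstring)."""
    if t <= 0:
        return seq.copy()
    p = 1.0 - math.exp(-t)
    probs = np.full(seq.shape, p)
    probs[pore[0] - 1 : pore[1]] = rho * p
    hit = rng.random(seq.shape) < probs
    out = seq.copy()
    if hit.any():
        # uniform over the other 19 residues
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def simulate_proteomes(
    taxonomy: Taxonomy, config: SimulationConfig
) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Evolve ``n_families`` gene families down the taxonomy.

    Returns per-organism gene dictionaries (organism -> {gene id: sequence})
    and the truth ledger.  Deterministic given config.seed.
    """
    config.validate()
    taxonomy.validate()
    rng = _rng(config.seed, _STREAM_PROTEOMES)
    freqs = config.freqs()
    truth = TruthSet()
    proteomes: dict[str, dict[str, str]] = {o: {} for o in taxonomy.organisms}

    L = config.seq_length
    pore_len = max(2, int(round(config.pore_fraction * L)))
    pore_start = max(1, (L - pore_len) // 2 + 1)
    pore = (pore_start, pore_start + pore_len - 1)

    for fam_idx in range(config.n_families):
        fam = f"fam{fam_idx + 1:03d}"
        truth.orthogroups[fam] = {}
        root_seq = rng.choice(20, size=L, p=freqs)
        # copies alive at a node: list of (sequence, duplication ancestry)
        counter = [0]
        event_counter = [0]

        def descend(node, copies: list[tuple[np.ndarray, tuple]]) -> None:
            t = node.edge.length or 0.0
            evolved: list[tuple[np.ndarray, tuple]] = []
            for c, sig in copies:
                # loss: any Poisson(ell*t) event kills this copy; loss
                # timing within the branch does not affect the outcome
                if rng.poisson(config.loss_rate * t) > 0:
                    continue
                # duplications occur at uniform times along the branch; the
                # lineage evolves piecewise and both children carry the
                # event in their ancestry with distinct tags
                n_dup = rng.poisson(config.duplication_rate * t)
                times = np.sort(rng.uniform(0.0, t, size=n_dup)) if n_dup else []
                lineages = [(c, sig)]
                prev = 0.0
                for tau in times:
                    dt = float(tau) - prev
                    lineages = [
                        (_evolve(s, dt, pore, config.pore_rate_multiplier, rng), g)
                        for s, g in lineages
                    ]
                    event_counter[0] += 1
                    eid = event_counter[0]
                    j = int(rng.integers(len(lineages)))
                    seq_j, sig_j = lineages[j]
                    lineages[j] = (seq_j, sig_j + ((eid, 0),))
                    lineages.append((seq_j.copy(), sig_j + ((eid, 1),)))
                    prev = float(tau)
                dt = t - prev
                evolved.extend(
                    (_evolve(s, dt, pore, config.pore_rate_multiplier, rng), g)
                    for s, g in lineages
                )
            if node.is_leaf():
                org = node.taxon.label
                genes = []
                for c, sig in evolved:
                    counter[0] += 1
                    gid = f"{org}|{fam}|g{counter[0]}"
                    seq = "".join(AMINO_ACIDS[i] for i in c)
                    proteomes[org][gid] = seq
                    truth.pore_regions[gid] = pore
                    truth.gene_signatures[gid] = list(sig)
                    genes.append(gid)
                truth.orthogroups[fam][org] = genes
                if len(genes) > 1:
                    truth.co_ortholog_events.append((org, fam))
            else:
                for child in node.child_nodes():
                    descend(child, evolved)

        root = taxonomy.tree.seed_node
        root_copies = [(root_seq.copy(), ())]
        if root.is_leaf():
            descend(root, root_copies)
        else:
            for child in root.child_nodes():
                descend(child, root_copies)
    return proteomes, truth


def write_fasta(seqs: dict[str, str], path) -> None:
    """Deterministic FASTA writer (insertion order, 60-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Metadata corruption
# ---------------------------------------------------------------------------

def corrupt_metadata(
    records: list[ProteinMetadata], config: SimulationConfig
) -> tuple[list[ProteinMetadata], dict[str, list[str]]]:
    """Plant integrity defects in default-valid metadata records.

    Defects are planted independently with the configured probabilities;
    sequence-level defects are only visible to the validation cascade when
    the record is also demoted to Unreviewed with low protein-existence
    evidence, mirroring how the cascade only scrutinises low-confidence
    entries.  Every planted defect is recorded.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_METADATA)
    truth: dict[str, list[str]] = {}
    out: list[ProteinMetadata] = []
    for rec in records:
        defects: list[str] = []
        entry_type = rec.entry_type
        pe = rec.protein_existence
        version = rec.sequence_version
        seq = rec.sequence
        domains, xrefs = rec.domain_count, rec.xref_count
        if rng.random() < config.p_unreviewed:
            entry_type = "Unreviewed"
            defects.append("unreviewed")
            if rng.random() < config.p_low_pe:
                pe = int(rng.choice([4, 5]))
                defects.append("low_pe")
        if rng.random() < config.p_fragment:
            # fragment (<30 aa) or fusion-like (>5000 aa); fragments dominate
            if rng.random() < 0.9:
                seq = seq[: int(rng.integers(5, 29))]
            else:
                reps = int(math.ceil(5100 / max(len(seq), 1)))
                seq = (seq * reps)[:5100]
            defects.append("length")
        if rng.random() < config.p_nonstandard:
            n_bad = max(1, int(0.1 * len(seq)))
            pos = rng.choice(len(seq), size=min(n_bad, len(seq)), replace=False)
            chars = list(seq)
            for p in pos:
                chars[p] = "X"
            seq = "".join(chars)
            defects.append("nonstandard_aa")
        if rng.random() < config.p_low_complexity:
            run = max(20, int(0.6 * len(seq)))
            seq = "A" * run + seq[run:]
            defects.append("compositional_bias")
        if rng.random() < config.p_high_version:
            version = int(rng.integers(101, 500))
            defects.append("version")
        if rng.random() < config.p_no_xrefs:
            domains = xrefs = 0
            defects.append("crossrefs")
        out.append(
            ProteinMetadata(
                accession=rec.accession,
                entry_type=entry_type,
                protein_existence=pe,
                sequence_version=version,
                sequence=seq,
                domain_count=domains,
                xref_count=xrefs,
            )
        )
        if defects:
            truth[rec.accession] = defects
    return out, truth


def default_metadata(
    proteomes: dict[str, dict[str, str]]
) -> list[ProteinMetadata]:
    """Fully valid (Reviewed, PE=1) metadata for every simulated gene."""
    records = []
    for org in proteomes:
        for gid, seq in proteomes[org].items():
            records.append(
                ProteinMetadata(
                    accession=gid,
                    entry_type="Reviewed",
                    protein_existence=1,
                    sequence_version=1,
                    sequence=seq,
                    domain_count=1,
                    xref_count=3,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Pattern MSA simulation
# ---------------------------------------------------------------------------

def simulate_pattern_msa(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], list[tuple[int, str, float]]]:
    """Pre-aligned MSA with planted foreground-conserved columns.

    Returns (alignment {id: row}, labels {id: 'foreground'|'background'},
    planted columns [(1-based column, residue set, strength)]).  Non-pattern
    columns are i.i.d. from the background profile for everyone; pattern
    columns draw from the planted residue set with probability ``strength``
    in the foreground and from the background profile in the background.
    Gaps are inserted uniformly at ``msa_gap_rate``.
    """
    config.validate()
    if config.msa_n_fg < 2 or config.msa_n_bg < 2:
        raise ValueError("need at least 2 sequences per label")
    if config.msa_n_pattern and not 0.5 < config.msa_strength <= 1:
        raise ValueError("pattern strength must be in (0.5, 1]")
    rng = _rng(config.seed, _STREAM_MSA)
    freqs = config.freqs()
    n_fg, n_bg, L = config.msa_n_fg, config.msa_n_bg, config.msa_length
    n = n_fg + n_bg
    matrix = rng.choice(20, size=(n, L), p=freqs)

    cols = rng.choice(L, size=config.msa_n_pattern, replace=False)
    cols.sort()
    planted: list[tuple[int, str, float]] = []
    for c in cols:
        residue = int(rng.integers(0, 20))
        take = rng.random(n_fg) < config.msa_strength
        matrix[:n_fg, c] = np.where(take, residue, matrix[:n_fg, c])
        planted.append((int(c) + 1, AMINO_ACIDS[residue], config.msa_strength))

    rows = np.array([[AMINO_ACIDS[v] for v in row] for row in matrix], dtype="<U1")
    if config.msa_gap_rate > 0:
        gaps = rng.random((n, L)) < config.msa_gap_rate
        rows[gaps] = "-"

    alignment: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i in range(n_fg):
        sid = f"FG|seq{i + 1:04d}"
        alignment[sid] = "".join(rows[i])
        labels[sid] = "foreground"
    for j in range(n_bg):
        sid = f"BG|seq{j + 1:04d}"
        alignment[sid] = "".join(rows[n_fg + j])
        labels[sid] = "background"
    return alignment, labels, planted


# ---------------------------------------------------------------------------
# Term annotations
# ---------------------------------------------------------------------------

def simulate_term_annotations(
    clusters: dict[str, list[str]], config: SimulationConfig
) -> tuple[dict[str, set[str]], dict[str, list[str]]]:
    """Term -> gene map with one planted enriched term per cluster.

    Background terms hit every gene independently at rate ``term_p0``; each
    cluster gets a dedicated planted term hitting its genes at rate
    ``term_p1`` (> p0) and other genes at p0.  With p1 == p0 nothing is
    planted (null model).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TERMS)
    genes = sorted({g for gs in clusters.values() for g in gs})
    term_map: dict[str, set[str]] = {}
    enriched: dict[str, list[str]] = {}
    for t in range(config.n_background_terms):
        term = f"TERM:{t + 1:04d}"
        term_map[term] = {g for g in genes if rng.random() < config.term_p0}
    if config.term_p1 > config.term_p0:
        for idx, (cluster, members) in enumerate(sorted(clusters.items())):
            term = f"TERM:planted_{cluster}"
            hits = {g for g in members if rng.random() < config.term_p1}
            hits |= {g for g in genes if g not in set(members)
                     and rng.random() < config.term_p0}
            term_map[term] = hits
            enriched.setdefault(cluster, []).append(term)
    return term_map, enriched


def write_term_map(term_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tgene\n")
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")


def read_term_map(path) -> dict[str, set[str]]:
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            term, gene = line.rstrip("\n").split("\t")
            term_map.setdefault(term, set()).add(gene)
    return term_map
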