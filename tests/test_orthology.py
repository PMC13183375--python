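"""Orthology inference: RBH oracle, MCL, filters, relation typing."""

import itertools

import numpy as np
import pytest

from channelome.orthology import (
    OrthologPair,
    OrthologyParams,
    Relation,
    classify_relation,
    filter_within_cluster,
    intersect_evidence,
    markov_cluster,
    reciprocal_best_pairs,
    run_orthology,
)
from channelome.search import ScoringScheme, SimilarityHit, search_all, sort_hits
from channelome.simulate import SimulationConfig, balanced_taxonomy, simulate_proteomes
from channelome.validation import ProteinMetadata


def hit(q, t, bit, ev=1e-30):
    return SimilarityHit(q, t, bit * 2.0, bit, ev, (1, 10), (1, 10))


RELAXED = OrthologyParams(
    forward_evalue_max=1e-3, reciprocal_evalue_max=1e-3, inflation=1.5
)


class TestReciprocalBestPairs:
    def test_single_mutual_pair(self):
        fwd = [hit("q1", "t1", 100.0)]
        rec = [hit("t1", "q1", 100.0)]
        assert reciprocal_best_pairs(fwd, rec, {"t1": "orgA"}, RELAXED) == [
            ("q1", "t1")
        ]

    def test_asymmetric_top_hit_rejected(self):
        # q1's top hit is t1, but t1's top reciprocal hit is q2
        fwd = [hit("q1", "t1", 100.0)]
        rec = [hit("t1", "q2", 120.0), hit("t1", "q1", 100.0)]
        assert reciprocal_best_pairs(fwd, rec, {"t1": "orgA"}, RELAXED) == []

    def test_empty_inputs(self):
        assert reciprocal_best_pairs([], [], {}, RELAXED) == []

    def test_top_hit_is_per_organism(self):
        fwd = [hit("q1", "a1", 100.0), hit("q1", "b1", 80.0)]
        rec = [hit("a1", "q1", 100.0), hit("b1", "q1", 80.0)]
        orgs = {"a1": "orgA", "b1": "orgB"}
        assert reciprocal_best_pairs(fwd, rec, orgs, RELAXED) == [
            ("q1", "a1"),
            ("q1", "b1"),
        ]

    def test_simulated_proteomes_match_double_loop_oracle(self):
        """RBH on 4 simulated proteomes equals an exhaustive double loop."""
        tax = balanced_taxonomy(4, 0.25)
        cfg = SimulationConfig(seed=13, n_families=8)
        proteomes, _ = simulate_proteomes(tax, cfg)
        ref = tax.organisms[0]
        queries = proteomes[ref]
        database = {
            g: s for o in tax.organisms[1:] for g, s in proteomes[o].items()
        }
        organism_of = {g: o for o in tax.organisms for g in proteomes[o]}
        scheme = ScoringScheme()
        fwd = search_all(queries, database, scheme, RELAXED.forward_evalue_max)
        cand = sorted({h.target for h in fwd})
        rec = search_all(
            {t: database[t] for t in cand}, queries, scheme,
            RELAXED.reciprocal_evalue_max,
        )
        got = reciprocal_best_pairs(fwd, rec, organism_of, RELAXED)

        # oracle: independent double loop over queries x organisms
        expected = set()
        rec_by_t = {}
        for h in rec:
            rec_by_t.setdefault(h.query, []).append(h)
        for q in queries:
            for org in tax.organisms[1:]:
                org_hits = [h for h in fwd
                            if h.query == q and organism_of[h.target] == org]
                if not org_hits:
                    continue
                top = sort_hits(org_hits)[0].target
                back = rec_by_t.get(top)
                if back and sort_hits(back)[0].target == q:
                    expected.add((q, top))
        assert set(got) == expected


def reference_mcl(edges, inflation, n_iter=200):
    """Minimal independent MCL transcription for cross-checking."""
    nodes = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, w in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = max(A[idx[u], idx[v]], w)
    loops = A.max(axis=0)
    loops[loops == 0] = 1.0
    A[np.diag_indices(n)] = loops
    M = A / A.sum(axis=0)
    for _ in range(n_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, 2) ** inflation
        M /= M.sum(axis=0)
        if np.max(np.abs(M - prev)) < 1e-6:
            break
    clusters = []
    for i in range(n):
        if M[i, i] > 1e-7:
            members = frozenset(nodes[j] for j in range(n) if M[i, j] > 1e-7)
            clusters.append(members)
    merged = []
    for c in clusters:
        overlapping = [m for m in merged if m & c]
        for m in overlapping:
            merged.remove(m)
            c = c | m
        merged.append(c)
    covered = set().union(*merged) if merged else set()
    merged += [frozenset({nodes[i]}) for i in range(n) if nodes[i] not in covered]
    return {frozenset(c) for c in merged}


def partition_sets(assignment):
    out = {}
    for node, cid in assignment.items():
        out.setdefault(cid, set()).add(node)
    return {frozenset(s) for s in out.values()}


class TestMarkovCluster:
    def test_two_disconnected_triangles(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                 ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
        clusters = markov_cluster(edges, 1.5)
        assert partition_sets(clusters) == {
            frozenset({"a", "b", "c"}), frozenset({"x", "y", "z"})
        }

    def test_single_node(self):
        assert markov_cluster([("a", "a", 1.0)], 2.0) == {"a": 0}

    def test_empty_graph(self):
        assert markov_cluster([], 1.5) == {}

    def test_clusters_refine_connected_components(self, rng):
        import networkx as nx

        for trial in range(5):
            n = 8
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1e6)))
            edges = [(str(u), str(v), 1.0) for u, v in g.edges]
            if not edges:
                continue
            clusters = markov_cluster(edges, 1.8)
            comp_of = {}
            for i, comp in enumerate(nx.connected_components(g)):
                for node in comp:
                    comp_of[str(node)] = i
            for u, cid in clusters.items():
                for v, cid2 in clusters.items():
                    if cid == cid2 and u in comp_of and v in comp_of:
                        assert comp_of[u] == comp_of[v]

    def test_matches_independent_reference_implementation(self, rng):
        for trial in range(8):
            n_nodes = int(rng.integers(3, 9))
            nodes = [f"n{i}" for i in range(n_nodes)]
            edges = []
            for i, j in itertools.combinations(range(n_nodes), 2):
                if rng.random() < 0.4:
                    edges.append((nodes[i], nodes[j], float(rng.integers(1, 5))))
            if not edges:
                continue
            got = partition_sets(markov_cluster(edges, 2.0))
            want = reference_mcl(edges, 2.0)
            assert got == want, edges


class TestFilterAndIntersect:
    def test_single_cluster_is_identity(self):
        pairs = [("q", "a"), ("q", "b")]
        clusters = {"q": 0, "a": 0, "b": 0}
        assert filter_within_cluster(pairs, clusters) == pairs

    def test_cross_cluster_pair_dropped(self):
        assert filter_within_cluster([("q", "a")], {"q": 0, "a": 1}) == []

    def test_missing_assignment_is_an_error(self):
        with pytest.raises(KeyError, match="a"):
            filter_within_cluster([("q", "a")], {"q": 0})

    def test_random_partitions_match_set_comprehension(self, rng):
        nodes = [f"n{i}" for i in range(12)]
        for _ in range(10):
            clusters = {n: int(rng.integers(0, 3)) for n in nodes}
            pairs = [
                (nodes[i], nodes[j])
                for i, j in itertools.combinations(range(12), 2)
                if rng.random() < 0.3
            ]
            got = filter_within_cluster(pairs, clusters)
            want = [(a, b) for a, b in pairs if clusters[a] == clusters[b]]
            assert got == want

    def test_intersection_identical_inputs(self):
        pairs = [("q", "t1"), ("q", "t2")]
        out = intersect_evidence(pairs, pairs, {"t1": "o1", "t2": "o2"})
        assert len(out) == 2
        assert all(p.evidence == {"full_length", "domain"} for p in out)

    def test_intersection_disjoint_inputs_empty(self):
        assert intersect_evidence([("q", "t1")], [("q", "t2")], {"t1": "o", "t2": "o"}) == []

    def test_intersection_matches_set_oracle(self, rng):
        universe = [(f"q{i}", f"t{j}") for i in range(4) for j in range(6)]
        orgs = {f"t{j}": f"org{j % 3}" for j in range(6)}
        for _ in range(10):
            full = {p for p in universe if rng.random() < 0.5}
            dom = {p for p in universe if rng.random() < 0.5}
            got = {(p.query, p.target) for p in intersect_evidence(full, dom, orgs)}
            assert got == full & dom
            assert len(got) <= min(len(full), len(dom))


class TestClassifyRelation:
    def test_unique_mutual_pair_is_one_to_one(self):
        pairs = [OrthologPair("q", "o1", "t1")]
        out = classify_relation(pairs)
        assert out[0].relation is Relation.one_to_one

    def test_planted_duplication_marks_co_orthologs(self):
        pairs = [OrthologPair("q", "o1", "t1"), OrthologPair("q", "o1", "t2")]
        out = classify_relation(pairs)
        assert all(p.relation is Relation.co_ortholog for p in out)

    def test_shared_target_marks_co_orthologs(self):
        pairs = [OrthologPair("q1", "o1", "t1"), OrthologPair("q2", "o1", "t1")]
        out = classify_relation(pairs)
        assert all(p.relation is Relation.co_ortholog for p in out)


class TestRunOrthology:
    def test_zero_divergence_perfect_recovery(self):
        """Identical sequences: one one-to-one pair per query per organism."""
        tax = balanced_taxonomy(4, 0.0)
        cfg = SimulationConfig(seed=2, n_families=4, duplication_rate=0, loss_rate=0)
        proteomes, truth = simulate_proteomes(tax, cfg)
        ref = tax.organisms[0]
        queries = dict(proteomes[ref])
        domains = {g: truth.pore_regions[g] for g in queries}
        targets = {o: g for o, g in proteomes.items() if o != ref}
        pairs, ledger = run_orthology(queries, domains, targets, None, RELAXED)
        pred = {(p.query, p.organism, p.target) for p in pairs}
        assert pred == truth.true_pairs(ref)
        assert all(p.relation is Relation.one_to_one for p in pairs)
        assert ledger == []

    def test_planted_co_ortholog_recovered_with_relation(self):
        """A lineage-specific duplication yields co-ortholog labels that
        match the planted truth events."""
        tax = balanced_taxonomy(4, 0.2)
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, n_families=5,
                                   duplication_rate=0.4, loss_rate=0.0)
            proteomes, truth = simulate_proteomes(tax, cfg)
            ref = tax.organisms[0]
            events = [e for e in truth.co_ortholog_events if e[0] != ref]
            if events:
                break
        else:  # pragma: no cover - simulation virtually always duplicates
            pytest.fail("no duplication planted in 40 seeds")
        queries = dict(proteomes[ref])
        domains = {g: truth.pore_regions[g] for g in queries}
        targets = {o: g for o, g in proteomes.items() if o != ref}
        pairs, _ = run_orthology(queries, domains, targets, None, RELAXED)
        by_cell = {}
        for p in pairs:
            by_cell.setdefault((p.query, p.organism), []).append(p)
        org, fam = events[0]
        cell_pairs = [
            p for (q, o), ps in by_cell.items() if o == org
            for p in ps if fam in p.query
        ]
        assert cell_pairs, "duplicated family not recovered at all"
        if len(cell_pairs) > 1:
            assert all(p.relation is Relation.co_ortholog for p in cell_pairs)

    def test_planted_fragment_dropped_with_reason(self):
        tax = balanced_taxonomy(4, 0.0)
        cfg = SimulationConfig(seed=2, n_families=2, duplication_rate=0, loss_rate=0)
        proteomes, truth = simulate_proteomes(tax, cfg)
        ref = tax.organisms[0]
        queries = dict(proteomes[ref])
        domains = {g: truth.pore_regions[g] for g in queries}
        targets = {o: g for o, g in proteomes.items() if o != ref}
        metadata = {}
        victim = next(iter(targets[tax.organisms[1]]))
        for org in targets:
            for g, seq in targets[org].items():
                if g == victim:
                    metadata[g] = ProteinMetadata(g, "Unreviewed", 4, 1, seq[:12], 1, 1)
                else:
                    metadata[g] = ProteinMetadata(g, "Reviewed", 1, 1, seq, 1, 1)
        pairs, ledger = run_orthology(queries, domains, targets, metadata, RELAXED)
        assert all(p.target != victim for p in pairs)
        assert any(t == victim and "length" in reason for _, t, reason in ledger)

    def test_determinism(self):
        tax = balanced_taxonomy(4, 0.2)
        cfg = SimulationConfig(seed=8, n_families=3)
        proteomes, truth = simulate_proteomes(tax, cfg)
        ref = tax.organisms[0]
        queries = dict(proteomes[ref])
        domains = {g: truth.pore_regions[g] for g in queries}
        targets = {o: g for o, g in proteomes.items() if o != ref}
        first, _ = run_orthology(queries, domains, targets, None, RELAXED)
        second, _ = run_orthology(queries, domains, targets, None, RELAXED)
        assert first == second
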