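"""Synthetic-data generators: reproducibility, planted truth, closed forms."""

import math

import numpy as np
import pytest

from channelome.simulate import (
    SimulationConfig,
    TruthSet,
    balanced_taxonomy,
    corrupt_metadata,
    default_metadata,
    read_taxonomy,
    simulate_pattern_msa,
    simulate_proteomes,
    simulate_term_annotations,
    write_fasta,
    write_taxonomy,
    _evolve,
)
from channelome.validation import ProteinMetadata, validate_batch

GOOD_SEQ = "MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGEENFKALVLIA" * 3


class TestTaxonomy:
    def test_balanced_tree_shape_and_lineages(self):
        tax = balanced_taxonomy(8, 0.3)
        assert len(tax.organisms) == 8
        assert all(tax.lineage_path[o] for o in tax.organisms)
        tax.validate()

    def test_newick_round_trip(self, tmp_path):
        tax = balanced_taxonomy(4, 0.5)
        path = tmp_path / "tax.nwk"
        write_taxonomy(tax, path)
        back = read_taxonomy(path)
        assert back.organisms == tax.organisms
        assert back.lineage_path == tax.lineage_path


class TestProteomeSimulation:
    def test_zero_rates_give_identical_copies(self):
        tax = balanced_taxonomy(4, 0.0)
        cfg = SimulationConfig(seed=5, n_families=3, duplication_rate=0, loss_rate=0)
        proteomes, truth = simulate_proteomes(tax, cfg)
        for fam, per_org in truth.orthogroups.items():
            seqs = {
                proteomes[org][g] for org, genes in per_org.items() for g in genes
            }
            assert len(seqs) == 1  # all organisms carry the root sequence
        assert truth.co_ortholog_events == []

    def test_saturating_loss_removes_family_everywhere(self):
        tax = balanced_taxonomy(4, 0.3)
        cfg = SimulationConfig(seed=5, n_families=2, duplication_rate=0, loss_rate=1e6)
        proteomes, truth = simulate_proteomes(tax, cfg)
        for fam, per_org in truth.orthogroups.items():
            assert all(genes == [] for genes in per_org.values())
        assert all(not genes for genes in proteomes.values())

    def test_per_branch_substitution_fraction_closed_form(self):
        """Fraction of substituted sites on one branch is 1 - e^(-t), within
        a binomial 99% CI at length 500 (outside the pore region)."""
        rng = np.random.default_rng(7)
        L, t = 500, 0.4
        seq = rng.integers(0, 20, size=L)
        pore = (1, 0)  # empty pore region
        fractions = []
        for _ in range(20):
            out = _evolve(seq, t, pore, 1.0, rng)
            fractions.append(np.mean(out != seq))
        p = 1 - math.exp(-t)
        se = math.sqrt(p * (1 - p) / (L * 20))
        assert abs(np.mean(fractions) - p) < 2.58 * se

    def test_pore_region_diverges_slower(self):
        tax = balanced_taxonomy(4, 0.5)
        cfg = SimulationConfig(
            seed=9, n_families=10, duplication_rate=0, loss_rate=0,
            pore_rate_multiplier=0.3,
        )
        proteomes, truth = simulate_proteomes(tax, cfg)
        inside, outside = [], []
        orgs = tax.organisms
        for fam, per_org in truth.orthogroups.items():
            g1, g2 = per_org[orgs[0]][0], per_org[orgs[-1]][0]
            s1, s2 = proteomes[orgs[0]][g1], proteomes[orgs[-1]][g2]
            ps, pe = truth.pore_regions[g1]
            for i, (a, b) in enumerate(zip(s1, s2), start=1):
                (inside if ps <= i <= pe else outside).append(a == b)
        assert np.mean(inside) > np.mean(outside)

    def test_bitwise_reproducibility(self, tmp_path):
        tax = balanced_taxonomy(4, 0.3)
        cfg = SimulationConfig(seed=11, n_families=4)
        p1, t1 = simulate_proteomes(tax, cfg)
        p2, t2 = simulate_proteomes(balanced_taxonomy(4, 0.3), cfg)
        assert p1 == p2
        assert t1.orthogroups == t2.orthogroups
        f1, f2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(p1[tax.organisms[0]], f1)
        write_fasta(p2[tax.organisms[0]], f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_gene_ledger_consistency(self):
        tax = balanced_taxonomy(8, 0.3)
        cfg = SimulationConfig(seed=3, n_families=6)
        proteomes, truth = simulate_proteomes(tax, cfg)
        emitted = {g for org in proteomes for g in proteomes[org]}
        in_truth = {
            g for per_org in truth.orthogroups.values()
            for genes in per_org.values() for g in genes
        }
        assert emitted == in_truth
        assert set(truth.pore_regions) == emitted
        assert set(truth.gene_signatures) == emitted

    def test_truth_json_round_trip(self, tmp_path):
        tax = balanced_taxonomy(4, 0.3)
        _, truth = simulate_proteomes(tax, SimulationConfig(seed=2, n_families=3))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthSet.from_json(path)
        assert back.orthogroups == truth.orthogroups
        assert back.gene_signatures == truth.gene_signatures
        assert back.true_pairs("org01") == truth.true_pairs("org01")

    def test_paralogs_excluded_from_true_pairs(self):
        """Genes split by a shared duplication event are not orthologs."""
        truth = TruthSet(
            orthogroups={"f": {"ref": ["q"], "o": ["t0", "t1", "t2"]}},
            gene_signatures={
                "q": [(1, 0)],
                "t0": [(1, 0)],       # same copy: ortholog
                "t1": [(1, 1)],       # split at duplication 1: paralog
                "t2": [(2, 0)],       # lineage-specific event: co-ortholog
            },
        )
        pairs = truth.true_pairs("ref")
        assert ("q", "o", "t0") in pairs
        assert ("q", "o", "t1") not in pairs
        assert ("q", "o", "t2") in pairs


class TestMetadataCorruption:
    def test_no_corruption_passes_cascade(self):
        cfg = SimulationConfig(
            seed=1, p_unreviewed=0, p_fragment=0, p_nonstandard=0,
            p_low_complexity=0, p_high_version=0, p_no_xrefs=0,
        )
        records = [ProteinMetadata(f"P{i}", "Reviewed", 1, 1, GOOD_SEQ, 1, 2)
                   for i in range(50)]
        out, truth = corrupt_metadata(records, cfg)
        assert truth == {}
        verdicts = validate_batch(out)
        assert all(v.passed for v in verdicts.values())

    def test_fragment_probability_one_fails_length(self):
        cfg = SimulationConfig(
            seed=1, p_unreviewed=1, p_low_pe=1, p_fragment=1,
            p_nonstandard=0, p_low_complexity=0, p_high_version=0, p_no_xrefs=0,
        )
        records = [ProteinMetadata(f"P{i}", "Reviewed", 1, 1, GOOD_SEQ, 1, 2)
                   for i in range(30)]
        out, truth = corrupt_metadata(records, cfg)
        verdicts = validate_batch(out)
        for rec in out:
            assert "length" in truth[rec.accession]
            assert not verdicts[rec.accession].passed
            assert "length" in verdicts[rec.accession].failed_checks

    def test_verdicts_match_planted_truth(self):
        """Cascade verdicts over a corrupted batch equal the verdict implied
        by each record's planted defect list."""
        cfg = SimulationConfig(seed=21)
        records = [ProteinMetadata(f"P{i:03d}", "Reviewed", 1, 1, GOOD_SEQ, 1, 2)
                   for i in range(300)]
        out, truth = corrupt_metadata(records, cfg)
        verdicts = validate_batch(out)
        step3 = {"length", "nonstandard_aa", "compositional_bias", "version", "crossrefs"}
        for rec in out:
            defects = set(truth.get(rec.accession, []))
            scrutinised = "unreviewed" in defects and "low_pe" in defects
            want_pass = not (scrutinised and defects & step3)
            assert verdicts[rec.accession].passed == want_pass, (
                rec.accession, defects,
            )


class TestPatternMSA:
    def test_full_strength_no_gaps_planted_columns_invariant(self):
        cfg = SimulationConfig(
            seed=4, msa_strength=1.0, msa_gap_rate=0.0,
            msa_n_fg=10, msa_n_bg=20, msa_length=40, msa_n_pattern=3,
        )
        aln, labels, planted = simulate_pattern_msa(cfg)
        for col, residue, strength in planted:
            fg_residues = {
                aln[sid][col - 1] for sid in aln if labels[sid] == "foreground"
            }
            assert fg_residues == {residue}

    def test_zero_planted_columns(self):
        cfg = SimulationConfig(seed=4, msa_n_pattern=0, msa_n_fg=5, msa_n_bg=5,
                               msa_length=30)
        aln, labels, planted = simulate_pattern_msa(cfg)
        assert planted == []
        assert len(aln) == 10

    def test_foreground_frequency_matches_strength(self):
        cfg = SimulationConfig(
            seed=8, msa_strength=0.9, msa_gap_rate=0.0,
            msa_n_fg=200, msa_n_bg=10, msa_length=50, msa_n_pattern=4,
        )
        aln, labels, planted = simulate_pattern_msa(cfg)
        fg = [sid for sid in aln if labels[sid] == "foreground"]
        hits = total = 0
        for col, residue, strength in planted:
            hits += sum(aln[sid][col - 1] == residue for sid in fg)
            total += len(fg)
        p = 0.9 + (1 - 0.9) / 20  # strength plus background accidental hits
        se = math.sqrt(p * (1 - p) / total)
        assert abs(hits / total - p) < 2.58 * se


class TestTermAnnotations:
    def test_null_has_no_planted_terms(self):
        cfg = SimulationConfig(seed=6, term_p0=0.1, term_p1=0.1)
        clusters = {"c1": [f"g{i}" for i in range(10)]}
        term_map, enriched = simulate_term_annotations(clusters, cfg)
        assert enriched == {}
        assert all(t.startswith("TERM:0") for t in term_map)

    def test_planted_term_targets_cluster(self):
        cfg = SimulationConfig(seed=6, term_p0=0.05, term_p1=1.0)
        clusters = {
            "c1": [f"g{i}" for i in range(10)],
            "c2": [f"h{i}" for i in range(10)],
        }
        term_map, enriched = simulate_term_annotations(clusters, cfg)
        planted = enriched["c1"][0]
        assert set(clusters["c1"]) <= term_map[planted]

    def test_background_counts_binomial(self):
        cfg = SimulationConfig(seed=6, term_p0=0.2, term_p1=0.2,
                               n_background_terms=100)
        genes = [f"g{i}" for i in range(50)]
        term_map, _ = simulate_term_annotations({"c": genes}, cfg)
        total = sum(len(v) for v in term_map.values())
        n = 100 * 50
        se = math.sqrt(0.2 * 0.8 / n)
        assert abs(total / n - 0.2) < 2.58 * se


def test_default_metadata_is_fully_valid():
    tax = balanced_taxonomy(4, 0.2)
    proteomes, _ = simulate_proteomes(tax, SimulationConfig(seed=1, n_families=3))
    records = default_metadata(proteomes)
    assert all(v.passed for v in validate_batch(records).values())
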