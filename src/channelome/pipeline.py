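"""End-to-end orchestration of the synthetic demonstration pipeline.

``run_pipeline`` wires the stages together — simulate -> search -> ortholog
-> validate -> profile -> enrich -> patterns — on generated data with
recorded ground truth, writes every intermediate as a plain-text file under
the output directory, and emits a JSON manifest listing the configuration,
master seed and SHA-256 digest of each output.  Re-running with the same
configuration reproduces the digests bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import simulate as sim
from .orthology import OrthologyParams, run_orthology, write_pairs_tsv
from .patterns import PatternParams, select_pattern_positions, write_patterns_tsv
from .profiling import (
    build_profile_matrix,
    cluster_profiles,
    enrich_terms,
    lineage_family_percentage,
    retained,
    write_enrichment_tsv,
)
from .search import ScoringScheme, search_all, write_tabular_hits
from .simulate import SimulationConfig, balanced_taxonomy
from .validation import (
    ValidationParams,
    validate_batch,
    write_metadata_tsv,
    write_verdicts,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("channelome")

ALL_STAGES = (
    "simulate", "search", "ortholog", "validate", "profile", "enrich", "patterns",
)


@dataclass
class PipelineConfig:
    outdir: str = "channelome_run"
    seed: int = 0
    n_organisms: int = 8
    branch_length: float = 0.3
    forward_evalue_max: float = 1e-5
    reciprocal_evalue_max: float = 1e-6  # relaxed for short synthetic sequences
    inflation: float = 1.5
    forward_mode: str = "top"
    n_clusters: int = 9
    enrichment_fdr: float = 0.01
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.simulation.seed = self.seed


def load_config(path, **overrides) -> PipelineConfig:
    """Flat TOML config: pipeline keys at top level, simulator keys under
    ``[simulation]``; keyword overrides win."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    sim_data = data.pop("simulation", {})
    data.update(overrides)
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    cfg = PipelineConfig(**data, simulation=SimulationConfig(**sim_data))
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages; return (and write) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"
        },
        "simulation": dataclasses.asdict(config.simulation),
        "stages": [],
        "outputs": {},
    }
    manifest["config"]["stages"] = list(config.stages)
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path

    scheme = ScoringScheme()
    params = OrthologyParams(
        forward_evalue_max=config.forward_evalue_max,
        reciprocal_evalue_max=config.reciprocal_evalue_max,
        inflation=config.inflation,
        forward_mode=config.forward_mode,
    )

    taxonomy = proteomes = truth = None
    queries = domains = metadata = None
    pairs = None
    cluster_map = None

    if "simulate" in config.stages:
        log.info("stage simulate: %d organisms, %d families",
                 config.n_organisms, config.simulation.n_families)
        taxonomy = balanced_taxonomy(config.n_organisms, config.branch_length)
        proteomes, truth = sim.simulate_proteomes(taxonomy, config.simulation)
        reference = taxonomy.organisms[0]
        queries = dict(proteomes[reference])
        domains = {g: truth.pore_regions[g] for g in queries}
        records = sim.default_metadata(proteomes)
        records, invalid = sim.corrupt_metadata(records, config.simulation)
        truth.invalid_records = invalid
        metadata = {r.accession: r for r in records}

        sim.write_taxonomy(taxonomy, out / "taxonomy.nwk")
        emit("taxonomy", out / "taxonomy.nwk")
        prot_dir = out / "proteomes"
        prot_dir.mkdir(exist_ok=True)
        for org in proteomes:
            sim.write_fasta(proteomes[org], prot_dir / f"{org}.fasta")
            emit(f"proteome_{org}", prot_dir / f"{org}.fasta")
        sim.write_fasta(queries, out / "queries.fasta")
        emit("queries", out / "queries.fasta")
        with open(out / "query_domains.tsv", "w") as fh:
            fh.write("query\tstart\tend\n")
            for g, (s, e) in domains.items():
                fh.write(f"{g}\t{s}\t{e}\n")
        emit("query_domains", out / "query_domains.tsv")
        write_metadata_tsv(records, out / "metadata.tsv")
        emit("metadata", out / "metadata.tsv")
        truth.to_json(out / "truth.json")
        emit("truth", out / "truth.json")
        manifest["stages"].append("simulate")

    if "search" in config.stages:
        if proteomes is None:
            raise RuntimeError("stage search: no proteomes (enable simulate)")
        log.info("stage search: forward similarity search")
        database = {g: s for org in proteomes for g, s in proteomes[org].items()}
        hits = search_all(queries, database, scheme, params.forward_evalue_max)
        write_tabular_hits(hits, out / "forward_hits.tsv")
        emit("forward_hits", out / "forward_hits.tsv")
        manifest["stages"].append("search")

    if "ortholog" in config.stages:
        if proteomes is None:
            raise RuntimeError("stage ortholog: no proteomes (enable simulate)")
        log.info("stage ortholog: dual-evidence RBH pipeline")
        target_proteomes = {
            org: genes
            for org, genes in proteomes.items()
            if org != taxonomy.organisms[0]
        }
        pairs, ledger = run_orthology(
            queries, domains, target_proteomes, metadata, params, scheme
        )
        write_pairs_tsv(pairs, out / "orthologs.tsv")
        emit("orthologs", out / "orthologs.tsv")
        with open(out / "drop_ledger.tsv", "w") as fh:
            fh.write("query\ttarget\treason\n")
            for q, t, r in ledger:
                fh.write(f"{q}\t{t}\t{r}\n")
        emit("drop_ledger", out / "drop_ledger.tsv")
        manifest["stages"].append("ortholog")

    if "validate" in config.stages:
        if metadata is None:
            raise RuntimeError("stage validate: no metadata (enable simulate)")
        log.info("stage validate: %d records", len(metadata))
        verdicts = validate_batch(metadata.values(), ValidationParams())
        write_verdicts(verdicts.values(), out / "validation.tsv")
        emit("validation", out / "validation.tsv")
        manifest["stages"].append("validate")

    matrix = None
    if "profile" in config.stages:
        if pairs is None:
            raise RuntimeError("stage profile: no ortholog pairs (enable ortholog)")
        log.info("stage profile: state matrix and Ward clustering")
        organisms = [o for o in taxonomy.organisms if o != taxonomy.organisms[0]]
        matrix = build_profile_matrix(
            pairs, list(queries), organisms, taxonomy.lineage_path
        )
        matrix.to_tsv(out / "profile_matrix.tsv")
        emit("profile_matrix", out / "profile_matrix.tsv")
        k = min(config.n_clusters, len(matrix.queries))
        assignment, _ = cluster_profiles(matrix, k, lineage=None)
        cluster_map = {}
        for gene, label in assignment.items():
            cluster_map.setdefault(f"cluster{label}", []).append(gene)
        with open(out / "profile_clusters.tsv", "w") as fh:
            fh.write("query\tcluster\n")
            for gene, label in sorted(assignment.items()):
                fh.write(f"{gene}\tcluster{label}\n")
        emit("profile_clusters", out / "profile_clusters.tsv")
        # family x lineage percentage summary (family = simulated family id)
        family_map = {g: g.split("|")[1] for g in matrix.queries}
        lineages = sorted({l for path in taxonomy.lineage_path.values() for l in path})
        with open(out / "lineage_summary.tsv", "w") as fh:
            fh.write("family\tlineage\tpercentage\tfound\tn_organisms\tfamily_size\n")
            for fam in sorted(set(family_map.values())):
                for lin in lineages:
                    if not matrix.organisms_in_lineage(lin):
                        continue
                    s = lineage_family_percentage(matrix, family_map, lin, fam)
                    fh.write(
                        f"{s.family}\t{s.lineage}\t{s.percentage:.2f}\t"
                        f"{s.found}\t{s.n_organisms}\t{s.family_size}\n"
                    )
        emit("lineage_summary", out / "lineage_summary.tsv")
        manifest["stages"].append("profile")

    if "enrich" in config.stages:
        if cluster_map is None:
            raise RuntimeError("stage enrich: no clusters (enable profile)")
        log.info("stage enrich: term enrichment per cluster")
        term_map, enriched_truth = sim.simulate_term_annotations(
            cluster_map, config.simulation
        )
        sim.write_term_map(term_map, out / "terms.tsv")
        emit("terms", out / "terms.tsv")
        universe = [g for genes in cluster_map.values() for g in genes]
        results = enrich_terms(cluster_map, term_map, universe)
        write_enrichment_tsv(results, out / "enrichment.tsv")
        emit("enrichment", out / "enrichment.tsv")
        write_enrichment_tsv(
            retained(results, config.enrichment_fdr),
            out / "enrichment_retained.tsv",
        )
        emit("enrichment_retained", out / "enrichment_retained.tsv")
        manifest["stages"].append("enrich")

    if "patterns" in config.stages:
        log.info("stage patterns: conserved-pattern detection")
        alignment, labels, planted = sim.simulate_pattern_msa(config.simulation)
        sim.write_fasta(alignment, out / "pattern_msa.fasta")
        emit("pattern_msa", out / "pattern_msa.fasta")
        with open(out / "pattern_truth.json", "w") as fh:
            json.dump([list(t) for t in planted], fh)
        emit("pattern_truth", out / "pattern_truth.json")
        positions = select_pattern_positions(
            alignment, labels, PatternParams(seed=config.seed)
        )
        write_patterns_tsv(positions, out / "patterns.tsv")
        emit("patterns", out / "patterns.tsv")
        manifest["stages"].append("patterns")

    for name, path in outputs.items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
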