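# Methods

This note documents the models, statistics and design choices behind the
package, in the order the pipeline runs.

## Annotation model

Membrane segments are 1-based inclusive intervals (UniProt convention) with
kind TM (fully membrane-crossing) or IM (partially embedded). The segment
list dialect is comma-separated `K:start-end` tokens with `K ∈ {T, I}`;
both the ASCII hyphen and the en-dash are accepted on input and the hyphen
is emitted on output, so parse∘format is the identity.

The pore-containing functional domain is defined as the smallest span
containing every TM segment. Its `reported_length` is `end − start`,
matching the printed convention of the curated table (the exemplar row
reports 220 for the span 8–228); because that convention is one short of
the inclusive residue count, the inclusive `span = end − start + 1` is
exposed alongside. Unit classification is a total function: a pore domain
present → pore-containing (or two-pore when the curated two-pore flag is
set — this is curated input, not computed, since no detection rule exists
for it); absent with complex-membership evidence → auxiliary; absent
without evidence → excluded from the curated list.

## Synthetic data generator

The generator emulates every input the pipeline consumes, with all planted
events recorded in a `TruthSet`.

**Sequence evolution.** Each family starts from a root sequence drawn from
the background amino-acid frequencies (uniform by default). Along a branch
of length `t` (expected substitutions/site) each site substitutes with
probability `1 − e^(−t)`, multiplied by ρ ≤ 1 inside the pore subregion
(default ρ = 0.5), with replacement uniform over the other 19 residues.
Sites are independent; there is no indel process (synthetic MSAs are
emitted pre-aligned). The closed form `1 − e^(−t)` holds exactly for a
branch without duplication events; when a branch carries duplications the
lineage evolves piecewise around the event times, which allows occasional
within-branch back-substitution.

**Duplication and loss.** Copy loss is Poisson(ℓ·t) per copy per branch
(any event kills the copy; timing is irrelevant to the outcome).
Duplications are Poisson(δ·t), placed at uniform times along the branch; a
duplicate copies the current sequence and both copies evolve independently
afterwards, which makes recent duplicates detectably more similar to each
other than to cross-species orthologs. Defaults δ = ℓ = 0.05 events per
unit branch length give a realistic low rate (a few events per 20-family
simulation). Every gene carries its duplication ancestry as a list of
(event id, child tag) pairs, and `TruthSet.true_pairs` applies the standard
orthology definition — two genes are orthologs iff their gene-tree MRCA is
a speciation — by comparing ancestries event by event. Pre-speciation
duplicates are therefore paralogs and excluded from truth, which is the
correct target for any RBH-family method.

**Study conditions.** The default conditions used throughout the tests and
the acceptance measurements are 8 organisms on a balanced taxonomy with
branch length 0.3, 20 families of length 150, pore fraction 0.8 (the
curated exemplar's pore domain covers 220 of 269 residues, so most of a
channel sequence is domain), ρ = 0.5, and δ = ℓ = 0.05. The metadata
corruptor plants the exact defects the validation cascade checks, each with
its own probability; the pattern-MSA generator plants foreground-conserved
columns (default 5 columns at strength 0.95 among 50 foreground / 200
background rows of width 120); the term-annotation generator plants one
enriched term per cluster at rate p1 > p0 over a background rate p0. Each
generator stage draws from its own RNG stream derived from the master seed,
so identical config + seed reproduce identical bytes.

**What the generator does not emulate.** Realistic indel evolution,
alignment error, rate heterogeneity across sites and lineages, composition
bias, and database-scale search heuristics. Passing tests demonstrate the
pipeline's correctness and statistical calibration under the model, not
performance on real proteomes at full scale.

## Similarity search

The search stage computes optimal local alignments (affine gaps; a gap of
length k costs open + k·extend, defaults 11/1; BLOSUM62) through
Bio.Align.PairwiseAligner, with Karlin–Altschul scaling on top:
`bits = (λ·raw − ln K)/ln 2`, `E = K·m·n·e^(−λ·raw)` with the standard
gapped-BLOSUM62 constants λ = 0.267, K = 0.041, m the database letter count
and n the query length. These e-values are monotone in score and
threshold-comparable, which is all the pipeline needs; composition-based
adjustments are omitted. Letters U/O/J are mapped to C/K/L (NCBI
convention); B/Z/X are scored by the matrix. Hits are ranked by
(bit score desc, e-value asc, target id asc) — the fixed tie-break that
makes "top hit" deterministic. Externally computed hits in the 12-column
tabular dialect (BLAST outfmt-6 compatible) can be ingested in place of the
built-in engine; identical hits give identical downstream results.

## Orthology inference

The pipeline is run twice — full-length queries, and pore-domain
subsequences extracted by coordinates — and the two result sets are
intersected, so a retained ortholog satisfies both overall similarity and
conservation of the functionally critical domain.

Within one run: the forward search keeps hits at e ≤ forward cutoff
(default 1e-5); by default only the top hit per (query, organism) proceeds
(an all-hits mode is available). Candidates are searched back against the
query proteome at the reciprocal cutoff; the shipped default is the
catalogue-scale 1e-200, while simulations use relaxed values (short
synthetic sequences cannot reach 1e-200) — both plain configuration. A
pair is a reciprocal best hit when each member is the other's top hit.

RBH alone cannot enumerate co-orthologs (each side's "top hit" is unique),
so seeds are expanded in the style of InParanoid/OrthoMCL: for a seed
(q, t), a same-proteome gene q′ with `bit(q′, q) ≥ bit(q, t)` arose after
the speciation the seed witnesses and inherits the relationship; likewise
on the target side. The relationship graph (RBH + completed pairs +
in-paralog edges) is clustered with MCL — expansion (matrix square),
inflation (entrywise power, default 1.5, plus column renormalisation) to
convergence (max change < 1e-6 or 200 iterations), attractor-based cluster
extraction — and only within-cluster relationships are kept. Edge weights
are alignment bit scores normalised by the organism-pair mean; without this
normalisation (OrthoMCL's), near-identical recent duplicates carry edge
weights an order of magnitude above cross-species edges and inflation
fragments family clusters.

Relation typing: a pair is one-to-one iff its query has exactly one
retained target in that organism and its target exactly one retained
query; any multiplicity marks the affected pairs co-ortholog. The rule is
chosen to coincide with RBH uniqueness; the underlying visualisation
states it emulates (one-to-one vs co-ortholog vs absent) come without a
printed formula.

Retained targets finally pass the validation cascade (below); pairs
dropped there are recorded in a drop ledger with the failing checks.

Measured at the default study conditions over 14 seeds, planted-ortholog
precision and recall are both ≥ 0.95 (typically 1.0); both degrade with
branch length as divergence pushes true pairs past the e-value cutoffs.

## Validation cascade

Step 1: Reviewed entries pass. Step 2: Unreviewed entries with protein
existence 1–3 (protein, transcript, homology) pass. Step 3: the remainder
must pass five checks — sequence version ≤ 100; low-complexity coverage
≤ 0.5 (fraction of residues in any sliding window of 12 whose Shannon
entropy over the 20-letter empirical distribution is < 2.2 bits, a
SEG-like criterion); non-standard residue fraction ≤ 0.05 (anything
outside the 20 canonical letters counts, including B, J, O, U, X, Z);
length within [30, 5000]; and not lacking both domain annotations and
cross-references. The cascade's source names the checks but no cutoffs;
the thresholds above are package defaults and all configurable, and each
check can be toggled independently. Version staleness ("very old update")
is not evaluated: the metadata schema carries no modification dates, so
only the high-version rule is implemented.

## Profiling and enrichment

The profile matrix assigns every query × organism cell one state: absent
(0), co-ortholog (1), one-to-one (2). Co-orthologs count as "found" in the
family × lineage percentage and encode as 1 (present) for clustering — the
state distinction is display-level; the percentage counts each
(query, organism) cell once regardless of target multiplicity. Clustering
is agglomerative Ward linkage on Euclidean distances of the binary rows
(scipy), restricted to the organisms of a chosen lineage (eukaryotes by
default, matching the sparsity of prokaryotic profiles), cut to exactly k
clusters (k = 9 at catalogue scale; capped at the row count in small
demonstrations).

Enrichment is the one-sided hypergeometric over-representation test,
`p = P(X ≥ k)` with `X ~ Hypergeom(N, K, n)`, computed by scipy's survival
function (log-space internally). BH-FDR is applied across all
cluster × term tests jointly (per-cluster correction available); retained
terms have FDR < 0.01. The universe defaults to the profiled queries.
Because hypergeometric p-values are discrete, they are super-uniform under
the null; the calibration check therefore compares the empirical rejection
rate at α both to α (upper bound) and to the exact attainable null rate
computed from each test's hypergeometric support.

## Pattern positions

For a column with k_F of n_F foreground and k_B of n_B background residues
(gaps excluded) matching a residue set R, with pseudocount a = 1:

    p̂ = (k_F + a)/(n_F + 2a),  q = (k_B + a)/(n_B + 2a)
    score = max(0, k_F·ln(p̂/q) + (n_F − k_F)·ln((1−p̂)/(1−q)))

R is grown greedily from the most frequent foreground residue while the
score strictly increases. Significance is assessed by a label-permutation
null of the column's greedy score: one seeded batch of permutations is
shared by all columns, the identical greedy procedure is applied inside
each permutation, and `p = (1 + #{null ≥ observed})/(P + 1)` (P = 5000 by
default; an exact mode enumerates all label assignments for tiny
alignments). BH-FDR across columns, selection at FDR < 0.01, and mapping
to reference numbering (count of non-gap reference residues up to the
column; reference-gapped columns are labelled "ref-gap" with the preceding
number). Columns where one label class is entirely gapped are skipped.

This is a contrast-statistic analogue of Bayesian pattern-partitioning
approaches, not a re-implementation: there is no hierarchical partition
sampling, and the two-level analysis (family-wide vs clade-specific tiers)
is obtained by running the selector twice with different
foreground/background splits.

Under the exchangeable null the permutation p-values are uniform (checked
by KS over ≥ 2000 columns); planted 5-column patterns at strength 0.95 are
recovered with F1 ≥ 0.9 at the default conditions, with an occasional
borderline false positive expected at roughly the FDR level.

## Pipeline and determinism

The orchestrator wires the stages behind a flat TOML configuration with CLI
overrides; logs go to standard error. All randomness flows from the master
seed through per-stage streams; outputs are plain text (FASTA, TSV, Newick,
JSON) written deterministically, and the manifest records the SHA-256 of
every output, so identical configuration + seed reproduce identical
digests. Problem sizes in the shipped demonstration and acceptance script
(4–8 organisms, 5–20 families, 120–2200 alignment columns, 299–5000
permutations) are chosen to exercise every stage in about a minute on one
CPU; catalogue-scale inputs (~1500 proteomes, thousands of alignment rows)
are outside desk scale and are not emulated.

## Known limitations

- The search engine is exact Smith–Waterman-style alignment without
  heuristic seeding; it is not intended for database-scale search.
- E-values use fixed Karlin–Altschul constants; they are comparable across
  runs of this package, not calibrated against any external tool.
- Orthology truth recovery is measured under the generator's site-
  independent substitution model; real proteomes add alignment error,
  domain shuffling and rate heterogeneity that the model does not capture.
- The enrichment module treats term maps as flat sets (no ontology DAG
  propagation).
- classify_relation's one-to-one rule is a package definition chosen for
  determinism and agreement with RBH uniqueness.
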