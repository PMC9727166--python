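# Methods

This note documents the models, conventions and design choices behind
npfkit, in the order the pipeline runs them, followed by what the synthetic
data does and does not emulate.

## Alignment model and significance

All homology decisions go through one engine: exact Smith–Waterman local
alignment under BLOSUM62 with affine gap penalties. We use the classic
blastp convention in which a gap of length *k* costs 11 + *k* (the aligner
is configured with open = −12 for the first gapped residue and −1 per
additional residue). Significance uses the Karlin–Altschul formula

    E = K · m · n · exp(−λ · S)

with the published gapped-BLOSUM62/11/1 constants λ = 0.267 and K = 0.041,
*m* the query length and *n* the effective database length: the target
length for a pairwise comparison, the total residue count of the database
for a search. No finite-size/length corrections are applied — E-values are
then an exact, invertible function of the raw score, which keeps every
threshold decision reproducible and lets tests verify scores against a
brute-force Gotoh dynamic program.

Conventions that matter for thresholds:

* **identity** = identical columns / alignment columns, *including* gap
  columns in the denominator (the common "pident over the alignment"
  convention);
* **coverage** = span of the local alignment on a sequence / that
  sequence's length;
* the unknown residue **X scores 0** against everything (it can neither
  create nor destroy a match); other ambiguity codes are rejected at load,
  so scoring is fully deterministic.

Database search uses a shared-4-mer prefilter: a target is skipped only
when it shares no length-4 subsequence with the query. In the significance
regime the pipeline operates in (E ≤ 1e−3, i.e. raw scores ≳ 50), a passing
alignment always contains runs of consecutive identities, so the prefilter
is result-neutral; the tests compare filtered and unfiltered searches
directly. At the collection sizes this package targets (≲ 5,000 proteins)
all-vs-all comparison is exact — there is no seed-and-extend heuristic to
tune.

This engine deliberately stands in for heterogeneous production tooling
(translated searches, profile-HMM domain scans): domain tiers are searched
as sequence databases, and all comparisons are protein-level. That is a
fidelity compromise — profile sensitivity is lower than HMM search — but it
preserves the threshold semantics (E-value, identity, coverage) that define
the method, and it makes every verdict auditable.

## Clustering

Families are built on the directed significant-hit graph: edge u→v when the
alignment of u (as query) against v passes E ≤ 1e−3, identity ≥ 0.30 and
query coverage ≥ 0.50. Coverage is evaluated on the query, so a short
protein may join a long representative but not vice versa. Score, identity
and E-value are symmetric under this E-value convention, so each unordered
pair is aligned once and both edge directions are decided from it.

Greedy set cover then repeatedly picks the uncovered protein that the most
uncovered proteins can still join (its uncovered in-neighbours), breaking
ties by longer sequence then lexicographically smaller id, and emits the
representative with those members as one family. This yields an exhaustive,
disjoint partition in which every member holds a qualifying edge onto its
representative (re-verified after every run), and the total tie-break order
makes the output independent of input order. The greedy family count is
checked against an independent re-implementation and against the classical
H(k)·OPT bound via exhaustive minimum covers on small random graphs.

## Novelty cascade

Every member of every family is searched against four tiers with the tier
thresholds: orthologous groups at E < 1e−3, both domain databases at
E < 1e−5, and the reference protein collection at E < 1e−3 *and* query
coverage > 50% (the coverage condition applies to that tier only). One
significant member hit anywhere makes the family KNOWN; otherwise it is an
NPF, or an NS when it has exactly one member in the analysed genome group —
the reading under which NPF and NS counts are disjoint. Verdicts carry the
matching tier and best hit per member, so every KNOWN call is auditable.
Tier search stops at a member's first significant tier (cascade order:
orthologous groups, domain A, domain B, reference); this changes no verdict,
only the evidence recorded.

NS families remain eligible for extension — their class is frozen at
classification time and extension only grows membership — because context
scoring requires extended families of three or more sequences, which
singletons can only reach through recruitment.

## Extension and prior-collection overlap

Each novel family is extended by querying its longest member (ties to the
smallest id) against the external collection; all hits at E ≤ 1e−3 and
query coverage ≥ 0.5 are recruited, with their genome and lineage labels.
A family counts as *present* in a prior novel-family collection when
strictly more than 90% of its members have a significant hit to a single
prior family; the maximising prior family and the exact fraction are
reported.

## Genomic-context conservation

Windows are ordinal: the ±3 genes around the focal gene on its scaffold,
oriented in the focal gene's frame (on the minus strand the gene at
index + 1 appears at offset −1, so +1 is always downstream). Offsets past a
scaffold end are absent; offset 0 is excluded from scoring since the focal
members are by definition unannotated.

For each (offset, namespace, label) the conservation fraction divides the
number of members whose neighbour at that offset carries the label by the
**number of genes in the family** — not by the number of members with an
occupied offset. Members truncated at scaffold edges therefore depress
conservation; this is the stricter of the two readings and the one the
formula states, and the occupancy-based alternative is available from the
recorded per-offset occupancies. The family **conservation score** is the
maximum fraction over all triples — the only aggregation under which
"score ≥ 0.9" guarantees that a specific conserved neighbour exists —
and families with score ≥ 0.9 are selected as conserved. Families with
fewer than three members are skipped with a logged notice, not an error.

Note a structural floor: any family whose members have at least one
annotated neighbour scores at least 1/m, so "score equals planted
conservation exactly" holds whenever the planted quota is ≥ 1 member.

## Dispersion, markers and statistics

For each lineage a family touches: coverage = carrier genomes of the
lineage / genomes of the lineage in the database; specificity = carrier
genomes of the lineage / all carrier genomes. A genome counts once
regardless of member multiplicity, so specificities sum to 1. Markers
require specificity > 0.7 **and** coverage > 0.7, both strict; two
specificities > 0.7 cannot coexist, so a family marks at most one lineage.
Metrics are computed on extended families (post-recruitment); pre-extension
metrics are available by passing the original member sets.

The per-genome novelty percentage is 100 × (proteins in NPF∪NS families) /
(total proteins). Group comparison uses **Welch's** unequal-variance
two-sample t-test (t, Welch–Satterthwaite df, two-sided p) — with group
sizes and variances as unequal as study-vs-reference collections are, the
pooled-variance assumption is untenable; the statistic is cross-checked
against closed-form arithmetic to 1e−10 in the tests.

Binary domain-family presence/absence profiles are clustered with
single-linkage agglomeration on Jaccard distances (d = 1 − |A∩B|/|A∪B|,
d = 0 for two empty profiles) and flattened at cophenetic distance ≤ 0.4.
Single linkage is chosen because a plain "distance with a threshold" rule
is exactly single-linkage connected components; cluster labels are the
smallest genome id of each cluster, for determinism.

## Synthetic data: what it emulates, and what passing means

The generator emulates the *structure* of a genome-resolved study: several
lineages × several genomes, scaffolds of ordered genes, a majority of
proteins diverged from a reference database of known families (each seed
carrying one unique label per annotation namespace), and a minority planted
from novel families with controlled lineage prevalence and neighbourhood
conservation. Defaults — 4 lineages × 5 genomes, 3 scaffolds × 17 genes,
30 reference families, 10% substitution divergence with 1% indels, and ten
planted families (five lineage-exclusive at 80% lineage coverage with
conservation 1.0/0.95/0.9/0.75/0.5, three spread across all lineages, two
singletons) — give ~1,000 proteins, large enough for every stage to act and
small enough for exact all-vs-all alignment.

Planting is quota-based, not Bernoulli: exactly round(c·m) of a family's m
members receive the designated marker neighbour at offset +1 (strand-
aware), carrier genomes are drawn to exact per-lineage quotas, and novel
sequences are rejection-sampled until they share no 8-mer with any
reference sequence. Three placement rules make recovery exact rather than
approximate: planted members sit on a spaced slot grid so no member's ±3
window overlaps another planted member or marker; background genes inside a
planted window never repeat a reference seed at the same (family, offset);
and every seed's labels are unique to it. A single seeded RNG stream is
threaded through all draws in a fixed order, so identical configurations
are bit-reproducible.

What the generator does **not** emulate: realistic amino-acid composition
or substitution processes, phylogenetically correlated divergence between
genomes of a lineage, annotation noise or multi-label genes, partial and
contaminated genomes, or read-level artefacts of assembly and binning.
Passing the recovery tests therefore shows that the pipeline's logic is
exact under its stated thresholds — not that those thresholds would achieve
perfect precision/recall on real proteomes, where homology detection, not
bookkeeping, is the hard part.

## Numerical and engineering choices

* Tie-breaks are total everywhere (hit sorting: E-value, then raw score,
  then target id; greedy cover: gain, length, id; longest member: length
  then id), so all outputs are permutation-stable.
* Report files contain no timestamps; wall-clock timings go to `run.log`
  only, and `report.json` stores outdir-relative paths — two runs with the
  same seed and settings are byte-identical.
* Completeness-corrected genome size is assembly size / completeness, with
  completeness required in (0, 1].
* Degenerate inputs fail loudly and early: empty FASTA, duplicate ids, loci
  referencing unknown proteins, non-contiguous gene indices, non-binary
  presence matrices, groups of fewer than two genomes for the t-test, and
  infeasible planting configurations are all hard errors naming the
  offending record.
* Average amino-acid identity (AAI) between two proteomes is the mean
  identity over reciprocal best hits at E ≤ 1e−3, identity ≥ 0.3, query
  coverage ≥ 0.5, reported together with the pair count and undefined
  (absent) when no pair qualifies.

## Known limitations

Sequence search is exact but O(n²); collections beyond ~10⁴ proteins need a
heuristic pre-clustering stage this package intentionally does not
implement. Domain tiers are sequence databases, not profile HMMs, so
remote-domain sensitivity is understated. Comparisons are protein-level
throughout — the nucleotide-vs-protein distinction of translated searches
is out of scope. The context score's family-size denominator is strict near
scaffold edges; studies with very fragmented assemblies may prefer the
occupancy denominator recoverable from the profile tables.
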