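"""Synthetic reference databases and genome communities with planted truth.

The generator emulates the structure of a genome-resolved metagenomic study:
several lineages, each with multiple genomes; scaffolds carrying ordered
genes; a majority of proteins derived (with divergence) from a reference
database of known families; and a minority drawn from *planted novel
families* with controlled per-lineage prevalence and controlled neighbourhood
conservation.  Every planted quantity is recorded in a
:class:`TruthTable`, so downstream recovery can be tested exactly.

Planting is quota-based, not Bernoulli: for planted neighbourhood
conservation ``c`` and family size ``m``, exactly ``round(c·m)`` members are
placed next to a gene carrying the family's designated marker label, so the
realized conservation fraction is known without sampling noise.  Three
further constructions keep recovery sharp:

* novel sequences are rejection-sampled until they share no length-8
  subsequence with any reference sequence, so the novelty cascade's verdict
  is guaranteed rather than calibrated;
* planted members sit on a spaced slot grid (≥ 5 genes apart), so no planted
  member's ±3 window overlaps another family's marker gene;
* background genes inside a planted window are drawn from reference seeds
  never repeated at the same (family, offset), and every seed's labels are
  unique to it, so no background label can reach the planted conservation
  level by coincidence.

A single explicitly seeded RNG stream is threaded through all draws in a
fixed order, making the outputs bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_dataset, write_fasta
from .records import AMINO_ACIDS, Dataset, GeneLocus, GenomeTable, ProteinRecord

__all__ = [
    "SimulationConfig",
    "PlantedFamilySpec",
    "PlantedFamilyTruth",
    "TruthTable",
    "ReferenceDatabase",
    "mutate_sequence",
    "random_protein",
    "generate_reference_db",
    "generate_community",
    "generate_collection",
    "default_planted_families",
]

_ALPHABET = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
NOVEL_KMER = 8  # planted novel proteins share no subsequence of this length
                # with any reference sequence
_SLOT_SPACING = 5  # planted members sit this many genes apart (window isolation)


@dataclass(frozen=True)
class PlantedFamilySpec:
    """Blueprint for one planted novel family.

    ``carriers`` maps lineage id → number of that lineage's genomes carrying
    exactly one member each.  ``conservation`` is the fraction of members
    placed next to the family's marker-labelled neighbour (offset +1 in the
    member's strand frame).
    """

    name: str
    carriers: dict[str, int]
    conservation: float = 0.0
    neighbor_namespace: str = "OG"

    @property
    def size(self) -> int:
        return sum(self.carriers.values())

    @property
    def neighbor_label(self) -> str:
        return f"NBR-{self.name}"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic community.

    Defaults describe the standard test community: 4 lineages × 5 genomes,
    3 scaffolds of 17 genes each, a 30-family reference database, 10%
    divergence between seed and derived sequences, and 10 planted novel
    families (five lineage-exclusive at 80% lineage coverage, three spread
    across all lineages, two singletons).
    """

    seed: int = 0
    n_lineages: int = 4
    genomes_per_lineage: int = 5
    scaffolds_per_genome: int = 3
    genes_per_scaffold: int = 17
    ref_db_families: int = 30
    copies_per_view: int = 2
    mutation_rate: float = 0.10
    indel_rate: float = 0.01
    frac_novel: float = 0.08
    novel_family_count: int = 10
    planted_families: list[PlantedFamilySpec] | None = None
    min_len: int = 120
    max_len: int = 200

    def validate(self) -> list[str]:
        problems = []
        for name in ("n_lineages", "genomes_per_lineage", "scaffolds_per_genome",
                     "genes_per_scaffold", "ref_db_families", "copies_per_view",
                     "min_len", "max_len"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if not (0.0 <= self.mutation_rate < 0.5):
            problems.append(f"mutation_rate must be in [0, 0.5), got {self.mutation_rate}")
        if not (0.0 <= self.indel_rate <= 0.5):
            problems.append(f"indel_rate must be in [0, 0.5], got {self.indel_rate}")
        if not (0.0 <= self.frac_novel <= 1.0):
            problems.append(f"frac_novel must be in [0, 1], got {self.frac_novel}")
        if self.min_len > self.max_len:
            problems.append("min_len must not exceed max_len")
        if self.planted_families is not None:
            for fam in self.planted_families:
                if not (0.0 <= fam.conservation <= 1.0):
                    problems.append(
                        f"family {fam.name}: conservation must be in [0, 1]"
                    )
        return problems

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))

    def lineage_ids(self) -> list[str]:
        return [f"L{i:02d}" for i in range(self.n_lineages)]

    def genome_ids(self, lineage: str) -> list[str]:
        return [f"{lineage}_G{g:02d}" for g in range(self.genomes_per_lineage)]


def default_planted_families(config: SimulationConfig) -> list[PlantedFamilySpec]:
    """The standard planted-family mix for a community.

    Lineage-exclusive families (one more than there are lineages, cycling
    through them) at 80% lineage coverage with conservation levels cycling
    through 1.0, 0.95, 0.9, 0.75, 0.5; then broadly distributed families
    carried by two genomes of every lineage (conservation 0.8, 0.6, 0.0);
    finally two singletons.
    """
    lineages = config.lineage_ids()
    count = config.novel_family_count
    exclusive_cons = [1.0, 0.95, 0.9, 0.75, 0.5]
    broad_cons = [0.8, 0.6, 0.0]
    n_single = min(2, count)
    n_exclusive = min(config.n_lineages + 1, count - n_single)
    n_broad = count - n_single - n_exclusive
    quota = max(1, round(0.8 * config.genomes_per_lineage))
    specs: list[PlantedFamilySpec] = []
    for i in range(n_exclusive):
        specs.append(
            PlantedFamilySpec(
                name=f"NOV{len(specs):02d}",
                carriers={lineages[i % len(lineages)]: quota},
                conservation=exclusive_cons[i % len(exclusive_cons)],
            )
        )
    for j in range(n_broad):
        specs.append(
            PlantedFamilySpec(
                name=f"NOV{len(specs):02d}",
                carriers={lin: min(2, config.genomes_per_lineage) for lin in lineages},
                conservation=broad_cons[j % len(broad_cons)],
            )
        )
    for s in range(n_single):
        specs.append(
            PlantedFamilySpec(
                name=f"NOV{len(specs):02d}",
                carriers={lineages[s % len(lineages)]: 1},
                conservation=0.0,
            )
        )
    return specs


def random_protein(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_ALPHABET, size=length)).decode()


def mutate_sequence(
    sequence: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0
) -> str:
    """Per-site substitution at ``rate`` (to a uniform *different* residue),
    then per-site indels at ``indel_rate`` (insertion or deletion, 50/50)."""
    if not (0.0 <= rate <= 0.5):
        raise ValueError(f"substitution rate must be in [0, 0.5], got {rate}")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    if rate > 0:
        hit = rng.random(arr.size) < rate
        n_hit = int(hit.sum())
        if n_hit:
            # offset trick: pick uniformly among the 19 residues != current
            current = np.searchsorted(_ALPHABET, arr[hit])
            shift = rng.integers(1, len(_ALPHABET), size=n_hit)
            arr[hit] = _ALPHABET[(current + shift) % len(_ALPHABET)]
    out = arr
    if indel_rate > 0:
        pieces: list[int] = []
        events = rng.random(out.size)
        kinds = rng.random(out.size)
        inserts = rng.choice(_ALPHABET, size=out.size)
        for i in range(out.size):
            if events[i] < indel_rate:
                if kinds[i] < 0.5:
                    continue  # deletion
                pieces.append(int(inserts[i]))  # insertion before site
                pieces.append(int(out[i]))
            else:
                pieces.append(int(out[i]))
        if not pieces:
            pieces = [int(out[0])]
        out = np.array(pieces, dtype=np.uint8)
    return out.tobytes().decode()


def _kmer_set(sequence: str, k: int = NOVEL_KMER) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


@dataclass
class ReferenceDatabase:
    """Seed families plus the four diverged database views built from them."""

    seeds: dict[str, str]
    seed_labels: dict[str, dict[str, frozenset[str]]]
    views: dict[str, dict[str, str]]  # OG / domainA / domainB / refseq

    def kmer_index(self, k: int = NOVEL_KMER) -> set[str]:
        index: set[str] = set()
        for seq in self.seeds.values():
            index |= _kmer_set(seq, k)
        for view in self.views.values():
            for seq in view.values():
                index |= _kmer_set(seq, k)
        return index

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for view_name in sorted(self.views):
            path = outdir / f"{view_name}.faa"
            write_fasta(dict(sorted(self.views[view_name].items())), path)
            paths[view_name] = path
        seeds_path = outdir / "seeds.faa"
        write_fasta(dict(sorted(self.seeds.items())), seeds_path)
        paths["seeds"] = seeds_path
        return paths


def generate_reference_db(config: SimulationConfig) -> ReferenceDatabase:
    """Seed sequences of i.i.d. uniform residues plus four diverged views.

    Each view (orthologous groups, two domain databases, reference proteins)
    holds ``copies_per_view`` copies of every seed, diverged at
    ``mutation_rate``.  Every seed carries one unique label in each of the
    five annotation namespaces.
    """
    rng = np.random.default_rng([config.seed, 0])
    seeds: dict[str, str] = {}
    seed_labels: dict[str, dict[str, frozenset[str]]] = {}
    for i in range(config.ref_db_families):
        seed_id = f"REF{i:04d}"
        length = int(rng.integers(config.min_len, config.max_len + 1))
        seeds[seed_id] = random_protein(rng, length)
        seed_labels[seed_id] = {
            "OG": frozenset({f"OG{i:04d}"}),
            "KEGG_KO": frozenset({f"K{i:05d}"}),
            "KEGG_PATHWAY": frozenset({f"map{i:04d}"}),
            "KEGG_MODULE": frozenset({f"M{i:04d}"}),
            "PFAM": frozenset({f"PF{i:04d}"}),
        }
    views: dict[str, dict[str, str]] = {}
    for view_name in ("OG", "domainA", "domainB", "refseq"):
        entries: dict[str, str] = {}
        for seed_id in seeds:
            for c in range(config.copies_per_view):
                entries[f"{view_name}|{seed_id}|{c}"] = mutate_sequence(
                    seeds[seed_id], config.mutation_rate, rng, config.indel_rate
                )
        views[view_name] = entries
    return ReferenceDatabase(seeds=seeds, seed_labels=seed_labels, views=views)


@dataclass
class PlantedFamilyTruth:
    """Everything planted for one novel family."""

    name: str
    seed_sequence: str
    member_ids: list[str]
    carrier_genomes: list[str]
    coverage: dict[str, float]     # intended, per lineage
    specificity: dict[str, float]  # intended, per lineage
    conservation: float            # intended c
    realized_conservation: float   # round(c·m)/m
    n_marked: int
    neighbor_namespace: str
    neighbor_label: str


@dataclass
class TruthTable:
    """Ground-truth ledger for one synthetic community."""

    families: dict[str, PlantedFamilyTruth] = field(default_factory=dict)
    protein_origin: dict[str, str] = field(default_factory=dict)  # pid → origin tag

    @property
    def novel_protein_ids(self) -> set[str]:
        return {
            pid for pid, origin in self.protein_origin.items()
            if origin.startswith("novel:")
        }

    def members_of(self, family_name: str) -> frozenset[str]:
        return frozenset(self.families[family_name].member_ids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "families": {
                name: {
                    "seed_sequence": fam.seed_sequence,
                    "member_ids": fam.member_ids,
                    "carrier_genomes": fam.carrier_genomes,
                    "coverage": fam.coverage,
                    "specificity": fam.specificity,
                    "conservation": fam.conservation,
                    "realized_conservation": fam.realized_conservation,
                    "n_marked": fam.n_marked,
                    "neighbor_namespace": fam.neighbor_namespace,
                    "neighbor_label": fam.neighbor_label,
                }
                for name, fam in sorted(self.families.items())
            },
            "protein_origin": dict(sorted(self.protein_origin.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        families = {
            name: PlantedFamilyTruth(
                name=name,
                seed_sequence=d["seed_sequence"],
                member_ids=list(d["member_ids"]),
                carrier_genomes=list(d["carrier_genomes"]),
                coverage=dict(d["coverage"]),
                specificity=dict(d["specificity"]),
                conservation=d["conservation"],
                realized_conservation=d["realized_conservation"],
                n_marked=d["n_marked"],
                neighbor_namespace=d["neighbor_namespace"],
                neighbor_label=d["neighbor_label"],
            )
            for name, d in payload["families"].items()
        }
        return cls(families=families, protein_origin=dict(payload["protein_origin"]))


def _novel_seed(rng: np.random.Generator, length: int, ref_index: set[str]) -> str:
    """Rejection-sample a sequence sharing no 8-mer with the reference db."""
    while True:
        candidate = random_protein(rng, length)
        if ref_index.isdisjoint(_kmer_set(candidate)):
            return candidate


def _novel_member(rng: np.random.Generator, seed: str, config: SimulationConfig,
                  ref_index: set[str]) -> str:
    while True:
        member = mutate_sequence(seed, config.mutation_rate, rng, config.indel_rate)
        if ref_index.isdisjoint(_kmer_set(member)):
            return member


def generate_community(
    config: SimulationConfig, reference_db: ReferenceDatabase
) -> tuple[Dataset, TruthTable]:
    """Build the genome collection with planted known and novel families."""
    rng = np.random.default_rng([config.seed, 1])
    specs = config.planted_families
    if config.frac_novel == 0:
        specs = []
    elif specs is None:
        specs = default_planted_families(config)

    lineages = config.lineage_ids()
    genomes = {lin: config.genome_ids(lin) for lin in lineages}
    k = 3  # context half-window the placement isolates

    for spec in specs:
        for lineage in spec.carriers:
            if lineage not in genomes:
                raise ValueError(f"family {spec.name}: unknown lineage {lineage!r}")
            if spec.carriers[lineage] > config.genomes_per_lineage:
                raise ValueError(
                    f"family {spec.name}: {spec.carriers[lineage]} carriers exceed "
                    f"{config.genomes_per_lineage} genomes in lineage {lineage}"
                )

    # spaced planting slots: windows of planted members never overlap another
    # planted member or its marker neighbour
    slot_indices = list(range(k, config.genes_per_scaffold - k, _SLOT_SPACING))
    if not slot_indices or slot_indices[-1] > config.genes_per_scaffold - 1 - k:
        slot_indices = [i for i in slot_indices if i <= config.genes_per_scaffold - 1 - k]
    free_slots: dict[str, list[tuple[str, int]]] = {}
    for lineage in lineages:
        for genome_id in genomes[lineage]:
            slots = [
                (f"{genome_id}_S{s:02d}", idx)
                for s in range(config.scaffolds_per_genome)
                for idx in slot_indices
            ]
            free_slots[genome_id] = slots

    ref_index = reference_db.kmer_index()

    # --- choose carriers, positions and marker quotas per planted family ---
    placements: dict[tuple[str, str, int], tuple[str, str, bool]] = {}
    #            (genome, scaffold, idx) → (family, strand, marked)
    marker_positions: dict[tuple[str, str, int], list[tuple[str, str]]] = {}
    #            background position → [(namespace, label)] to add
    family_carriers: dict[str, list[str]] = {}
    family_seeds: dict[str, str] = {}
    for spec in specs:
        carriers: list[str] = []
        for lineage in sorted(spec.carriers):
            order = rng.permutation(len(genomes[lineage]))
            carriers.extend(genomes[lineage][i] for i in order[: spec.carriers[lineage]])
        carriers.sort()
        family_carriers[spec.name] = carriers
        length = int(rng.integers(config.min_len, config.max_len + 1))
        family_seeds[spec.name] = _novel_seed(rng, length, ref_index)
        n_marked = round(spec.conservation * len(carriers))
        for rank, genome_id in enumerate(carriers):
            if not free_slots[genome_id]:
                raise ValueError(
                    f"infeasible placement: genome {genome_id} has no free slot "
                    f"for family {spec.name} (more planted members than gene slots)"
                )
            pick = int(rng.integers(len(free_slots[genome_id])))
            scaffold_id, idx = free_slots[genome_id].pop(pick)
            strand = "+" if rng.random() < 0.5 else "-"
            marked = rank < n_marked
            placements[(genome_id, scaffold_id, idx)] = (spec.name, strand, marked)
            if marked:
                nbr = idx + 1 if strand == "+" else idx - 1
                marker_positions.setdefault((genome_id, scaffold_id, nbr), []).append(
                    (spec.neighbor_namespace, spec.neighbor_label)
                )

    # background-seed constraints: inside a planted window, never reuse a seed
    # at the same (family, offset)
    window_constraints: dict[tuple[str, str, int], list[tuple[str, int]]] = {}
    for (genome_id, scaffold_id, idx), (family, strand, _marked) in placements.items():
        sign = 1 if strand == "+" else -1
        for offset in range(-k, k + 1):
            if offset == 0:
                continue
            nidx = idx + sign * offset
            if 0 <= nidx < config.genes_per_scaffold:
                window_constraints.setdefault(
                    (genome_id, scaffold_id, nidx), []
                ).append((family, offset))
    used_seeds: dict[tuple[str, int], set[str]] = {}

    seed_ids = sorted(reference_db.seeds)

    # --- emit genomes gene by gene, one RNG stream, fixed order ---
    truth = TruthTable()
    family_members: dict[str, list[str]] = {spec.name: [] for spec in specs}
    genome_tables: dict[str, GenomeTable] = {}
    proteins: dict[str, ProteinRecord] = {}
    for lineage in lineages:
        for genome_id in genomes[lineage]:
            scaffolds: dict[str, list[GeneLocus]] = {}
            for s in range(config.scaffolds_per_genome):
                scaffold_id = f"{genome_id}_S{s:02d}"
                loci: list[GeneLocus] = []
                for idx in range(config.genes_per_scaffold):
                    pid = f"{scaffold_id}_g{idx:02d}"
                    key = (genome_id, scaffold_id, idx)
                    if key in placements:
                        family, strand, _marked = placements[key]
                        sequence = _novel_member(
                            rng, family_seeds[family], config, ref_index
                        )
                        annotations: dict[str, frozenset[str]] = {}
                        family_members[family].append(pid)
                        truth.protein_origin[pid] = f"novel:{family}"
                    else:
                        constraints = window_constraints.get(key, ())
                        banned: set[str] = set()
                        for constraint in constraints:
                            banned |= used_seeds.get(constraint, set())
                        candidates = [sid for sid in seed_ids if sid not in banned]
                        if not candidates:
                            candidates = seed_ids
                        seed_id = candidates[int(rng.integers(len(candidates)))]
                        for constraint in constraints:
                            used_seeds.setdefault(constraint, set()).add(seed_id)
                        sequence = mutate_sequence(
                            reference_db.seeds[seed_id], config.mutation_rate,
                            rng, config.indel_rate,
                        )
                        annotations = {
                            ns: labels
                            for ns, labels in reference_db.seed_labels[seed_id].items()
                        }
                        extra = marker_positions.get(key, ())
                        if extra:
                            annotations = {ns: set(v) for ns, v in annotations.items()}
                            for namespace, label in extra:
                                annotations.setdefault(namespace, set()).add(label)
                            annotations = {
                                ns: frozenset(v) for ns, v in annotations.items()
                            }
                        strand = "+" if rng.random() < 0.5 else "-"
                        truth.protein_origin[pid] = f"known:{seed_id}"
                    loci.append(
                        GeneLocus(
                            protein_id=pid, scaffold_id=scaffold_id,
                            gene_index=idx, strand=strand,
                            annotations=annotations,
                        )
                    )
                    proteins[pid] = ProteinRecord(
                        protein_id=pid, genome_id=genome_id,
                        scaffold_id=scaffold_id, gene_index=idx,
                        strand=strand, sequence=sequence,
                    )
                scaffolds[scaffold_id] = loci
            genome_tables[genome_id] = GenomeTable(
                genome_id=genome_id,
                lineage_id=lineage,
                assembly_size=int(rng.integers(2_000_000, 5_000_001)),
                completeness=float(np.round(rng.uniform(0.6, 1.0), 3)),
                scaffolds=scaffolds,
            )

    for spec in specs:
        carriers = family_carriers[spec.name]
        n_marked = round(spec.conservation * len(carriers))
        per_lineage_carriers = {
            lin: sum(1 for g in carriers if g.startswith(lin)) for lin in spec.carriers
        }
        truth.families[spec.name] = PlantedFamilyTruth(
            name=spec.name,
            seed_sequence=family_seeds[spec.name],
            member_ids=sorted(family_members[spec.name]),
            carrier_genomes=carriers,
            coverage={
                lin: n / config.genomes_per_lineage
                for lin, n in per_lineage_carriers.items()
            },
            specificity={
                lin: n / len(carriers) for lin, n in per_lineage_carriers.items()
            },
            conservation=spec.conservation,
            realized_conservation=n_marked / len(carriers),
            n_marked=n_marked,
            neighbor_namespace=spec.neighbor_namespace,
            neighbor_label=spec.neighbor_label,
        )

    dataset = Dataset(genomes=genome_tables, proteins=proteins)
    return dataset, truth


def generate_collection(
    truth: TruthTable,
    reference_db: ReferenceDatabase,
    carriers: dict[str, list[tuple[str, str]]],
    rate: float = 0.15,
    seed: int = 0,
    background_per_genome: int = 3,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """An external genome collection for extension tests.

    ``carriers`` maps a planted family name to (genome_id, lineage_id) pairs;
    each listed genome receives one diverged copy (at ``rate``) of the
    family's novel seed, plus ``background_per_genome`` diverged reference
    seeds.  Returns (sequences, protein → genome, protein → lineage).
    """
    rng = np.random.default_rng([seed, 2])
    ref_index = reference_db.kmer_index()
    sequences: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    genome_lineage: dict[str, str] = {}
    for family in sorted(carriers):
        seed_seq = truth.families[family].seed_sequence
        for genome_id, lineage_id in carriers[family]:
            genome_lineage[genome_id] = lineage_id
            pid = f"{genome_id}|{family}"
            while True:
                member = mutate_sequence(seed_seq, rate, rng)
                if ref_index.isdisjoint(_kmer_set(member)):
                    break
            sequences[pid] = member
            genome_of[pid] = genome_id
            lineage_of[pid] = lineage_id
    seed_ids = sorted(reference_db.seeds)
    for genome_id in sorted(genome_lineage):
        for b in range(background_per_genome):
            seed_id = seed_ids[int(rng.integers(len(seed_ids)))]
            pid = f"{genome_id}|bg{b:02d}"
            sequences[pid] = mutate_sequence(reference_db.seeds[seed_id], rate, rng)
            genome_of[pid] = genome_id
            lineage_of[pid] = genome_lineage[genome_id]
    return sequences, genome_of, lineage_of


def write_simulation(
    config: SimulationConfig, outdir: str | Path
) -> tuple[Dataset, TruthTable, ReferenceDatabase, dict[str, Path]]:
    """Generate and write a full simulation: dataset files, reference views
    and the truth ledger."""
    outdir = Path(outdir)
    reference_db = generate_reference_db(config)
    dataset, truth = generate_community(config, reference_db)
    paths = write_dataset(dataset, outdir / "community")
    paths.update(reference_db.write(outdir / "reference"))
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return dataset, truth, reference_db, paths
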