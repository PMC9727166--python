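"""Core domain types shared by every pipeline stage.

A *dataset* is a collection of genomes, each assigned to a lineage and carrying
scaffolds with ordered genes.  Every gene encodes one protein and may carry
functional annotations in one or more namespaces (orthologous groups, KEGG
orthologs/pathways/modules, Pfam domains).  Gene order is ordinal: the context
analysis works on gene positions along a scaffold, never on base-pair
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

__all__ = [
    "AMINO_ACIDS",
    "NAMESPACES",
    "STRANDS",
    "DatasetError",
    "ProteinRecord",
    "GeneLocus",
    "GenomeTable",
    "Dataset",
    "Thresholds",
    "estimate_complete_size",
]

#: The 20 standard amino acids.  ``X`` (unknown residue) is additionally
#: accepted in sequences; other IUPAC ambiguity codes are rejected at load.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Annotation namespaces recognised by the context analysis.
NAMESPACES = ("OG", "KEGG_KO", "KEGG_PATHWAY", "KEGG_MODULE", "PFAM")

STRANDS = ("+", "-")


class DatasetError(ValueError):
    """Raised when input data violates a structural invariant."""


def _check_sequence(protein_id: str, sequence: str) -> None:
    if not sequence:
        raise DatasetError(f"protein {protein_id!r}: empty sequence")
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise DatasetError(
            f"protein {protein_id!r}: invalid residue(s) {sorted(bad)}; "
            f"only the 20 standard amino acids and X are accepted"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein tied to its genome, scaffold and ordinal gene position."""

    protein_id: str
    genome_id: str
    scaffold_id: str
    gene_index: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        _check_sequence(self.protein_id, self.sequence)
        if self.strand not in STRANDS:
            raise DatasetError(
                f"protein {self.protein_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.gene_index < 0:
            raise DatasetError(f"protein {self.protein_id!r}: negative gene_index")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """Positional and functional context of one gene on a scaffold.

    ``annotations`` maps a namespace (see :data:`NAMESPACES`) to a frozenset of
    opaque labels; empty sets are permitted and simply contribute nothing to
    conservation profiles.
    """

    protein_id: str
    scaffold_id: str
    gene_index: int
    strand: str
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for namespace in self.annotations:
            if namespace not in NAMESPACES:
                raise DatasetError(
                    f"locus {self.protein_id!r}: unknown annotation namespace {namespace!r}"
                )


@dataclass
class GenomeTable:
    """One genome: lineage assignment, size estimates and ordered loci.

    ``scaffolds`` maps scaffold_id to the list of loci sorted by gene_index;
    indices on each scaffold form a contiguous ``0..n-1`` range.
    """

    genome_id: str
    lineage_id: str
    assembly_size: int
    completeness: float
    scaffolds: dict[str, list[GeneLocus]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 1.0):
            raise DatasetError(
                f"genome {self.genome_id!r}: completeness must be in (0, 1], "
                f"got {self.completeness}"
            )
        for scaffold_id, loci in self.scaffolds.items():
            indices = [locus.gene_index for locus in loci]
            if indices != list(range(len(loci))):
                raise DatasetError(
                    f"genome {self.genome_id!r} scaffold {scaffold_id!r}: "
                    f"gene_index values must form a contiguous 0..n-1 range"
                )

    @property
    def loci(self) -> list[GeneLocus]:
        out: list[GeneLocus] = []
        for scaffold_id in sorted(self.scaffolds):
            out.extend(self.scaffolds[scaffold_id])
        return out

    @property
    def estimated_complete_size(self) -> float:
        return estimate_complete_size(self.assembly_size, self.completeness)


def estimate_complete_size(assembly_size: float, completeness: float) -> float:
    """Completeness-corrected genome size: ``assembly_size / completeness``.

    Draft genomes recovered from metagenomes are incomplete; dividing the
    assembled size by the estimated completeness fraction gives an estimate of
    the full genome size.
    """
    if not (0.0 < completeness <= 1.0):
        raise ValueError(f"completeness must be in (0, 1], got {completeness}")
    return assembly_size / completeness


@dataclass
class Dataset:
    """A genome collection: genomes with loci plus the protein sequences."""

    genomes: dict[str, GenomeTable]
    proteins: dict[str, ProteinRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_locus: set[tuple[str, str, int]] = set()
        locus_proteins: set[str] = set()
        for genome in self.genomes.values():
            for locus in genome.loci:
                key = (genome.genome_id, locus.scaffold_id, locus.gene_index)
                if key in seen_locus:
                    raise DatasetError(f"duplicate locus {key}")
                seen_locus.add(key)
                if locus.protein_id not in self.proteins:
                    raise DatasetError(
                        f"locus references unknown protein {locus.protein_id!r}"
                    )
                if locus.protein_id in locus_proteins:
                    raise DatasetError(
                        f"protein {locus.protein_id!r} appears at more than one locus"
                    )
                locus_proteins.add(locus.protein_id)
        for protein_id in self.proteins:
            if protein_id not in locus_proteins:
                raise DatasetError(f"protein {protein_id!r} has no locus")

    @property
    def lineage_map(self) -> dict[str, str]:
        """genome_id → lineage_id."""
        return {g.genome_id: g.lineage_id for g in self.genomes.values()}

    @property
    def protein_genome(self) -> dict[str, str]:
        """protein_id → genome_id."""
        return {p.protein_id: p.genome_id for p in self.proteins.values()}

    def sequences(self) -> dict[str, str]:
        return {pid: rec.sequence for pid, rec in self.proteins.items()}

    def locus_of(self, protein_id: str) -> tuple[GenomeTable, GeneLocus]:
        rec = self.proteins.get(protein_id)
        if rec is None:
            raise KeyError(f"unknown protein {protein_id!r}")
        genome = self.genomes[rec.genome_id]
        for locus in genome.scaffolds[rec.scaffold_id]:
            if locus.protein_id == protein_id:
                return genome, locus
        raise KeyError(f"protein {protein_id!r} has no locus in {rec.genome_id!r}")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class Thresholds:
    """All cutoffs used along the pipeline, with their working defaults.

    Clustering uses relaxed homology thresholds (30% identity, E < 1e-3, 50%
    query coverage).  The novelty cascade applies E < 1e-3 to the orthologous
    group tier, E < 1e-5 to both domain tiers, and E < 1e-3 plus >50% query
    coverage to the reference-protein tier.  Family extension reuses the
    1e-3 / 50% rule.  A family is called conserved when some neighbouring
    functional label within the ±3 gene window reaches a 0.9 conservation
    fraction, and is a lineage marker when both specificity and coverage
    strictly exceed 0.7.
    """

    cluster_min_identity: float = 0.30
    cluster_min_query_cov: float = 0.50
    cluster_max_evalue: float = 1e-3
    novelty_evalue_og: float = 1e-3
    novelty_evalue_domainA: float = 1e-5
    novelty_evalue_domainB: float = 1e-5
    novelty_evalue_refseq: float = 1e-3
    novelty_refseq_min_qcov: float = 0.50
    extension_max_evalue: float = 1e-3
    extension_min_qcov: float = 0.50
    context_window: int = 3
    conserved_score_cutoff: float = 0.90
    marker_specificity_cutoff: float = 0.70
    marker_coverage_cutoff: float = 0.70
    overlap_member_fraction: float = 0.90
    jaccard_cut: float = 0.40

    _FRACTIONS = (
        "cluster_min_identity",
        "cluster_min_query_cov",
        "novelty_refseq_min_qcov",
        "extension_min_qcov",
        "conserved_score_cutoff",
        "marker_specificity_cutoff",
        "marker_coverage_cutoff",
        "overlap_member_fraction",
        "jaccard_cut",
    )
    _EVALUES = (
        "cluster_max_evalue",
        "novelty_evalue_og",
        "novelty_evalue_domainA",
        "novelty_evalue_domainB",
        "novelty_evalue_refseq",
        "extension_max_evalue",
    )

    def validate(self) -> list[str]:
        """Return a list of human-readable violations (empty when valid)."""
        problems = []
        for name in self._FRACTIONS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                problems.append(f"{name} must be a fraction in [0, 1], got {value}")
        for name in self._EVALUES:
            value = getattr(self, name)
            if not value > 0:
                problems.append(f"{name} must be a positive E-value, got {value}")
        if self.context_window < 1:
            problems.append(f"context_window must be >= 1, got {self.context_window}")
        return problems

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if not f.name.startswith("_")]
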