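"""Readers and writers for the plain-text formats the pipeline touches.

Protein sequences travel as FASTA (the header token up to the first whitespace
is the protein id).  Gene coordinates come either from GFF3 (CDS features, the
``ID`` attribute naming the protein) or from a minimal TSV dialect with columns
``protein_id, genome_id, scaffold_id, start, end, strand``.  Annotations and
lineage assignments are tab-separated tables with a header row.  Start/end
coordinates are used once, to sort genes along each scaffold into ordinal
positions; downstream stages consume ordinals only.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    Dataset,
    DatasetError,
    GeneLocus,
    GenomeTable,
    NAMESPACES,
    ProteinRecord,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_dataset",
    "write_dataset",
    "write_family_report",
    "read_family_report",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered id → sequence mapping."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise DatasetError(f"duplicate protein_id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise DatasetError(f"empty FASTA: {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_gff3_gene_table(path: str | Path) -> pd.DataFrame:
    """Extract CDS rows from a GFF3 file into the minimal gene-table frame.

    The genome id is taken from a ``genome_id=`` attribute when present, else
    from the ``##genome-id`` pragma preceding the features, else defaults to
    the file stem.
    """
    rows = []
    current_genome = Path(path).stem
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("##genome-id"):
                current_genome = line.split(None, 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DatasetError(f"malformed GFF3 line in {path}: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attributes = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if "ID" not in attributes:
                raise DatasetError(f"GFF3 CDS without ID attribute in {path}")
            rows.append(
                {
                    "protein_id": attributes["ID"],
                    "genome_id": attributes.get("genome_id", current_genome),
                    "scaffold_id": seqid,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows)


_GENE_TABLE_COLUMNS = ["protein_id", "genome_id", "scaffold_id", "start", "end", "strand"]


def load_dataset(
    proteins_path: str | Path,
    gene_table_path: str | Path,
    annotations_path: str | Path,
    lineage_path: str | Path,
) -> Dataset:
    """Assemble a validated :class:`Dataset` from its four on-disk tables.

    Gene tables may be the minimal TSV dialect or GFF3 (detected from the
    ``.gff``/``.gff3`` extension).  Genes are sorted by start coordinate within
    each scaffold and assigned contiguous 0-based ordinal positions.
    """
    sequences = read_fasta(proteins_path)

    gene_path = Path(gene_table_path)
    if gene_path.suffix.lower() in {".gff", ".gff3"}:
        table = _parse_gff3_gene_table(gene_path)
    else:
        table = pd.read_csv(gene_path, sep="\t", dtype=str)
        missing = set(_GENE_TABLE_COLUMNS) - set(table.columns)
        if missing:
            raise DatasetError(f"gene table missing column(s) {sorted(missing)}")
        table = table[_GENE_TABLE_COLUMNS].copy()
        table["start"] = table["start"].astype(int)
        table["end"] = table["end"].astype(int)
    if table.empty:
        raise DatasetError(f"gene table {gene_table_path} has no CDS rows")

    for protein_id in table["protein_id"]:
        if protein_id not in sequences:
            raise DatasetError(
                f"gene table references protein {protein_id!r} absent from FASTA"
            )

    annotations = pd.read_csv(annotations_path, sep="\t", dtype=str)
    for col in ("protein_id", "namespace", "label"):
        if col not in annotations.columns:
            raise DatasetError(f"annotation table missing column {col!r}")
    per_protein: dict[str, dict[str, set[str]]] = {}
    for row in annotations.itertuples(index=False):
        if row.namespace not in NAMESPACES:
            raise DatasetError(f"unknown annotation namespace {row.namespace!r}")
        per_protein.setdefault(row.protein_id, {}).setdefault(row.namespace, set()).add(
            row.label
        )

    lineages = pd.read_csv(lineage_path, sep="\t", dtype=str)
    for col in ("genome_id", "lineage_id"):
        if col not in lineages.columns:
            raise DatasetError(f"lineage table missing column {col!r}")
    genome_meta: dict[str, tuple[str, int, float]] = {}

    def _opt(row, name, default):
        value = getattr(row, name, None)
        if value is None or isinstance(value, float) or value == "":
            return default  # column absent or cell empty
        return value

    for row in lineages.itertuples(index=False):
        size = int(_opt(row, "assembly_size", 0))
        completeness = float(_opt(row, "completeness", 1.0))
        genome_meta[row.genome_id] = (row.lineage_id, size, completeness)

    genomes: dict[str, GenomeTable] = {}
    for genome_id, genome_rows in table.groupby("genome_id", sort=True):
        if genome_id not in genome_meta:
            raise DatasetError(f"genome {genome_id!r} missing from lineage table")
        lineage_id, size, completeness = genome_meta[genome_id]
        scaffolds: dict[str, list[GeneLocus]] = {}
        for scaffold_id, scaffold_rows in genome_rows.groupby("scaffold_id", sort=True):
            ordered = scaffold_rows.sort_values(["start", "end", "protein_id"])
            loci = []
            for gene_index, row in enumerate(ordered.itertuples(index=False)):
                raw = per_protein.get(row.protein_id, {})
                loci.append(
                    GeneLocus(
                        protein_id=row.protein_id,
                        scaffold_id=scaffold_id,
                        gene_index=gene_index,
                        strand=row.strand,
                        annotations={ns: frozenset(v) for ns, v in sorted(raw.items())},
                    )
                )
            scaffolds[scaffold_id] = loci
        genomes[genome_id] = GenomeTable(
            genome_id=genome_id,
            lineage_id=lineage_id,
            assembly_size=size,
            completeness=completeness,
            scaffolds=scaffolds,
        )

    proteins: dict[str, ProteinRecord] = {}
    for genome in genomes.values():
        for locus in genome.loci:
            proteins[locus.protein_id] = ProteinRecord(
                protein_id=locus.protein_id,
                genome_id=genome.genome_id,
                scaffold_id=locus.scaffold_id,
                gene_index=locus.gene_index,
                strand=locus.strand,
                sequence=sequences[locus.protein_id],
            )
    extra = set(sequences) - set(proteins)
    if extra:
        raise DatasetError(
            f"FASTA contains protein(s) with no gene-table row: {sorted(extra)[:5]}"
        )
    return Dataset(genomes=genomes, proteins=proteins)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset as the four tables :func:`load_dataset` consumes.

    Gene start coordinates are synthesised from the ordinal positions
    (1000 bp per gene slot) purely so that sorting by coordinate reproduces
    the ordinal order; they carry no other meaning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.faa",
        "gene_table": outdir / "gene_table.tsv",
        "annotations": outdir / "annotations.tsv",
        "lineages": outdir / "lineages.tsv",
    }
    write_fasta(
        {pid: dataset.proteins[pid].sequence for pid in sorted(dataset.proteins)},
        paths["proteins"],
    )
    with open(paths["gene_table"], "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_GENE_TABLE_COLUMNS)
        for genome_id in sorted(dataset.genomes):
            genome = dataset.genomes[genome_id]
            for scaffold_id in sorted(genome.scaffolds):
                for locus in genome.scaffolds[scaffold_id]:
                    start = 1 + 1000 * locus.gene_index
                    end = start + 3 * len(dataset.proteins[locus.protein_id].sequence)
                    writer.writerow(
                        [locus.protein_id, genome_id, scaffold_id, start, end, locus.strand]
                    )
    with open(paths["annotations"], "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "namespace", "label"])
        for genome_id in sorted(dataset.genomes):
            for locus in dataset.genomes[genome_id].loci:
                for namespace in sorted(locus.annotations):
                    for label in sorted(locus.annotations[namespace]):
                        writer.writerow([locus.protein_id, namespace, label])
    with open(paths["lineages"], "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "lineage_id", "assembly_size", "completeness"])
        for genome_id in sorted(dataset.genomes):
            genome = dataset.genomes[genome_id]
            writer.writerow(
                [genome_id, genome.lineage_id, genome.assembly_size, genome.completeness]
            )
    return paths


_REPORT_COLUMNS = [
    "family_id",
    "size",
    "members_per_genome",
    "novelty_class",
    "conservation_score",
    "lineage_metrics",
]


def write_family_report(partition, verdicts, metrics, path, *,
                        scores=None, protein_genome=None) -> None:
    """Write the per-family summary table.

    One row per family, ascending family id: id, size, per-genome member
    counts (``genome:count`` pairs, comma-joined), novelty class, conservation
    score (empty when not computed) and per-lineage coverage/specificity
    (``lineage:coverage:specificity`` triples, semicolon-joined).
    """
    scores = scores or {}
    protein_genome = protein_genome or {}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_REPORT_COLUMNS)
        for family in sorted(partition.families, key=lambda f: f.family_id):
            per_genome: dict[str, int] = {}
            for member in family.member_ids:
                genome = protein_genome.get(member, "?")
                per_genome[genome] = per_genome.get(genome, 0) + 1
            genome_field = ",".join(
                f"{g}:{per_genome[g]}" for g in sorted(per_genome)
            )
            verdict = verdicts.get(family.family_id)
            klass = verdict.klass if verdict is not None else ""
            score = scores.get(family.family_id)
            score_field = "" if score is None else f"{score:.6g}"
            fam_metrics = metrics.get(family.family_id)
            if fam_metrics is None:
                metric_field = ""
            else:
                metric_field = ";".join(
                    f"{lin}:{cov:.6g}:{spec:.6g}"
                    for lin, (cov, spec) in sorted(fam_metrics.per_lineage.items())
                )
            writer.writerow(
                [
                    family.family_id,
                    len(family.member_ids),
                    genome_field,
                    klass,
                    score_field,
                    metric_field,
                ]
            )


def read_family_report(path: str | Path) -> pd.DataFrame:
    """Reload a family report as a DataFrame (values stay strings)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
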