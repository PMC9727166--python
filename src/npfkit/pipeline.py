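"""End-to-end orchestration: simulate → load → cluster → classify → extend →
context → dispersion → report.

A run is fully described by a :class:`PipelineConfig` (parsed from a YAML
file); identical config and seed reproduce byte-identical report files.  Wall
-clock stage timings go to the run log only, never into report files, so the
reports stay byte-comparable across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import context as context_mod
from . import dispersion as dispersion_mod
from .clustering import cluster_proteins, write_partition_tsv
from .homology import SequenceDatabase
from .io import load_dataset, write_family_report
from .novelty import (
    DatabaseSuite,
    classify_partition,
    extend_families,
    write_extension_tsv,
    write_verdicts_tsv,
)
from .records import Dataset, Thresholds
from .simulate import SimulationConfig, PlantedFamilySpec, write_simulation

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig | None = None
    # file-input mode (ignored when a simulation is configured)
    proteins: Path | None = None
    gene_table: Path | None = None
    annotations: Path | None = None
    lineages: Path | None = None
    reference_db: dict[str, Path] | None = None  # tier → FASTA
    # optional external collection for family extension
    collection_proteins: Path | None = None
    collection_metadata: Path | None = None  # TSV: protein_id, genome_id, lineage_id
    # optional comparison group for the novelty-rate t-test
    reference_percentages: list[float] | None = None

    def to_dict(self) -> dict:
        def convert(value):
            if isinstance(value, Path):
                return str(value)
            if dataclasses.is_dataclass(value) and not isinstance(value, type):
                return {
                    k: convert(v) for k, v in dataclasses.asdict(value).items()
                }
            if isinstance(value, dict):
                return {k: convert(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [convert(v) for v in value]
            return value

        return {
            f.name: convert(getattr(self, f.name))
            for f in dataclasses.fields(self)
        }


def _build_simulation(section: dict, seed: int, errors: list[str]) -> SimulationConfig | None:
    planted = section.pop("planted_families", None)
    specs = None
    if planted is not None:
        specs = []
        for entry in planted:
            try:
                specs.append(
                    PlantedFamilySpec(
                        name=entry["name"],
                        carriers=dict(entry["carriers"]),
                        conservation=float(entry.get("conservation", 0.0)),
                        neighbor_namespace=entry.get("neighbor_namespace", "OG"),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"simulation.planted_families: invalid entry ({exc})")
                return None
    section.setdefault("seed", seed)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(section) - known
    if unknown:
        errors.append(f"simulation: unknown field(s) {sorted(unknown)}")
        return None
    try:
        return SimulationConfig(planted_families=specs,
                                **{k: v for k, v in section.items()
                                   if k != "planted_families"})
    except ValueError as exc:
        errors.append(f"simulation: {exc}")
        return None


def validate_config(path: str | Path) -> PipelineConfig | list[str]:
    """Parse and validate a YAML pipeline config.

    Returns the resolved :class:`PipelineConfig`, or the full list of
    violations when anything is wrong.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ValueError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    errors: list[str] = []
    seed = int(raw.get("seed", 0))
    outdir = Path(raw.get("outdir", "npfkit_out"))

    thresholds = Thresholds()
    if "thresholds" in raw:
        known = set(Thresholds.field_names())
        unknown = set(raw["thresholds"]) - known
        if unknown:
            errors.append(f"thresholds: unknown field(s) {sorted(unknown)}")
        else:
            try:
                thresholds = Thresholds(**raw["thresholds"])
            except ValueError as exc:
                errors.append(f"thresholds: {exc}")

    simulation = None
    if "simulation" in raw:
        simulation = _build_simulation(dict(raw["simulation"]), seed, errors)

    config = PipelineConfig(outdir=outdir, seed=seed, thresholds=thresholds,
                            simulation=simulation)

    inputs = raw.get("inputs", {})
    if simulation is None:
        for key in ("proteins", "gene_table", "annotations", "lineages"):
            if key not in inputs:
                errors.append(f"inputs.{key} is required when no simulation is configured")
            else:
                p = Path(inputs[key])
                if not p.exists():
                    errors.append(f"inputs.{key}: path does not exist: {p}")
                setattr(config, key, p)
        refdb = raw.get("reference_db", {})
        for tier in ("OG", "domainA", "domainB", "refseq"):
            if tier not in refdb:
                errors.append(f"reference_db.{tier} is required when no simulation is configured")
        if refdb and not errors:
            config.reference_db = {}
            for tier, p in refdb.items():
                p = Path(p)
                if not p.exists():
                    errors.append(f"reference_db.{tier}: path does not exist: {p}")
                config.reference_db[tier] = p

    collection = raw.get("collection", {})
    if collection:
        for key, attr in (("proteins", "collection_proteins"),
                          ("metadata", "collection_metadata")):
            if key not in collection:
                errors.append(f"collection.{key} is required when a collection is given")
            else:
                p = Path(collection[key])
                if not p.exists():
                    errors.append(f"collection.{key}: path does not exist: {p}")
                setattr(config, attr, p)

    if "reference_percentages" in raw:
        values = raw["reference_percentages"]
        if not isinstance(values, list) or len(values) < 2:
            errors.append("reference_percentages must be a list of >= 2 numbers")
        else:
            config.reference_percentages = [float(v) for v in values]

    if errors:
        return errors
    return config


@dataclass
class RunReport:
    """Per-stage counts and output paths for one pipeline run."""

    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"counts": self.counts, "outputs": self.outputs},
                       indent=1, sort_keys=True)
        )


class _StageTimer:
    def __init__(self, log_path: Path):
        self.log_path = log_path
        self.lines: list[str] = []

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                elapsed = time.perf_counter() - self_inner.t0
                status = "FAILED" if exc_type else "ok"
                timer.lines.append(f"{name}\t{status}\t{elapsed:.2f}s")
                logger.info("stage %s: %s (%.2fs)", name, status, elapsed)
                if exc_type:
                    timer.flush()
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    def flush(self) -> None:
        self.log_path.write_text("\n".join(self.lines) + "\n")


def _load_collection(config: PipelineConfig):
    if config.collection_proteins is None:
        return None, {}, {}
    from .io import read_fasta
    import csv as _csv

    sequences = read_fasta(config.collection_proteins)
    genome_of: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    with open(config.collection_metadata) as handle:
        reader = _csv.DictReader(handle, delimiter="\t")
        for row in reader:
            genome_of[row["protein_id"]] = row["genome_id"]
            lineage_of[row["protein_id"]] = row["lineage_id"]
    return sequences, genome_of, lineage_of


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage, writing deterministic outputs under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timer = _StageTimer(outdir / "run.log")
    report = RunReport()
    thresholds = config.thresholds

    (outdir / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True, default=str)
    )

    with timer.stage("load"):
        if config.simulation is not None:
            _dataset, truth, reference_db, paths = write_simulation(
                config.simulation, outdir / "simulated"
            )
            # reload through the files so the run exercises the readers too
            dataset = load_dataset(
                paths["proteins"], paths["gene_table"],
                paths["annotations"], paths["lineages"],
            )
            suite = DatabaseSuite(
                tiers={
                    tier: SequenceDatabase(reference_db.views[tier], name=tier)
                    for tier in ("OG", "domainA", "domainB", "refseq")
                }
            )
            report.outputs["truth"] = str(paths["truth"])
        else:
            dataset = load_dataset(
                config.proteins, config.gene_table,
                config.annotations, config.lineages,
            )
            suite = DatabaseSuite(
                tiers={
                    tier: SequenceDatabase.from_fasta(path, name=tier)
                    for tier, path in config.reference_db.items()
                }
            )
        report.counts["n_genomes"] = len(dataset.genomes)
        report.counts["n_proteins"] = len(dataset.proteins)

    sequences = dataset.sequences()

    with timer.stage("cluster"):
        partition = cluster_proteins(sequences, thresholds)
        partition_path = outdir / "partition.tsv"
        write_partition_tsv(partition, partition_path)
        report.counts["n_families"] = len(partition)
        report.outputs["partition"] = str(partition_path)

    with timer.stage("classify"):
        verdicts = classify_partition(partition, sequences, suite, thresholds)
        verdicts_path = outdir / "verdicts.tsv"
        write_verdicts_tsv(verdicts, verdicts_path)
        tally = {"KNOWN": 0, "NPF": 0, "NS": 0}
        for verdict in verdicts.values():
            tally[verdict.klass] += 1
        report.counts["n_known"] = tally["KNOWN"]
        report.counts["n_npf"] = tally["NPF"]
        report.counts["n_ns"] = tally["NS"]
        assert tally["KNOWN"] + tally["NPF"] + tally["NS"] == len(partition), (
            "novelty classes must partition the families"
        )
        report.outputs["verdicts"] = str(verdicts_path)

    novel_ids = {fid for fid, v in verdicts.items() if v.is_novel}
    novel_families = [partition.by_id[fid] for fid in sorted(novel_ids)]

    with timer.stage("extend"):
        coll_sequences, coll_genomes, coll_lineages = _load_collection(config)
        extended = extend_families(
            novel_families, sequences, coll_sequences,
            coll_genomes, coll_lineages, thresholds,
        )
        extension_path = outdir / "extension.tsv"
        write_extension_tsv(extended, extension_path)
        report.counts["n_recruits"] = sum(len(e.recruited) for e in extended.values())
        report.outputs["extension"] = str(extension_path)

    with timer.stage("context"):
        eligible = {
            fid: ext.all_member_ids
            for fid, ext in extended.items()
            if len(ext) >= context_mod.MIN_CONTEXT_FAMILY_SIZE
        }
        profiles = context_mod.profile_families(
            eligible, [dataset], k=thresholds.context_window
        )
        scores = {
            fid: context_mod.conservation_score(profile)
            for fid, profile in profiles.items()
        }
        conserved = context_mod.select_conserved(
            profiles, thresholds.conserved_score_cutoff
        )
        profiles_path = outdir / "context_profiles.tsv"
        context_mod.write_profiles_tsv(profiles, profiles_path)
        conserved_path = outdir / "conserved_families.txt"
        conserved_path.write_text(
            "".join(f"{fid}\n" for fid in sorted(conserved))
        )
        report.counts["n_extended_ge3"] = len(eligible)
        report.counts["n_conserved"] = len(conserved)
        report.outputs["context_profiles"] = str(profiles_path)
        report.outputs["conserved"] = str(conserved_path)

    with timer.stage("dispersion"):
        protein_genome = dataset.protein_genome
        lineage_map = dict(dataset.lineage_map)
        for pid, genome in (coll_genomes or {}).items():
            lineage_map.setdefault(genome, (coll_lineages or {}).get(pid, "?"))
        metrics = {}
        for fid in sorted(novel_ids):
            carriers = dispersion_mod.carrier_genomes(
                extended[fid].all_member_ids, protein_genome,
                extended[fid].recruit_genomes,
            )
            metrics[fid] = dispersion_mod.lineage_metrics(fid, carriers, lineage_map)
        markers = dispersion_mod.select_markers(
            metrics, thresholds.marker_specificity_cutoff,
            thresholds.marker_coverage_cutoff,
        )
        metrics_path = outdir / "lineage_metrics.tsv"
        dispersion_mod.write_metrics_tsv(metrics, markers, metrics_path)
        report.counts["n_markers_per_lineage"] = {
            lineage: len(markers[lineage]) for lineage in sorted(markers)
        }
        report.outputs["lineage_metrics"] = str(metrics_path)

        # per-genome novelty percentages (+ Welch test when a comparison
        # group is configured)
        totals: dict[str, int] = {}
        novel_counts: dict[str, int] = {}
        for pid, genome in protein_genome.items():
            totals[genome] = totals.get(genome, 0) + 1
            if partition.by_protein[pid] in novel_ids:
                novel_counts[genome] = novel_counts.get(genome, 0) + 1
        novelty_table = {
            genome: {
                "total": totals[genome],
                "novel": novel_counts.get(genome, 0),
                "percent": 100.0 * novel_counts.get(genome, 0) / totals[genome],
            }
            for genome in sorted(totals)
        }
        summary_payload: dict = {"per_genome": novelty_table}
        if config.reference_percentages is not None:
            summary = dispersion_mod.novelty_summary(
                protein_genome, partition.by_protein, novel_ids,
                config.reference_percentages,
            )
            summary_payload["welch"] = {
                "t_statistic": summary.t_statistic,
                "df": summary.df,
                "p_value": summary.p_value,
                "study_mean": summary.study_mean,
                "study_sd": summary.study_sd,
                "reference_mean": summary.reference_mean,
                "reference_sd": summary.reference_sd,
            }
        summary_path = outdir / "novelty_summary.json"
        summary_path.write_text(json.dumps(summary_payload, indent=1, sort_keys=True))
        report.outputs["novelty_summary"] = str(summary_path)

        # Pfam presence/absence profile clustering of the genomes
        pfam_labels = sorted(
            {
                label
                for genome in dataset.genomes.values()
                for locus in genome.loci
                for label in locus.annotations.get("PFAM", ())
            }
        )
        if pfam_labels:
            import numpy as np

            genome_ids = sorted(dataset.genomes)
            matrix = np.zeros((len(genome_ids), len(pfam_labels)), dtype=int)
            column = {label: j for j, label in enumerate(pfam_labels)}
            for i, genome_id in enumerate(genome_ids):
                for locus in dataset.genomes[genome_id].loci:
                    for label in locus.annotations.get("PFAM", ()):
                        matrix[i, column[label]] = 1
            clusters = dispersion_mod.jaccard_profile_clustering(
                matrix, genome_ids, cut=thresholds.jaccard_cut
            )
            clusters_path = outdir / "profile_clusters.tsv"
            with open(clusters_path, "w") as handle:
                handle.write("genome_id\tcluster\n")
                for genome_id in genome_ids:
                    handle.write(f"{genome_id}\t{clusters[genome_id]}\n")
            report.counts["n_profile_clusters"] = len(set(clusters.values()))
            report.outputs["profile_clusters"] = str(clusters_path)

    with timer.stage("report"):
        report_path = outdir / "family_report.tsv"
        write_family_report(
            partition, verdicts, metrics, report_path,
            scores=scores, protein_genome=protein_genome,
        )
        report.outputs["family_report"] = str(report_path)
        report.outputs["report"] = str(outdir / "report.json")
        report.outputs = {
            key: str(Path(value).relative_to(outdir))
            for key, value in report.outputs.items()
        }
        report.to_json(outdir / "report.json")

    timer.flush()
    return report
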