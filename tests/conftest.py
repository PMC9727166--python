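"""Shared fixtures: one synthetic community with planted ground truth, the
in-memory analysis chain over it, and a twice-run pipeline for determinism
checks.  All heavyweight objects are session-scoped so the whole suite pays
for clustering and classification once."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from npfkit.clustering import FamilyPartition, cluster_proteins
from npfkit.context import conservation_score, profile_families, select_conserved
from npfkit.dispersion import carrier_genomes, lineage_metrics, select_markers
from npfkit.homology import SequenceDatabase
from npfkit.novelty import DatabaseSuite, classify_partition, extend_families
from npfkit.records import Dataset, Thresholds
from npfkit.simulate import (
    ReferenceDatabase,
    SimulationConfig,
    TruthTable,
    generate_community,
    generate_reference_db,
)

COMMUNITY_SEED = 42


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=COMMUNITY_SEED)


@pytest.fixture(scope="session")
def reference_db(sim_config) -> ReferenceDatabase:
    return generate_reference_db(sim_config)


@pytest.fixture(scope="session")
def community(sim_config, reference_db) -> tuple[Dataset, TruthTable]:
    return generate_community(sim_config, reference_db)


@dataclass
class AnalysisResult:
    """The full in-memory analysis chain over the standard community."""

    dataset: Dataset
    truth: TruthTable
    partition: FamilyPartition
    verdicts: dict
    extended: dict
    profiles: dict
    scores: dict
    conserved: set
    metrics: dict
    markers: dict

    def truth_family_of(self, family_id: str) -> str | None:
        """Planted family whose member set equals this detected family's."""
        members = self.partition.by_id[family_id].member_ids
        for name in self.truth.families:
            if self.truth.members_of(name) == members:
                return name
        return None


@pytest.fixture(scope="session")
def analysis(community, reference_db) -> AnalysisResult:
    dataset, truth = community
    thresholds = Thresholds()
    sequences = dataset.sequences()
    partition = cluster_proteins(sequences, thresholds)
    suite = DatabaseSuite(
        tiers={
            tier: SequenceDatabase(reference_db.views[tier], name=tier)
            for tier in ("OG", "domainA", "domainB", "refseq")
        }
    )
    verdicts = classify_partition(partition, sequences, suite, thresholds)
    novel_ids = sorted(fid for fid, v in verdicts.items() if v.is_novel)
    extended = extend_families(
        [partition.by_id[fid] for fid in novel_ids], sequences, None,
        thresholds=thresholds,
    )
    eligible = {
        fid: ext.all_member_ids for fid, ext in extended.items() if len(ext) >= 3
    }
    profiles = profile_families(eligible, [dataset], k=thresholds.context_window)
    scores = {fid: conservation_score(p) for fid, p in profiles.items()}
    conserved = select_conserved(profiles, thresholds.conserved_score_cutoff)
    protein_genome = dataset.protein_genome
    lineage_map = dataset.lineage_map
    metrics = {
        fid: lineage_metrics(
            fid,
            carrier_genomes(extended[fid].all_member_ids, protein_genome),
            lineage_map,
        )
        for fid in novel_ids
    }
    markers = select_markers(
        metrics, thresholds.marker_specificity_cutoff,
        thresholds.marker_coverage_cutoff,
    )
    return AnalysisResult(
        dataset=dataset, truth=truth, partition=partition, verdicts=verdicts,
        extended=extended, profiles=profiles, scores=scores, conserved=conserved,
        metrics=metrics, markers=markers,
    )


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The full pipeline run twice with identical seed and settings."""
    from npfkit.pipeline import PipelineConfig, run_pipeline

    outdirs = []
    reports = []
    for name in ("run_a", "run_b"):
        outdir = tmp_path_factory.mktemp("pipeline") / name
        config = PipelineConfig(
            outdir=outdir, seed=COMMUNITY_SEED,
            simulation=SimulationConfig(seed=COMMUNITY_SEED),
        )
        reports.append(run_pipeline(config))
        outdirs.append(outdir)
    return outdirs, reports
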