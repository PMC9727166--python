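"""Domain types, dataset loading/writing, and completeness-corrected sizes."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from npfkit.clustering import Family, FamilyPartition
from npfkit.dispersion import LineageMetrics
from npfkit.io import (
    load_dataset,
    read_family_report,
    write_dataset,
    write_family_report,
)
from npfkit.novelty import NoveltyVerdict
from npfkit.records import (
    Dataset,
    DatasetError,
    GeneLocus,
    GenomeTable,
    ProteinRecord,
    Thresholds,
    estimate_complete_size,
)


def _toy_dataset() -> Dataset:
    loci = [
        GeneLocus("p1", "s1", 0, "+", {"PFAM": frozenset({"PF0001"})}),
        GeneLocus("p2", "s1", 1, "-", {}),
    ]
    genome = GenomeTable("g1", "linA", 2_000_000, 0.8, {"s1": loci})
    proteins = {
        "p1": ProteinRecord("p1", "g1", "s1", 0, "+", "MKVLAWWK"),
        "p2": ProteinRecord("p2", "g1", "s1", 1, "-", "ACDEFGHIKLMNP"),
    }
    return Dataset(genomes={"g1": genome}, proteins=proteins)


class TestDomainTypes:
    def test_ambiguity_codes_rejected_but_x_allowed(self):
        ProteinRecord("p", "g", "s", 0, "+", "MKXVLA")
        with pytest.raises(DatasetError, match="invalid residue"):
            ProteinRecord("p", "g", "s", 0, "+", "MKBVLA")

    def test_empty_sequence_rejected(self):
        with pytest.raises(DatasetError, match="empty sequence"):
            ProteinRecord("p", "g", "s", 0, "+", "")

    def test_gene_indices_must_be_contiguous(self):
        loci = [GeneLocus("p1", "s1", 0, "+"), GeneLocus("p2", "s1", 2, "+")]
        with pytest.raises(DatasetError, match="contiguous"):
            GenomeTable("g", "lin", 1, 1.0, {"s1": loci})

    def test_dataset_rejects_locus_for_unknown_protein(self):
        loci = [GeneLocus("pX", "s1", 0, "+")]
        genome = GenomeTable("g1", "lin", 1, 1.0, {"s1": loci})
        with pytest.raises(DatasetError, match="pX"):
            Dataset(genomes={"g1": genome}, proteins={})

    def test_threshold_validation_names_offending_field(self):
        with pytest.raises(ValueError, match="marker_coverage_cutoff"):
            Thresholds(marker_coverage_cutoff=1.5)
        with pytest.raises(ValueError, match="cluster_max_evalue"):
            Thresholds(cluster_max_evalue=0.0)


class TestCompleteSize:
    @pytest.mark.parametrize(
        "size,completeness,expected",
        [
            (2_000_000, 1.0, 2_000_000),
            (1_500_000, 0.5, 3_000_000),
            (2_910_000, 0.97, 3_000_000),
        ],
    )
    def test_worked_examples(self, size, completeness, expected):
        assert estimate_complete_size(size, completeness) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_invalid_completeness_rejected(self, bad):
        with pytest.raises(ValueError):
            estimate_complete_size(1_000_000, bad)

    @settings(deadline=None, max_examples=50)
    @given(
        size=st.integers(min_value=1, max_value=10**8),
        c1=st.floats(min_value=0.01, max_value=1.0),
        c2=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_monotone_decreasing_in_completeness(self, size, c1, c2):
        lo, hi = sorted((c1, c2))
        assert estimate_complete_size(size, hi) <= estimate_complete_size(size, lo)


class TestDatasetRoundTrip:
    def test_write_then_load_is_identity(self, tmp_path):
        dataset = _toy_dataset()
        paths = write_dataset(dataset, tmp_path)
        loaded = load_dataset(
            paths["proteins"], paths["gene_table"],
            paths["annotations"], paths["lineages"],
        )
        assert set(loaded.proteins) == set(dataset.proteins)
        for pid in dataset.proteins:
            assert loaded.proteins[pid] == dataset.proteins[pid]
        for gid, genome in dataset.genomes.items():
            assert loaded.genomes[gid].lineage_id == genome.lineage_id
            assert loaded.genomes[gid].completeness == genome.completeness
            assert loaded.genomes[gid].scaffolds == genome.scaffolds

    def test_shuffled_gene_table_is_resorted_to_ordinals(self, tmp_path):
        dataset = _toy_dataset()
        paths = write_dataset(dataset, tmp_path)
        lines = paths["gene_table"].read_text().splitlines()
        shuffled = [lines[0]] + lines[1:][::-1]
        paths["gene_table"].write_text("\n".join(shuffled) + "\n")
        loaded = load_dataset(
            paths["proteins"], paths["gene_table"],
            paths["annotations"], paths["lineages"],
        )
        indices = [
            locus.gene_index for locus in loaded.genomes["g1"].scaffolds["s1"]
        ]
        assert indices == [0, 1]
        assert loaded.proteins["p1"].gene_index == 0

    def test_gene_table_row_for_absent_protein_names_it(self, tmp_path):
        dataset = _toy_dataset()
        paths = write_dataset(dataset, tmp_path)
        with open(paths["gene_table"], "a") as handle:
            handle.write("pX\tg1\ts1\t9000\t9300\t+\n")
        with pytest.raises(DatasetError, match="pX"):
            load_dataset(
                paths["proteins"], paths["gene_table"],
                paths["annotations"], paths["lineages"],
            )

    def test_empty_fasta_is_a_hard_error(self, tmp_path):
        dataset = _toy_dataset()
        paths = write_dataset(dataset, tmp_path)
        paths["proteins"].write_text("")
        with pytest.raises(DatasetError, match="empty FASTA"):
            load_dataset(
                paths["proteins"], paths["gene_table"],
                paths["annotations"], paths["lineages"],
            )

    def test_gff3_gene_table_dialect(self, tmp_path):
        dataset = _toy_dataset()
        paths = write_dataset(dataset, tmp_path)
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "##genome-id g1\n"
            "s1\tsim\tCDS\t1\t24\t.\t+\t0\tID=p1\n"
            "s1\tsim\tCDS\t1001\t1039\t.\t-\t0\tID=p2\n"
        )
        loaded = load_dataset(
            paths["proteins"], gff, paths["annotations"], paths["lineages"],
        )
        assert loaded.proteins["p2"].gene_index == 1
        assert loaded.proteins["p2"].strand == "-"


class TestFamilyReport:
    def _partition(self):
        families = [
            Family("F2", "p2", frozenset({"p2"}), "p2"),
            Family("F1", "p1", frozenset({"p1"}), "p1"),
        ]
        return FamilyPartition(families)

    def test_empty_partition_gives_header_only(self, tmp_path):
        path = tmp_path / "report.tsv"
        write_family_report(FamilyPartition([]), {}, {}, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("family_id\t")

    def test_rows_ascend_by_family_id(self, tmp_path):
        path = tmp_path / "report.tsv"
        write_family_report(self._partition(), {}, {}, path)
        table = read_family_report(path)
        assert list(table["family_id"]) == ["F1", "F2"]

    def test_reloaded_values_match_in_memory_metrics(self, tmp_path):
        partition = self._partition()
        verdicts = {
            "F1": NoveltyVerdict("F1", "NPF"),
            "F2": NoveltyVerdict("F2", "KNOWN"),
        }
        metrics = {
            "F1": LineageMetrics("F1", {"linA": (0.6, 0.75), "linB": (0.1, 0.25)})
        }
        scores = {"F1": 0.9}
        path = tmp_path / "report.tsv"
        write_family_report(
            partition, verdicts, metrics, path,
            scores=scores, protein_genome={"p1": "g1", "p2": "g2"},
        )
        table = read_family_report(path).set_index("family_id")
        assert table.loc["F1", "novelty_class"] == "NPF"
        assert table.loc["F2", "novelty_class"] == "KNOWN"
        assert float(table.loc["F1", "conservation_score"]) == 0.9
        assert table.loc["F1", "lineage_metrics"] == "linA:0.6:0.75;linB:0.1:0.25"
        assert table.loc["F1", "members_per_genome"] == "g1:1"
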