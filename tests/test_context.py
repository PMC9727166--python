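"""Neighbourhood extraction, conservation profiles and the family score."""

from __future__ import annotations

import logging

import pytest

from npfkit.context import (
    conservation_profile,
    conservation_score,
    extract_neighborhood,
    profile_families,
    select_conserved,
)
from npfkit.records import Dataset, GeneLocus, GenomeTable, ProteinRecord


def _scaffold_dataset(n_genes: int = 7, strands: str | None = None) -> Dataset:
    """One scaffold of n genes; gene i carries OG label ``POS{i}``."""
    strands = strands or "+" * n_genes
    loci = [
        GeneLocus(f"p{i}", "s1", i, strands[i],
                  {"OG": frozenset({f"POS{i}"})})
        for i in range(n_genes)
    ]
    genome = GenomeTable("g1", "lin", 1, 1.0, {"s1": loci})
    proteins = {
        f"p{i}": ProteinRecord(f"p{i}", "g1", "s1", i, strands[i], "MKVLA")
        for i in range(n_genes)
    }
    return Dataset(genomes={"g1": genome}, proteins=proteins)


def _mirror(dataset: Dataset) -> Dataset:
    """Reverse gene order and flip all strands on every scaffold."""
    genomes = {}
    proteins = {}
    for gid, genome in dataset.genomes.items():
        scaffolds = {}
        for sid, loci in genome.scaffolds.items():
            n = len(loci)
            flipped = []
            for locus in reversed(loci):
                flipped.append(
                    GeneLocus(
                        locus.protein_id, sid, n - 1 - locus.gene_index,
                        "+" if locus.strand == "-" else "-",
                        locus.annotations,
                    )
                )
            scaffolds[sid] = flipped
        genomes[gid] = GenomeTable(gid, genome.lineage_id, genome.assembly_size,
                                   genome.completeness, scaffolds)
        for locus in (l for s in scaffolds.values() for l in s):
            old = dataset.proteins[locus.protein_id]
            proteins[locus.protein_id] = ProteinRecord(
                locus.protein_id, gid, locus.scaffold_id, locus.gene_index,
                locus.strand, old.sequence,
            )
    return Dataset(genomes=genomes, proteins=proteins)


class TestExtractNeighborhood:
    def test_scaffold_start_truncates_upstream_offsets(self):
        dataset = _scaffold_dataset(4)
        window = extract_neighborhood("p0", dataset, k=3)
        assert sorted(window) == [0, 1, 2, 3]
        assert window[1].protein_id == "p1"

    def test_minus_strand_reverses_offset_signs(self):
        dataset = _scaffold_dataset(7, strands="+++-+++")
        window = extract_neighborhood("p3", dataset, k=3)
        assert window[-1].protein_id == "p4"
        assert window[1].protein_id == "p2"

    def test_windows_match_hand_enumeration_on_seven_gene_scaffold(self):
        dataset = _scaffold_dataset(7)
        for focal in range(7):
            window = extract_neighborhood(f"p{focal}", dataset, k=3)
            expected = {
                o: f"p{focal + o}"
                for o in range(-3, 4)
                if 0 <= focal + o < 7
            }
            assert {o: l.protein_id for o, l in window.items()} == expected

    def test_unknown_protein_is_a_hard_error(self):
        with pytest.raises(KeyError):
            extract_neighborhood("ghost", _scaffold_dataset(3), k=3)


class TestConservationProfile:
    def _family_dataset(self, labels_at: dict[str, dict[int, str]]) -> Dataset:
        """One genome per family member; member on a 7-gene scaffold at
        index 3 (+ strand); ``labels_at[member][offset]`` sets the OG label
        of the neighbour at that offset."""
        genomes = {}
        proteins = {}
        for m, (member, offsets) in enumerate(labels_at.items()):
            gid = f"g{m}"
            sid = f"{gid}_s"
            loci = []
            for i in range(7):
                offset = i - 3
                if offset == 0:
                    pid, annotations = member, {}
                else:
                    pid = f"{gid}_n{i}"
                    label = offsets.get(offset)
                    annotations = {"OG": frozenset({label})} if label else {}
                loci.append(GeneLocus(pid, sid, i, "+", annotations))
                proteins[pid] = ProteinRecord(pid, gid, sid, i, "+", "MKVLA")
            genomes[gid] = GenomeTable(gid, "lin", 1, 1.0, {sid: loci})
        return Dataset(genomes=genomes, proteins=proteins)

    def test_unanimous_label_scores_one(self):
        dataset = self._family_dataset(
            {f"m{i}": {1: "X"} for i in range(4)}
        )
        profile = conservation_profile("fam", [f"m{i}" for i in range(4)], [dataset])
        assert profile.fractions[(1, "OG", "X")] == 1.0
        assert conservation_score(profile) == 1.0
        assert select_conserved({"fam": profile}) == {"fam"}

    def test_three_of_four_scores_three_quarters(self):
        labels = {f"m{i}": {-2: "K"} for i in range(3)}
        labels["m3"] = {}
        dataset = self._family_dataset(labels)
        profile = conservation_profile("fam", sorted(labels), [dataset])
        assert profile.fractions[(-2, "OG", "K")] == 0.75
        assert conservation_score(profile) == 0.75
        assert select_conserved({"fam": profile}) == set()

    def test_unannotated_neighbourhoods_score_zero(self):
        dataset = self._family_dataset({f"m{i}": {} for i in range(4)})
        profile = conservation_profile("fam", [f"m{i}" for i in range(4)], [dataset])
        assert profile.fractions == {}
        assert conservation_score(profile) == 0.0

    def test_scaffold_edge_members_depress_the_denominator(self):
        # member at scaffold start has no -1 neighbour: the fraction divides
        # by family size, not by occupancy
        dataset = _scaffold_dataset(7)
        profile = conservation_profile("fam", ["p0", "p2"], [dataset], k=1)
        # p2's -1 neighbour is p1 (POS1); p0 has none
        assert profile.fractions[(-1, "OG", "POS1")] == 0.5
        assert profile.occupancy[-1] == 1

    def test_mirrored_scaffold_leaves_profiles_unchanged(self, community):
        dataset, truth = community
        mirrored = _mirror(dataset)
        for name, fam in sorted(truth.families.items()):
            if len(fam.member_ids) < 3:
                continue
            original = conservation_profile(name, fam.member_ids, [dataset])
            flipped = conservation_profile(name, fam.member_ids, [mirrored])
            assert original.fractions == flipped.fractions


class TestPlantedConservation:
    def test_quota_planted_scores_recovered_exactly(self, community):
        dataset, truth = community
        for name, fam in sorted(truth.families.items()):
            if len(fam.member_ids) < 3:
                continue
            profile = conservation_profile(name, fam.member_ids, [dataset])
            # background neighbours each contribute one distinct label, so a
            # family with annotated neighbours scores at least 1/m; the
            # planted quota is recovered exactly above that floor
            floor = 1.0 / len(fam.member_ids)
            expected = max(fam.realized_conservation, floor)
            assert conservation_score(profile) == pytest.approx(
                expected, abs=0
            ), name

    def test_small_families_skipped_with_notice(self, caplog):
        dataset = _scaffold_dataset(7)
        with caplog.at_level(logging.INFO, logger="npfkit.context"):
            profiles = profile_families({"tiny": {"p1", "p2"}}, [dataset])
        assert profiles == {}
        assert any("skipped" in record.message for record in caplog.records)
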