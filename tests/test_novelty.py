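"""Novelty cascade, family extension and prior-collection overlap."""

from __future__ import annotations

import numpy as np
import pytest

from npfkit.clustering import Family
from npfkit.homology import SequenceDatabase
from npfkit.novelty import (
    DatabaseSuite,
    classify_family_novelty,
    collection_overlap,
    extend_families,
    ExtendedFamily,
)
from npfkit.records import Thresholds
from npfkit.simulate import (
    _kmer_set,
    generate_collection,
    mutate_sequence,
    random_protein,
)


def _suite_from(reference_db) -> DatabaseSuite:
    return DatabaseSuite(
        tiers={
            tier: SequenceDatabase(reference_db.views[tier], name=tier)
            for tier in ("OG", "domainA", "domainB", "refseq")
        }
    )


def _singleton(pid: str) -> Family:
    return Family(pid, pid, frozenset({pid}), pid)


class TestCascade:
    def test_missing_tier_is_a_hard_error(self):
        db = SequenceDatabase({"x": "MKVLAWWK"})
        with pytest.raises(ValueError, match="missing tier"):
            DatabaseSuite(tiers={"OG": db})

    def test_member_identical_to_og_entry_is_known(self, reference_db):
        suite = _suite_from(reference_db)
        entry = next(iter(reference_db.views["OG"].values()))
        verdict = classify_family_novelty(
            _singleton("q"), {"q": entry}, suite
        )
        assert verdict.klass == "KNOWN"
        tier, hit = verdict.evidence["q"]
        assert tier == "OG"
        assert hit.evalue <= 1e-3

    def test_planted_novel_singleton_is_ns(self, community, reference_db):
        dataset, truth = community
        suite = _suite_from(reference_db)
        singleton_family = next(
            name for name, fam in truth.families.items()
            if len(fam.member_ids) == 1
        )
        pid = truth.families[singleton_family].member_ids[0]
        verdict = classify_family_novelty(
            _singleton(pid), {pid: dataset.proteins[pid].sequence}, suite
        )
        assert verdict.klass == "NS"
        assert verdict.evidence[pid] is None

    def test_multi_member_novel_family_is_npf(self, community, reference_db):
        dataset, truth = community
        suite = _suite_from(reference_db)
        name = next(
            name for name, fam in truth.families.items()
            if len(fam.member_ids) > 1
        )
        members = truth.members_of(name)
        rep = sorted(members)[0]
        family = Family("fam", rep, members, rep)
        verdict = classify_family_novelty(
            family, dataset.sequences(), suite
        )
        assert verdict.klass == "NPF"

    def test_augmenting_a_tier_only_moves_verdicts_toward_known(
        self, community, reference_db
    ):
        dataset, truth = community
        name = sorted(truth.families)[0]
        members = truth.members_of(name)
        rep = sorted(members)[0]
        family = Family("fam", rep, members, rep)
        sequences = dataset.sequences()
        base_suite = _suite_from(reference_db)
        assert classify_family_novelty(family, sequences, base_suite).klass == "NPF"
        # add one member's own sequence to the refseq tier → KNOWN
        augmented = dict(reference_db.views["refseq"])
        augmented["planted_copy"] = sequences[rep]
        suite = DatabaseSuite(
            tiers={
                "OG": base_suite.tiers["OG"],
                "domainA": base_suite.tiers["domainA"],
                "domainB": base_suite.tiers["domainB"],
                "refseq": SequenceDatabase(augmented, name="refseq"),
            }
        )
        assert classify_family_novelty(family, sequences, suite).klass == "KNOWN"
        # adding unrelated sequences must not flip a KNOWN family back
        rng = np.random.default_rng(0)
        augmented.update({f"r{i}": random_protein(rng, 120) for i in range(10)})
        suite.tiers["refseq"] = SequenceDatabase(augmented, name="refseq")
        assert classify_family_novelty(family, sequences, suite).klass == "KNOWN"


class TestExtension:
    def test_exact_copy_in_collection_is_recruited(self):
        rng = np.random.default_rng(1)
        seq = random_protein(rng, 150)
        family = _singleton("q")
        extended = extend_families(
            [family], {"q": seq}, {"copy": seq, "noise": random_protein(rng, 150)},
            {"copy": "gX", "noise": "gY"}, {"copy": "linX", "noise": "linY"},
        )
        assert set(extended["q"].recruited) == {"copy"}
        assert extended["q"].recruit_genomes["copy"] == "gX"

    def test_disjoint_collection_recruits_nothing(self):
        rng = np.random.default_rng(2)
        seq = random_protein(rng, 150)
        index = _kmer_set(seq, 8)
        collection = {}
        while len(collection) < 10:
            candidate = random_protein(rng, 150)
            if index.isdisjoint(_kmer_set(candidate, 8)):
                collection[f"c{len(collection)}"] = candidate
        extended = extend_families([_singleton("q")], {"q": seq}, collection)
        assert extended["q"].recruited == {}

    def test_planted_collection_copies_all_recovered(self, community, reference_db):
        dataset, truth = community
        name = next(
            name for name, fam in truth.families.items()
            if len(fam.member_ids) >= 4
        )
        carriers = {
            name: [(f"EXT_G{i:02d}", "LEXT") for i in range(7)]
        }
        sequences, genome_of, lineage_of = generate_collection(
            truth, reference_db, carriers, rate=0.15, seed=3,
        )
        members = truth.members_of(name)
        lengths = {pid: len(dataset.proteins[pid].sequence) for pid in members}
        rep = min(members, key=lambda p: (-lengths[p], p))
        family = Family("fam", rep, members, rep)
        extended = extend_families(
            [family], dataset.sequences(), sequences, genome_of, lineage_of,
        )
        recruited = extended["fam"]
        assert set(recruited.recruited) == {
            f"EXT_G{i:02d}|{name}" for i in range(7)
        }
        assert set(recruited.recruit_genomes.values()) == {
            f"EXT_G{i:02d}" for i in range(7)
        }

    def test_recruits_cannot_overlap_original_members(self):
        with pytest.raises(ValueError, match="overlap"):
            ExtendedFamily("f", frozenset({"a"}), recruited={"a": None})


class TestCollectionOverlap:
    def _family_of(self, members: dict[str, str]) -> ExtendedFamily:
        return ExtendedFamily("fam", frozenset(members))

    def test_identical_family_is_present_with_fraction_one(self):
        rng = np.random.default_rng(4)
        seqs = {f"m{i}": random_protein(rng, 120) for i in range(4)}
        present, best, fraction = collection_overlap(
            self._family_of(seqs), seqs, {"prior1": dict(seqs)}
        )
        assert present and best == "prior1" and fraction == 1.0

    def test_disjoint_family_is_absent_with_fraction_zero(self):
        rng = np.random.default_rng(5)
        seqs = {f"m{i}": random_protein(rng, 120) for i in range(3)}
        index = set().union(*(_kmer_set(s, 8) for s in seqs.values()))
        prior = {}
        while len(prior) < 3:
            candidate = random_protein(rng, 120)
            if index.isdisjoint(_kmer_set(candidate, 8)):
                prior[f"p{len(prior)}"] = candidate
        present, _best, fraction = collection_overlap(
            self._family_of(seqs), seqs, {"prior1": prior}
        )
        assert not present and fraction == 0.0

    def test_nine_of_ten_is_absent_at_the_strict_boundary(self):
        rng = np.random.default_rng(6)
        seed = random_protein(rng, 150)
        members = {f"m{i}": mutate_sequence(seed, 0.1, rng) for i in range(9)}
        index = _kmer_set(seed, 8)
        while True:
            outlier = random_protein(rng, 150)
            if index.isdisjoint(_kmer_set(outlier, 8)):
                break
        members["outlier"] = outlier
        prior = {"prior1": {"p0": seed}}
        present, best, fraction = collection_overlap(
            self._family_of(members), members, prior
        )
        assert fraction == pytest.approx(0.9)
        assert not present  # strictly greater than 0.90 is required
        del members["outlier"]
        present_full, _b, fraction_full = collection_overlap(
            self._family_of(members), members, prior
        )
        assert fraction_full == 1.0 and present_full
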