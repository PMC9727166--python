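"""Novelty cascade, family extension and prior-collection overlap.

A family is *known* when any member has a significant hit in any of four
reference tiers: orthologous groups (E < 1e-3), two domain databases
(E < 1e-5 each) and a reference protein collection (E < 1e-3 and query
coverage > 50%).  Families with no significant hit anywhere are novel protein
families (NPFs); a novel family observed only once in the analysed genome
group is a novel singleton (NS).  NPFs and NSs are then *extended* by querying
the longest member against an external genome collection and recruiting every
significant hit (E ≤ 1e-3, query coverage ≥ 0.5); the class assigned at
cascade time is frozen, extension only grows membership.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .clustering import Family, FamilyPartition
from .homology import AlignmentResult, SequenceDatabase, search
from .records import Thresholds

__all__ = [
    "TIER_ORDER",
    "DatabaseSuite",
    "NoveltyVerdict",
    "ExtendedFamily",
    "classify_family_novelty",
    "classify_partition",
    "extend_families",
    "collection_overlap",
    "write_verdicts_tsv",
    "write_extension_tsv",
]

#: Cascade order; a member stops searching at its first significant tier.
TIER_ORDER = ("OG", "domainA", "domainB", "refseq")


@dataclass
class DatabaseSuite:
    """The four reference tiers with their per-tier significance rules."""

    tiers: dict[str, SequenceDatabase]

    def __post_init__(self) -> None:
        missing = [t for t in TIER_ORDER if t not in self.tiers]
        if missing:
            raise ValueError(f"database suite missing tier(s): {missing}")

    def tier_thresholds(self, thresholds: Thresholds) -> dict[str, tuple[float, float]]:
        """tier → (max E-value, min query coverage)."""
        return {
            "OG": (thresholds.novelty_evalue_og, 0.0),
            "domainA": (thresholds.novelty_evalue_domainA, 0.0),
            "domainB": (thresholds.novelty_evalue_domainB, 0.0),
            "refseq": (thresholds.novelty_evalue_refseq, thresholds.novelty_refseq_min_qcov),
        }


@dataclass
class NoveltyVerdict:
    """Classification of one family with per-member hit evidence.

    ``evidence`` maps each member to the (tier, best hit) that made it known,
    or ``None`` when the member hit nothing in any tier.
    """

    family_id: str
    klass: str  # KNOWN | NPF | NS
    evidence: dict[str, tuple[str, AlignmentResult] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klass not in ("KNOWN", "NPF", "NS"):
            raise ValueError(f"invalid novelty class {self.klass!r}")

    @property
    def is_novel(self) -> bool:
        return self.klass in ("NPF", "NS")


def classify_family_novelty(
    family: Family,
    sequences: dict[str, str],
    suite: DatabaseSuite,
    thresholds: Thresholds | None = None,
) -> NoveltyVerdict:
    """Run every member through the cascade and classify the family.

    A single significant member hit in any tier makes the whole family KNOWN;
    otherwise the family is an NPF, or an NS when it has exactly one member.
    """
    thresholds = thresholds or Thresholds()
    rules = suite.tier_thresholds(thresholds)
    evidence: dict[str, tuple[str, AlignmentResult] | None] = {}
    any_hit = False
    for member in sorted(family.member_ids):
        member_evidence = None
        for tier in TIER_ORDER:
            max_e, min_qcov = rules[tier]
            hits = search(
                sequences[member], suite.tiers[tier], max_e, min_qcov,
                query_id=member,
            )
            if hits:
                member_evidence = (tier, hits[0])
                any_hit = True
                break
        evidence[member] = member_evidence
    if any_hit:
        klass = "KNOWN"
    elif len(family.member_ids) == 1:
        klass = "NS"
    else:
        klass = "NPF"
    return NoveltyVerdict(family_id=family.family_id, klass=klass, evidence=evidence)


def classify_partition(
    partition: FamilyPartition,
    sequences: dict[str, str],
    suite: DatabaseSuite,
    thresholds: Thresholds | None = None,
) -> dict[str, NoveltyVerdict]:
    return {
        family.family_id: classify_family_novelty(family, sequences, suite, thresholds)
        for family in partition.families
    }


@dataclass
class ExtendedFamily:
    """A novel family plus the members recruited from an external collection."""

    family_id: str
    original_member_ids: frozenset[str]
    recruited: dict[str, AlignmentResult] = field(default_factory=dict)
    recruit_genomes: dict[str, str] = field(default_factory=dict)   # recruit → genome
    recruit_lineages: dict[str, str] = field(default_factory=dict)  # recruit → lineage

    def __post_init__(self) -> None:
        overlap = self.original_member_ids & set(self.recruited)
        if overlap:
            raise ValueError(
                f"family {self.family_id}: recruits overlap original members: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def all_member_ids(self) -> frozenset[str]:
        return self.original_member_ids | set(self.recruited)

    def __len__(self) -> int:
        return len(self.original_member_ids) + len(self.recruited)


def extend_families(
    novel_families: list[Family],
    sequences: dict[str, str],
    collection_sequences: dict[str, str] | None,
    collection_genomes: dict[str, str] | None = None,
    collection_lineages: dict[str, str] | None = None,
    thresholds: Thresholds | None = None,
) -> dict[str, ExtendedFamily]:
    """Recruit external homologs into each novel family.

    The query is the family's longest member (ties already resolved to the
    smallest id at clustering time).  With no collection supplied, every
    family is returned unextended.
    """
    thresholds = thresholds or Thresholds()
    collection_genomes = collection_genomes or {}
    collection_lineages = collection_lineages or {}
    extended: dict[str, ExtendedFamily] = {}
    database = (
        SequenceDatabase(collection_sequences, name="collection")
        if collection_sequences
        else None
    )
    for family in novel_families:
        recruited: dict[str, AlignmentResult] = {}
        if database is not None:
            hits = search(
                sequences[family.longest_member_id],
                database,
                thresholds.extension_max_evalue,
                thresholds.extension_min_qcov,
                query_id=family.longest_member_id,
            )
            for hit in hits:
                if hit.target_id not in family.member_ids:
                    recruited[hit.target_id] = hit
        extended[family.family_id] = ExtendedFamily(
            family_id=family.family_id,
            original_member_ids=family.member_ids,
            recruited=recruited,
            recruit_genomes={
                rid: collection_genomes.get(rid, "?") for rid in recruited
            },
            recruit_lineages={
                rid: collection_lineages.get(rid, "?") for rid in recruited
            },
        )
    return extended


def collection_overlap(
    extended_family: ExtendedFamily,
    member_sequences: dict[str, str],
    prior_collection: dict[str, dict[str, str]],
    thresholds: Thresholds | None = None,
) -> tuple[bool, str | None, float]:
    """Is this family already present in a prior novel-family collection?

    For each prior family, the overlap fraction is the share of this family's
    members with a significant hit (E ≤ 1e-3, query coverage ≥ 0.5) to any of
    that prior family's sequences.  The family is *present* when the best
    fraction strictly exceeds 0.90.  Returns (present, best prior family id,
    best fraction).
    """
    thresholds = thresholds or Thresholds()
    members = sorted(extended_family.all_member_ids & set(member_sequences))
    if not members:
        raise ValueError(f"family {extended_family.family_id}: no member sequences")
    best_id: str | None = None
    best_fraction = 0.0
    for prior_id in sorted(prior_collection):
        db = SequenceDatabase(prior_collection[prior_id], name=prior_id)
        matched = 0
        for member in members:
            hits = search(
                member_sequences[member], db,
                thresholds.extension_max_evalue, thresholds.extension_min_qcov,
                query_id=member,
            )
            if hits:
                matched += 1
        fraction = matched / len(members)
        if fraction > best_fraction or (fraction == best_fraction and best_id is None):
            best_fraction = fraction
            best_id = prior_id
    present = best_fraction > thresholds.overlap_member_fraction
    return present, best_id, best_fraction


def write_verdicts_tsv(verdicts: dict[str, NoveltyVerdict], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["family_id", "class", "member_id", "evidence_tier",
                         "best_hit", "evalue"])
        for family_id in sorted(verdicts):
            verdict = verdicts[family_id]
            for member in sorted(verdict.evidence):
                item = verdict.evidence[member]
                if item is None:
                    writer.writerow([family_id, verdict.klass, member, "", "", ""])
                else:
                    tier, hit = item
                    writer.writerow(
                        [family_id, verdict.klass, member, tier,
                         hit.target_id, f"{hit.evalue:.6g}"]
                    )


def write_extension_tsv(extended: dict[str, ExtendedFamily], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["family_id", "recruit_id", "genome_id", "lineage_id",
                         "evalue", "qcov"])
        for family_id in sorted(extended):
            fam = extended[family_id]
            for recruit_id in sorted(fam.recruited):
                hit = fam.recruited[recruit_id]
                writer.writerow(
                    [family_id, recruit_id,
                     fam.recruit_genomes.get(recruit_id, "?"),
                     fam.recruit_lineages.get(recruit_id, "?"),
                     f"{hit.evalue:.6g}", f"{hit.query_coverage:.4f}"]
                )
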