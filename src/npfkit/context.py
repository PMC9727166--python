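"""Gene-neighbourhood extraction and functional-conservation scoring.

For each member of an extended family the ±3 gene window around the focal
gene is read off the scaffold by gene-order arithmetic.  Offsets are oriented
in the focal gene's frame: on the minus strand the gene at ``index + 1``
appears at offset −1, so that offset +1 is always downstream of the focal
gene.  For every (offset, namespace, label) triple the conservation fraction
is the number of members whose neighbour at that offset carries the label,
divided by the number of genes in the family; members whose window is
truncated at a scaffold edge therefore depress conservation.  The family's
conservation score is the maximum fraction over all triples, and families
scoring ≥ 0.9 are called conserved.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .records import Dataset, GeneLocus

__all__ = [
    "ContextProfile",
    "extract_neighborhood",
    "conservation_profile",
    "conservation_score",
    "select_conserved",
    "profile_families",
    "write_profiles_tsv",
]

logger = logging.getLogger(__name__)

MIN_CONTEXT_FAMILY_SIZE = 3


def extract_neighborhood(
    protein_id: str, dataset: Dataset, k: int = 3
) -> dict[int, GeneLocus]:
    """Loci at offsets −k..+k around a focal gene, in the focal gene's frame.

    Offsets past a scaffold end are simply absent.  Offset 0 (the focal gene
    itself) is included for completeness; conservation scoring ignores it.
    """
    genome, locus = dataset.locus_of(protein_id)
    scaffold = genome.scaffolds[locus.scaffold_id]
    sign = 1 if locus.strand == "+" else -1
    window: dict[int, GeneLocus] = {}
    for offset in range(-k, k + 1):
        index = locus.gene_index + sign * offset
        if 0 <= index < len(scaffold):
            window[offset] = scaffold[index]
    return window


@dataclass
class ContextProfile:
    """Per-offset, per-namespace label conservation for one family."""

    family_id: str
    n_members: int
    k: int
    fractions: dict[tuple[int, str, str], float] = field(default_factory=dict)
    occupancy: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (offset, _ns, _label), fraction in self.fractions.items():
            if offset == 0:
                raise ValueError("offset 0 must not appear in a context profile")
            if not (0.0 <= fraction <= 1.0):
                raise ValueError(f"conservation fraction out of range: {fraction}")


def conservation_profile(
    family_id: str,
    member_ids,
    datasets: list[Dataset],
    k: int = 3,
) -> ContextProfile:
    """Conservation fractions over the ±k window of every family member.

    Members are looked up across the given datasets (the study genomes plus,
    when extension recruited external proteins, the collection).  A member
    found in no dataset contributes to the denominator only.
    """
    members = sorted(member_ids)
    n = len(members)
    counts: dict[tuple[int, str, str], int] = {}
    occupancy: dict[int, int] = {o: 0 for o in range(-k, k + 1) if o != 0}
    for member in members:
        window = None
        for dataset in datasets:
            if member in dataset.proteins:
                window = extract_neighborhood(member, dataset, k)
                break
        if window is None:
            continue
        for offset, locus in window.items():
            if offset == 0:
                continue
            occupancy[offset] += 1
            for namespace, labels in locus.annotations.items():
                for label in labels:
                    key = (offset, namespace, label)
                    counts[key] = counts.get(key, 0) + 1
    fractions = {key: count / n for key, count in counts.items()}
    return ContextProfile(
        family_id=family_id, n_members=n, k=k,
        fractions=fractions, occupancy=occupancy,
    )


def conservation_score(profile: ContextProfile) -> float:
    """Maximum conservation fraction over all (offset, namespace, label)."""
    if not profile.fractions:
        return 0.0
    return max(profile.fractions.values())


def select_conserved(
    profiles: dict[str, ContextProfile], cutoff: float = 0.90
) -> set[str]:
    """Family ids whose conservation score reaches the cutoff."""
    return {
        family_id
        for family_id, profile in profiles.items()
        if conservation_score(profile) >= cutoff
    }


def profile_families(
    families: dict[str, frozenset[str] | set[str]],
    datasets: list[Dataset],
    k: int = 3,
    min_size: int = MIN_CONTEXT_FAMILY_SIZE,
) -> dict[str, ContextProfile]:
    """Profile every family with at least ``min_size`` members.

    Smaller families are skipped with a logged notice — their neighbourhood
    support is too thin to score.
    """
    profiles: dict[str, ContextProfile] = {}
    for family_id in sorted(families):
        members = families[family_id]
        if len(members) < min_size:
            logger.info(
                "family %s skipped for context scoring: %d member(s) < %d",
                family_id, len(members), min_size,
            )
            continue
        profiles[family_id] = conservation_profile(family_id, members, datasets, k)
    return profiles


def write_profiles_tsv(profiles: dict[str, ContextProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["family_id", "offset", "namespace", "label",
                         "fraction", "occupancy"])
        for family_id in sorted(profiles):
            profile = profiles[family_id]
            for (offset, namespace, label) in sorted(profile.fractions):
                writer.writerow(
                    [family_id, offset, namespace, label,
                     f"{profile.fractions[(offset, namespace, label)]:.6g}",
                     profile.occupancy.get(offset, 0)]
                )
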