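"""Greedy set-cover clustering over the significant-hit graph.

All proteins are first compared all-vs-all under relaxed homology thresholds
(identity ≥ 0.30, E ≤ 1e-3, query coverage ≥ 0.50, coverage measured on the
query so that a short member may join a long representative).  The resulting
directed graph is then partitioned by greedy set cover: repeatedly pick the
uncovered protein that the most uncovered proteins can still join (ties
broken by longer sequence, then lexicographically smaller id) as a
representative; that protein together with the uncovered proteins holding a
qualifying edge onto it forms one family.  The
result is an exhaustive, disjoint partition, stable under permutation of the
input order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .homology import _ALIGNER, PREFILTER_K, _kmers, align_local, evalue_from_score
from .records import Thresholds

__all__ = [
    "Family",
    "FamilyPartition",
    "build_hit_graph",
    "greedy_set_cover_cluster",
    "cluster_proteins",
    "write_partition_tsv",
    "read_partition_tsv",
]


@dataclass(frozen=True)
class Family:
    """A protein family: representative, members and the longest member."""

    family_id: str
    representative_id: str
    member_ids: frozenset[str]
    longest_member_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"family {self.family_id}: representative not among members"
            )
        if self.longest_member_id not in self.member_ids:
            raise ValueError(
                f"family {self.family_id}: longest member not among members"
            )

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class FamilyPartition:
    """An exhaustive, disjoint set of families over one protein universe."""

    families: list[Family]

    def __post_init__(self) -> None:
        self.by_protein: dict[str, str] = {}
        for family in self.families:
            for member in family.member_ids:
                if member in self.by_protein:
                    raise ValueError(
                        f"protein {member!r} assigned to more than one family"
                    )
                self.by_protein[member] = family.family_id
        self.by_id = {f.family_id: f for f in self.families}

    def validate_against(self, protein_ids) -> None:
        universe = set(protein_ids)
        covered = set(self.by_protein)
        if covered != universe:
            missing = universe - covered
            extra = covered - universe
            raise ValueError(
                f"partition does not match protein universe: "
                f"missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.families)


def _longest_member(member_ids, lengths: dict[str, int]) -> str:
    return min(member_ids, key=lambda pid: (-lengths[pid], pid))


def build_hit_graph(proteins: dict[str, str], thresholds: Thresholds | None = None,
                    *, prefilter: bool = True) -> nx.DiGraph:
    """Directed significant-hit graph over a protein set.

    Edge u→v exists iff the local alignment of u (query) against v (target)
    satisfies E ≤ cluster_max_evalue, identity ≥ cluster_min_identity and
    query coverage ≥ cluster_min_query_cov.  Self-edges are always present.
    E-values use the pairwise convention (n = target length).  Since the raw
    score, identity and E-value of a pair are symmetric, each unordered pair
    is aligned once and both directed edges are decided from it (only the
    coverage side differs).
    """
    if not proteins:
        raise ValueError("build_hit_graph requires at least one protein")
    thresholds = thresholds or Thresholds()
    graph = nx.DiGraph()
    ids = sorted(proteins)
    for pid in ids:
        graph.add_node(pid, length=len(proteins[pid]))
        graph.add_edge(pid, pid)
    kmer_sets = {pid: _kmers(proteins[pid]) for pid in ids} if prefilter else None
    for i, u in enumerate(ids):
        seq_u = proteins[u]
        for v in ids[i + 1 :]:
            if prefilter and kmer_sets[u].isdisjoint(kmer_sets[v]):
                continue
            seq_v = proteins[v]
            score = _ALIGNER.score(seq_u, seq_v)
            if (
                evalue_from_score(score, len(seq_u), len(seq_v))
                > thresholds.cluster_max_evalue
            ):
                continue
            result = align_local(seq_u, seq_v, query_id=u, target_id=v)
            if result.evalue > thresholds.cluster_max_evalue:
                continue
            if result.identity < thresholds.cluster_min_identity:
                continue
            if result.query_coverage >= thresholds.cluster_min_query_cov:
                graph.add_edge(u, v)
            if result.target_coverage >= thresholds.cluster_min_query_cov:
                graph.add_edge(v, u)
    return graph


def greedy_set_cover_cluster(graph: nx.DiGraph) -> FamilyPartition:
    """Partition the hit graph into families by greedy set cover.

    Until every protein is covered: among uncovered proteins, pick the one
    that the most uncovered proteins can join — i.e. with the most uncovered
    in-neighbours, each candidate member satisfying the query-coverage rule
    with itself as the query — ties go to the longer sequence, then the
    smaller id — and emit it with its uncovered in-neighbours as one family.
    Family ids are assigned in order of selection (``F000001``, ...).
    """
    lengths = {node: graph.nodes[node].get("length", 0) for node in graph.nodes}
    uncovered = set(graph.nodes)
    families: list[Family] = []
    while uncovered:
        best = None
        best_key = None
        for node in uncovered:
            gain = sum(1 for nbr in graph.predecessors(node) if nbr in uncovered)
            key = (-gain, -lengths[node], node)
            if best_key is None or key < best_key:
                best_key = key
                best = node
        members = {nbr for nbr in graph.predecessors(best) if nbr in uncovered}
        members.add(best)
        uncovered -= members
        families.append(
            Family(
                family_id=f"F{len(families) + 1:06d}",
                representative_id=best,
                member_ids=frozenset(members),
                longest_member_id=_longest_member(members, lengths),
            )
        )
    partition = FamilyPartition(families)
    partition.validate_against(graph.nodes)
    # every member must have a qualifying edge to its representative
    for family in partition.families:
        for member in family.member_ids:
            if not graph.has_edge(member, family.representative_id):
                raise AssertionError(
                    f"member {member!r} lacks an edge to representative "
                    f"{family.representative_id!r}"
                )
    return partition


def cluster_proteins(proteins: dict[str, str],
                     thresholds: Thresholds | None = None) -> FamilyPartition:
    """All-vs-all comparison followed by greedy set-cover clustering."""
    return greedy_set_cover_cluster(build_hit_graph(proteins, thresholds))


def write_partition_tsv(partition: FamilyPartition, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["family_id", "representative_id", "protein_id"])
        for family in sorted(partition.families, key=lambda f: f.family_id):
            for member in sorted(family.member_ids):
                writer.writerow([family.family_id, family.representative_id, member])


def read_partition_tsv(path: str | Path, lengths: dict[str, int]) -> FamilyPartition:
    rows: dict[str, tuple[str, set[str]]] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if header[:3] != ["family_id", "representative_id", "protein_id"]:
            raise ValueError(f"unexpected partition header in {path}: {header}")
        for family_id, representative_id, protein_id in reader:
            rows.setdefault(family_id, (representative_id, set()))[1].add(protein_id)
    families = [
        Family(
            family_id=family_id,
            representative_id=rep,
            member_ids=frozenset(members),
            longest_member_id=_longest_member(members, lengths),
        )
        for family_id, (rep, members) in sorted(rows.items())
    ]
    return FamilyPartition(families)
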