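"""Lineage dispersion metrics, marker selection, novelty rates and profile
clustering.

For every lineage in which a family is detected:

* coverage   = carrier genomes of the lineage / genomes of the lineage in the
  database,
* specificity = carrier genomes of the lineage / all carrier genomes of the
  family

(a genome counts once however many members it holds; specificities over
lineages sum to 1).  A family marks a lineage when both exceed 0.7 strictly —
at most one lineage can qualify, since two specificities > 0.7 cannot
coexist.  Per-genome novelty rates (percentage of proteins in novel families)
are compared between genome groups with Welch's unequal-variance two-sample
t-test.  Binary presence/absence profiles are clustered by single-linkage
agglomeration on Jaccard distances with a flat cut.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import cluster as scipy_cluster
from scipy import stats

__all__ = [
    "LineageMetrics",
    "NoveltySummary",
    "carrier_genomes",
    "lineage_metrics",
    "select_markers",
    "welch_ttest",
    "novelty_summary",
    "jaccard_profile_clustering",
    "write_metrics_tsv",
]


@dataclass
class LineageMetrics:
    """Per-lineage (coverage, specificity) pairs for one family."""

    family_id: str
    per_lineage: dict[str, tuple[float, float]] = field(default_factory=dict)

    def coverage(self, lineage: str) -> float:
        return self.per_lineage.get(lineage, (0.0, 0.0))[0]

    def specificity(self, lineage: str) -> float:
        return self.per_lineage.get(lineage, (0.0, 0.0))[1]


def carrier_genomes(member_ids, protein_genome: dict[str, str],
                    recruit_genomes: dict[str, str] | None = None) -> set[str]:
    """Distinct genomes carrying at least one member of a family."""
    recruit_genomes = recruit_genomes or {}
    genomes = set()
    for member in member_ids:
        genome = protein_genome.get(member) or recruit_genomes.get(member)
        if genome is None:
            raise KeyError(f"no genome known for member {member!r}")
        genomes.add(genome)
    return genomes


def lineage_metrics(
    family_id: str,
    carriers: set[str],
    lineage_map: dict[str, str],
) -> LineageMetrics:
    """Coverage and specificity of a family within each lineage it touches.

    ``lineage_map`` covers the whole genome database; its lineage sizes are
    the coverage denominators.
    """
    missing = sorted(g for g in carriers if g not in lineage_map)
    if missing:
        raise KeyError(f"carrier genome(s) missing from lineage map: {missing[:5]}")
    lineage_sizes: dict[str, int] = {}
    for lineage in lineage_map.values():
        lineage_sizes[lineage] = lineage_sizes.get(lineage, 0) + 1
    carriers_per_lineage: dict[str, int] = {}
    for genome in carriers:
        lineage = lineage_map[genome]
        carriers_per_lineage[lineage] = carriers_per_lineage.get(lineage, 0) + 1
    total_carriers = len(carriers)
    per_lineage = {
        lineage: (count / lineage_sizes[lineage], count / total_carriers)
        for lineage, count in carriers_per_lineage.items()
    }
    return LineageMetrics(family_id=family_id, per_lineage=per_lineage)


def select_markers(
    metrics: dict[str, LineageMetrics],
    specificity_cutoff: float = 0.70,
    coverage_cutoff: float = 0.70,
) -> dict[str, set[str]]:
    """lineage → families that are specific AND widespread there (strict >)."""
    markers: dict[str, set[str]] = {}
    for family_id, m in metrics.items():
        for lineage, (coverage, specificity) in m.per_lineage.items():
            if specificity > specificity_cutoff and coverage > coverage_cutoff:
                markers.setdefault(lineage, set()).add(family_id)
    return markers


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test: (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


@dataclass
class NoveltySummary:
    """Per-genome novelty percentages and the between-group Welch test."""

    per_genome: dict[str, tuple[int, int, float]]  # genome → (total, novel, %)
    study_mean: float
    study_sd: float
    reference_mean: float
    reference_sd: float
    t_statistic: float
    df: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "per_genome": {
                g: {"total": t, "novel": n, "percent": p}
                for g, (t, n, p) in sorted(self.per_genome.items())
            },
            "study_mean": self.study_mean,
            "study_sd": self.study_sd,
            "reference_mean": self.reference_mean,
            "reference_sd": self.reference_sd,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def novelty_summary(
    protein_genome: dict[str, str],
    partition_by_protein: dict[str, str],
    novel_family_ids: set[str],
    reference_group_percentages,
) -> NoveltySummary:
    """Novelty percentage per genome plus the Welch test vs a reference group.

    The percentage for a genome is 100 × (proteins in NPF∪NS families) /
    (total proteins).  ``reference_group_percentages`` is the comparison
    group's per-genome novelty percentages (≥ 2 values).
    """
    totals: dict[str, int] = {}
    novel: dict[str, int] = {}
    for protein_id, genome in protein_genome.items():
        totals[genome] = totals.get(genome, 0) + 1
        if partition_by_protein[protein_id] in novel_family_ids:
            novel[genome] = novel.get(genome, 0) + 1
    per_genome = {
        genome: (
            totals[genome],
            novel.get(genome, 0),
            100.0 * novel.get(genome, 0) / totals[genome],
        )
        for genome in totals
    }
    study = np.array([p for (_t, _n, p) in per_genome.values()], dtype=float)
    reference = np.asarray(list(reference_group_percentages), dtype=float)
    t, df, p = welch_ttest(study, reference)
    return NoveltySummary(
        per_genome=per_genome,
        study_mean=float(study.mean()),
        study_sd=float(study.std(ddof=1)) if len(study) > 1 else 0.0,
        reference_mean=float(reference.mean()),
        reference_sd=float(reference.std(ddof=1)),
        t_statistic=t,
        df=df,
        p_value=p,
    )


def _jaccard_condensed(matrix: np.ndarray) -> np.ndarray:
    """Condensed Jaccard distances over the rows of a binary matrix.

    d = 1 − |A∩B| / |A∪B|, with d = 0 when both rows are empty sets.
    """
    n = matrix.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(matrix[i], matrix[j]).sum()
            if union == 0:
                out.append(0.0)
            else:
                inter = np.logical_and(matrix[i], matrix[j]).sum()
                out.append(1.0 - inter / union)
    return np.array(out, dtype=float)


def jaccard_profile_clustering(
    presence, genome_ids=None, cut: float = 0.40
) -> dict[str, str]:
    """Single-linkage clustering of genomes by binary profile similarity.

    ``presence`` is a genomes × profiles 0/1 matrix (a DataFrame with genome
    index, or an array plus ``genome_ids``).  Clusters are flattened at
    cophenetic distance ≤ ``cut`` and labelled by their smallest genome id.
    """
    try:
        import pandas as pd

        if isinstance(presence, pd.DataFrame):
            genome_ids = list(presence.index.astype(str))
            presence = presence.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    matrix = np.asarray(presence)
    if genome_ids is None:
        genome_ids = [str(i) for i in range(matrix.shape[0])]
    if not np.isin(matrix, (0, 1)).all():
        raise ValueError("presence/absence matrix must be binary (0/1)")
    matrix = matrix.astype(bool)
    if matrix.shape[0] == 1:
        return {genome_ids[0]: genome_ids[0]}
    distances = _jaccard_condensed(matrix)
    linkage = scipy_cluster.hierarchy.linkage(distances, method="single")
    flat = scipy_cluster.hierarchy.fcluster(linkage, t=cut, criterion="distance")
    label_of: dict[int, str] = {}
    for cluster_id in set(flat):
        members = [genome_ids[i] for i in range(len(flat)) if flat[i] == cluster_id]
        label_of[cluster_id] = min(members)
    return {genome_ids[i]: label_of[flat[i]] for i in range(len(flat))}


def write_metrics_tsv(
    metrics: dict[str, LineageMetrics],
    markers: dict[str, set[str]],
    path: str | Path,
) -> None:
    marked = {
        (family_id, lineage)
        for lineage, families in markers.items()
        for family_id in families
    }
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["family_id", "lineage", "coverage", "specificity", "is_marker"])
        for family_id in sorted(metrics):
            for lineage in sorted(metrics[family_id].per_lineage):
                coverage, specificity = metrics[family_id].per_lineage[lineage]
                writer.writerow(
                    [family_id, lineage, f"{coverage:.6g}", f"{specificity:.6g}",
                     int((family_id, lineage) in marked)]
                )
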