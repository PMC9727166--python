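"""Pairwise local alignment and database search.

This is the shared engine behind clustering, the novelty cascade, family
extension, overlap tests and AAI.  Alignment is exact Smith–Waterman under
BLOSUM62 with affine gap penalties (a gap of length *k* costs ``11 + k``, the
classic blastp default).  Statistical significance uses the Karlin–Altschul
formula

    E = K · m · n · exp(−λ · S)

with the published gapped-BLOSUM62 constants λ = 0.267 and K = 0.041, where
``m`` is the query length and ``n`` the effective database length (for a
pairwise comparison, the target length; for a database search, the total
residue count of the database).  No length corrections are applied, so E-values
are exactly reproducible from the raw score.

Identity is matches divided by alignment columns, gap columns included in the
denominator.  Coverage is the span of the local alignment on a sequence
divided by that sequence's length.  The unknown residue ``X`` scores 0 against
everything, so it can neither create nor destroy a match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "KA_LAMBDA",
    "KA_K",
    "AlignmentResult",
    "SequenceDatabase",
    "align_local",
    "search",
    "compute_aai",
    "write_hits_tsv",
]

KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11   # charged once per gap
GAP_EXTEND = 1  # charged per gapped residue (a length-1 gap costs 12)

#: k-mer length of the search prefilter; a target is skipped only when it
#: shares no k-mer of this length with the query.
PREFILTER_K = 4


def _scoring_matrix():
    matrix = substitution_matrices.load("BLOSUM62")
    index = {letter: i for i, letter in enumerate(matrix.alphabet)}
    x = index["X"]
    for letter in matrix.alphabet:
        matrix[x, index[letter]] = 0.0
        matrix[index[letter], x] = 0.0
    return matrix


_MATRIX = _scoring_matrix()


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def evalue_from_score(raw_score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw_score)


def bitscore_from_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


@dataclass(frozen=True)
class AlignmentResult:
    """One query→target local alignment with its derived statistics."""

    query_id: str
    target_id: str
    raw_score: float
    bitscore: float
    evalue: float
    identity: float
    query_coverage: float
    target_coverage: float
    alignment_length: int
    n_identical: int

    def significant(self, max_evalue: float, min_query_cov: float = 0.0,
                    min_identity: float = 0.0) -> bool:
        return (
            self.evalue <= max_evalue
            and self.query_coverage >= min_query_cov
            and self.identity >= min_identity
        )


def align_local(
    query: str,
    target: str,
    *,
    query_id: str = "query",
    target_id: str = "target",
    db_length: int | None = None,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    ``db_length`` overrides the effective database length ``n`` in the E-value
    (defaults to the target length, the pairwise convention).
    """
    if not query or not target:
        raise ValueError("align_local requires non-empty sequences")
    n = db_length if db_length is not None else len(target)
    alignments = _ALIGNER.align(query, target)
    score = alignments.score
    if score <= 0:
        # no positive-scoring local alignment: report an empty alignment
        return AlignmentResult(
            query_id=query_id, target_id=target_id, raw_score=0.0,
            bitscore=bitscore_from_score(0.0),
            evalue=evalue_from_score(0.0, len(query), n),
            identity=0.0, query_coverage=0.0, target_coverage=0.0,
            alignment_length=0, n_identical=0,
        )
    alignment = alignments[0]
    counts = alignment.counts()
    columns = len(alignment[0])
    identical = counts.identities
    q_blocks, t_blocks = alignment.aligned
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        raw_score=float(score),
        bitscore=bitscore_from_score(float(score)),
        evalue=evalue_from_score(float(score), len(query), n),
        identity=identical / columns,
        query_coverage=q_span / len(query),
        target_coverage=t_span / len(target),
        alignment_length=columns,
        n_identical=identical,
    )


def _kmers(sequence: str, k: int = PREFILTER_K) -> frozenset[str]:
    return frozenset(
        sequence[i : i + k]
        for i in range(len(sequence) - k + 1)
        if "X" not in sequence[i : i + k]
    )


class SequenceDatabase:
    """A searchable protein collection with a shared-k-mer prefilter.

    The prefilter only ever skips a target that shares no length-4
    subsequence with the query; any target with a plausibly significant
    alignment (identity ≥ 0.3 over half the query) shares many.
    """

    def __init__(self, sequences: dict[str, str], name: str = "db"):
        if not sequences:
            raise ValueError(f"database {name!r} is empty")
        self.name = name
        self.sequences = dict(sequences)
        self.total_residues = sum(len(s) for s in self.sequences.values())
        self._kmer_sets = {tid: _kmers(seq) for tid, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def candidates(self, query: str) -> list[str]:
        query_kmers = _kmers(query)
        return [
            tid
            for tid in self.sequences
            if not query_kmers.isdisjoint(self._kmer_sets[tid])
        ]

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "SequenceDatabase":
        from .io import read_fasta

        return cls(read_fasta(path), name=name or Path(path).stem)


def search(
    query: str,
    database: SequenceDatabase,
    max_evalue: float,
    min_query_cov: float = 0.0,
    min_identity: float = 0.0,
    *,
    query_id: str = "query",
    prefilter: bool = True,
) -> list[AlignmentResult]:
    """All database targets passing the thresholds, best first.

    E-values use ``n`` = total residue count of the database.  Hits are sorted
    by ascending E-value, then descending raw score, then target id.
    """
    target_ids = database.candidates(query) if prefilter else list(database.sequences)
    hits = []
    for target_id in target_ids:
        # score-only pass first: the E-value depends only on the raw score,
        # so targets that cannot reach max_evalue skip the traceback
        score = _ALIGNER.score(query, database.sequences[target_id])
        if evalue_from_score(score, len(query), database.total_residues) > max_evalue:
            continue
        result = align_local(
            query,
            database.sequences[target_id],
            query_id=query_id,
            target_id=target_id,
            db_length=database.total_residues,
        )
        if result.significant(max_evalue, min_query_cov, min_identity):
            hits.append(result)
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.target_id))
    return hits


def compute_aai(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    *,
    max_evalue: float = 1e-3,
    min_identity: float = 0.30,
    min_query_cov: float = 0.50,
) -> tuple[float | None, int]:
    """Average amino-acid identity over reciprocal best hits.

    Best hits are computed in both directions under the stated thresholds; a
    pair is orthologous when each sequence is the other's best hit.  Returns
    ``(mean identity, number of pairs)``; the identity is ``None`` when no
    pair qualifies (AAI undefined).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("compute_aai requires non-empty proteomes")
    db_b = SequenceDatabase(proteome_b, name="b")
    db_a = SequenceDatabase(proteome_a, name="a")

    def best_hits(queries: dict[str, str], db: SequenceDatabase) -> dict[str, AlignmentResult]:
        best: dict[str, AlignmentResult] = {}
        for qid, seq in queries.items():
            hits = search(
                seq, db, max_evalue, min_query_cov, min_identity, query_id=qid
            )
            if hits:
                best[qid] = hits[0]
        return best

    forward = best_hits(proteome_a, db_b)
    backward = best_hits(proteome_b, db_a)
    identities = []
    for qid, hit in forward.items():
        reciprocal = backward.get(hit.target_id)
        if reciprocal is not None and reciprocal.target_id == qid:
            identities.append((hit.identity + reciprocal.identity) / 2.0)
    if not identities:
        return None, 0
    return sum(identities) / len(identities), len(identities)


def write_hits_tsv(hits: list[AlignmentResult], path: str | Path) -> None:
    """Write hits as a blast-tabular-style TSV."""
    header = [
        "qseqid", "sseqid", "pident", "length", "nident",
        "rawscore", "bitscore", "evalue", "qcovs", "scovs",
    ]
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for h in hits:
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.target_id,
                        f"{100.0 * h.identity:.2f}",
                        str(h.alignment_length),
                        str(h.n_identical),
                        f"{h.raw_score:.1f}",
                        f"{h.bitscore:.2f}",
                        f"{h.evalue:.3g}",
                        f"{100.0 * h.query_coverage:.2f}",
                        f"{100.0 * h.target_coverage:.2f}",
                    ]
                )
                + "\n"
            )
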