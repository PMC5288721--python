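"""All-vs-all protein similarity search at desk scale.

An exact affine-gap Smith-Waterman (through Biopython's PairwiseAligner)
stands in for a heuristic search engine: at the scale this package targets
(thousands of proteins) exactness is affordable and removes seeding
correctness risk. What is preserved from standard practice is the
*thresholding* behaviour: hits are reported with an E-value-like statistic

    E = K * m * n * exp(-lambda * S)

with fixed, documented per-matrix constants (the gapped BLOSUM62 11/1
values lambda=0.267, K=0.041), query length m and total subject length n,
and filtered at the conventional cutoffs (1e-10 within a genome, 1e-5
across genomes). Absolute E-values are not meant to match any external
tool; the cutoffs are the contract.

A shared-k-mer prefilter skips sequence pairs with no common word of the
configured length. It is an optimisation whose soundness (no reported hit is
lost) is asserted by tests, not assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import FormatError, GenomeAnnotation, HitRecord, HitTable

__all__ = ["SearchParams", "align_pair", "all_vs_all", "best_hits"]

#: Karlin-Altschul constants per substitution matrix (gapped, open 11 extend 1)
_KA_CONSTANTS = {"BLOSUM62": (0.267, 0.041)}


@dataclass(frozen=True)
class SearchParams:
    """Alignment scoring and reporting thresholds.

    ``gap_open``/``gap_extend`` follow the usual convention where a gap of
    length g costs gap_open + g*gap_extend. The default E-value cutoffs are
    1e-10 for within-genome (paralog) searches and 1e-5 for cross-genome
    searches. ``kmer_prefilter_length`` of None disables the prefilter.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_cutoff_self: float = 1e-10
    evalue_cutoff_cross: float = 1e-5
    kmer_prefilter_length: int | None = 5

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.evalue_cutoff_self <= 0 or self.evalue_cutoff_cross <= 0:
            raise ValueError("E-value cutoffs must be > 0")
        if self.substitution_matrix not in _KA_CONSTANTS:
            raise ValueError(f"no E-value constants for {self.substitution_matrix}")

    @property
    def karlin_altschul(self) -> tuple[float, float]:
        return _KA_CONSTANTS[self.substitution_matrix]


def _make_aligner(params: SearchParams, mode: str) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.substitution_matrix).copy()
    # X is scored 0 against everything (unknown residue carries no signal)
    if "X" in matrix.alphabet:
        for aa in matrix.alphabet:
            matrix["X", aa] = 0.0
            matrix[aa, "X"] = 0.0
    aligner = Align.PairwiseAligner(scoring=None)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = mode
    if mode == "global":
        # free end gaps: protein pairs are compared over their overlap
        aligner.end_gap_score = 0.0
    return aligner


def evalue(score: float, m: int, n: int, params: SearchParams) -> float:
    """Karlin-Altschul expectation for a local alignment score."""
    lam, k = params.karlin_altschul
    return k * m * n * math.exp(-lam * score)


def _alignment_stats(alignment) -> tuple[float, int, int, int, int, int, int, int]:
    """identity%, length, mismatches, gap opens and 1-based coordinates."""
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches
    gap_cols = counts.gaps
    length = aligned_cols + gap_cols
    pid = 100.0 * counts.identities / length if length else 0.0
    gap_opens = counts.open_internal_insertions + counts.open_internal_deletions
    (t_start, t_end) = (alignment.aligned[0][0][0], alignment.aligned[0][-1][1])
    (q_start, q_end) = (alignment.aligned[1][0][0], alignment.aligned[1][-1][1])
    return pid, length, counts.mismatches, gap_opens, t_start + 1, t_end, q_start + 1, q_end


def align_pair(
    a: str,
    b: str,
    params: SearchParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    search_space: tuple[int, int] | None = None,
) -> HitRecord:
    """Optimal affine-gap local alignment of two protein sequences.

    ``search_space`` optionally gives (query length, database length) for the
    E-value; by default the two sequence lengths are used. Raises on empty
    input.
    """
    params = params or SearchParams()
    if not a or not b:
        raise FormatError("empty sequence passed to align_pair")
    aligner = _make_aligner(params, "local")
    if aligner.score(a, b) <= 0:
        raise FormatError(
            f"{query_id}/{subject_id}: no positive-scoring local alignment"
        )
    # all returned alignments are co-optimal; take the first deterministically
    alignment = aligner.align(a, b)[0]
    m, n = search_space if search_space else (len(a), len(b))
    score = alignment.score
    pid, length, mismatches, gap_opens, qs, qe, ss, se = _alignment_stats(alignment)
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=pid,
        alignment_length=length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        e_value=evalue(score, m, n, params),
        bit_score=score,
    )


def align_global(a: str, b: str, params: SearchParams | None = None) -> tuple[str, str]:
    """Global (end-gap-free) protein alignment, for codon back-translation."""
    params = params or SearchParams()
    aligner = _make_aligner(params, "global")
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def _kmer_sets(proteins: dict[str, str], k: int) -> dict[str, set[str]]:
    return {
        gid: {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for gid, seq in proteins.items()
    }


def _candidate_pairs(
    prot_a: dict[str, str],
    prot_b: dict[str, str],
    self_mode: bool,
    k: int | None,
) -> list[tuple[str, str]]:
    """Ordered unique pairs to score, optionally prefiltered by shared k-mers."""
    if self_mode:
        all_pairs = list(combinations(sorted(prot_a), 2))
    else:
        all_pairs = [(qa, qb) for qa in sorted(prot_a) for qb in sorted(prot_b)]
    if k is None:
        return all_pairs
    kmers_a = _kmer_sets(prot_a, k)
    kmers_b = kmers_a if self_mode else _kmer_sets(prot_b, k)
    # invert: k-mer -> genes, then collect co-occurring pairs
    index_a: dict[str, list[str]] = {}
    for gid, km in kmers_a.items():
        for w in km:
            index_a.setdefault(w, []).append(gid)
    shared: set[tuple[str, str]] = set()
    if self_mode:
        for gids in index_a.values():
            if len(gids) > 1:
                shared.update(combinations(sorted(gids), 2))
    else:
        for gid_b, km in kmers_b.items():
            hits = set()
            for w in km:
                hits.update(index_a.get(w, ()))
            shared.update((ga, gid_b) for ga in hits)
    return sorted(shared)


def all_vs_all(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation | None = None,
    params: SearchParams | None = None,
) -> HitTable:
    """All-vs-all protein search within one genome or between two.

    Within a genome (``ann_b`` None or identical) the self E-value cutoff
    applies, each unordered pair is scored once and reported in both
    orientations, and trivial self-hits (query == subject) are recorded so
    callers can flag them; across genomes the cross cutoff applies and hits
    are likewise reported in both orientations. A gene without a stored CDS
    is an error naming the gene.
    """
    params = params or SearchParams()
    self_mode = ann_b is None or ann_b is ann_a or ann_b.genome_id == ann_a.genome_id
    ann_b = ann_a if self_mode else ann_b

    def proteins_of(ann: GenomeAnnotation) -> dict[str, str]:
        missing = [g.gene_id for g in ann.genes if g.gene_id not in ann.cds]
        if missing:
            raise FormatError(
                f"genome {ann.genome_id}: no protein for gene {missing[0]}"
            )
        return ann.proteins()

    prot_a = proteins_of(ann_a)
    prot_b = prot_a if self_mode else proteins_of(ann_b)
    cutoff = params.evalue_cutoff_self if self_mode else params.evalue_cutoff_cross
    lam, kconst = params.karlin_altschul
    db_len = sum(len(s) for s in prot_b.values())
    aligner = _make_aligner(params, "local")

    records: list[HitRecord] = []
    pairs = _candidate_pairs(prot_a, prot_b, self_mode, params.kmer_prefilter_length)
    for qa, qb in pairs:
        sa, sb = prot_a[qa], prot_b[qb]
        score = aligner.score(sa, sb)
        e = kconst * len(sa) * db_len * math.exp(-lam * score)
        if e > cutoff:
            continue
        rec = align_pair(sa, sb, params, qa, qb, search_space=(len(sa), db_len))
        records.append(rec)
        records.append(
            HitRecord(
                query_id=qb,
                subject_id=qa,
                percent_identity=rec.percent_identity,
                alignment_length=rec.alignment_length,
                mismatches=rec.mismatches,
                gap_opens=rec.gap_opens,
                q_start=rec.s_start,
                q_end=rec.s_end,
                s_start=rec.q_start,
                s_end=rec.q_end,
                e_value=evalue(score, len(sb), db_len, params),
                bit_score=rec.bit_score,
            )
        )
    if self_mode:
        for gid in sorted(prot_a):
            seq = prot_a[gid]
            rec = align_pair(seq, seq, params, gid, gid, search_space=(len(seq), db_len))
            if rec.e_value <= cutoff:
                records.append(rec)
    return HitTable(records)


def best_hits(hits: HitTable, k: int) -> HitTable:
    """Top-k subjects per query by bit score (ties: E-value, then subject id).

    Self-hits are excluded from the ranking.
    """
    if k <= 0:
        raise ValueError("k must be a positive count")
    if len(hits) == 0:
        raise FormatError("best_hits called on an empty table")
    by_query: dict[str, list[HitRecord]] = {}
    for rec in hits.non_self():
        by_query.setdefault(rec.query_id, []).append(rec)
    out: list[HitRecord] = []
    for query in sorted(by_query):
        ranked = sorted(
            by_query[query], key=lambda r: (-r.bit_score, r.e_value, r.subject_id)
        )
        out.extend(ranked[:k])
    return HitTable(out)
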