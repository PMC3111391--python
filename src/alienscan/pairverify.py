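"""Full-contig overlap verification of candidate pairs.

A candidate comparison only certifies a shared >=100 bp block. Truly
identical-by-descent contigs must agree over their *entire* mutual overlap:
each pair is aligned end-gap-free (overlap/dovetail global alignment, match
+1, mismatch -2, gap -4, N mismatching everything) and accepted only with
zero mismatches, zero internal gaps, and flush ends.

The accepted verdict is decided canonically, independent of alignment
traceback: a pair is accepted iff some ungapped flush overlay with zero
mismatches attains the optimal alignment score. Rejected pairs get their
mismatch/gap counts from the optimal alignment path.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _dna
from .errors import DataIntegrityError, ParameterError
from .seqio import Contig

__all__ = [
    "Verdict",
    "PairAlignment",
    "CandidateSummary",
    "overlap_align",
    "align_comparisons",
    "verify_comparisons",
    "summarize_candidates",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_SCORE = -4


class Verdict(str, Enum):
    accepted = "accepted"
    rejected_mismatch = "rejected_mismatch"
    rejected_gap = "rejected_gap"
    rejected_nonextension = "rejected_nonextension"


@dataclass(frozen=True)
class PairAlignment:
    """Verdict record for one query/subject contig pair."""

    query_id: str
    subject_id: str
    strand: str
    overlap_len: int  # aligned residue pairs (matches + mismatches)
    n_mismatch: int
    n_internal_gap: int
    flush_left: bool
    flush_right: bool
    score: float
    verdict: Verdict


@dataclass(frozen=True)
class CandidateSummary:
    """Aggregate statistics over the accepted inter-genotype contig pairs."""

    n_accepted_pairs: int
    n_unique_query: int
    n_unique_subject: int
    mean_overlap: Optional[float]
    min_overlap: Optional[int]
    max_overlap: Optional[int]
    mean_read_count: Optional[float] = None

    @property
    def mean_overlap_bp(self) -> Optional[int]:
        """Mean overlap rounded to the nearest integer bp."""
        return None if self.mean_overlap is None else round(self.mean_overlap)


def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            mat[x, y] = MATCH_SCORE if (x == y and x != "N") else MISMATCH_SCORE
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    try:  # attribute names changed across Biopython releases
        aligner.open_internal_gap_score = GAP_SCORE
        aligner.extend_internal_gap_score = GAP_SCORE
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.internal_open_gap_score = GAP_SCORE
        aligner.internal_extend_gap_score = GAP_SCORE
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _best_perfect_overlay(a: str, b: str) -> tuple[int, int]:
    """Longest zero-mismatch ungapped flush overlay of a and b.

    Returns (overlap_len, a_start_offset_of_b) for the best overlay, or
    (0, 0) when none exists. N never matches.
    """
    best = (0, 0)
    for shift in range(-(len(b) - 1), len(a)):
        a_lo = max(0, shift)
        a_hi = min(len(a), shift + len(b))
        if a_hi <= a_lo:
            continue
        a_sub = a[a_lo:a_hi]
        b_sub = b[a_lo - shift : a_hi - shift]
        if a_sub == b_sub and "N" not in a_sub:
            if a_hi - a_lo > best[0]:
                best = (a_hi - a_lo, shift)
    return best


def overlap_align(a: str, b: str, strand: str = "+") -> PairAlignment:
    """Optimal end-gap-free overlap alignment of two contig sequences.

    ``b`` is reverse-complemented first when strand is '-'. The returned
    record carries ids "a"/"b"; :func:`align_comparisons` substitutes real
    contig ids.
    """
    if not a or not b:
        raise ParameterError("cannot align empty sequences")
    if strand not in "+-":
        raise ParameterError("strand must be '+' or '-'")
    b_oriented = _dna.revcomp(b) if strand == "-" else b
    score = _ALIGNER.score(a, b_oriented)

    perfect_len, _ = _best_perfect_overlay(a, b_oriented)
    if perfect_len > 0 and perfect_len * MATCH_SCORE >= score:
        # a zero-mismatch flush overlay is optimal -> accepted
        return PairAlignment(
            query_id="a",
            subject_id="b",
            strand=strand,
            overlap_len=perfect_len,
            n_mismatch=0,
            n_internal_gap=0,
            flush_left=True,
            flush_right=True,
            score=float(perfect_len * MATCH_SCORE),
            verdict=Verdict.accepted,
        )

    aln = _ALIGNER.align(a, b_oriented)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return PairAlignment(
            query_id="a",
            subject_id="b",
            strand=strand,
            overlap_len=0,
            n_mismatch=0,
            n_internal_gap=0,
            flush_left=False,
            flush_right=False,
            score=float(score),
            verdict=Verdict.rejected_nonextension,
        )
    pairs = 0
    mism = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        pairs += ae - as_
        for x, y in zip(a[as_:ae], b_oriented[bs:be]):
            if x != y or x == "N":
                mism += 1
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    internal_gaps = (span_a - pairs) + (span_b - pairs)
    flush_left = blocks_a[0][0] == 0 or blocks_b[0][0] == 0
    flush_right = blocks_a[-1][1] == len(a) or blocks_b[-1][1] == len(b_oriented)
    if mism > 0:
        verdict = Verdict.rejected_mismatch
    elif internal_gaps > 0:
        verdict = Verdict.rejected_gap
    else:
        verdict = Verdict.rejected_nonextension
    return PairAlignment(
        query_id="a",
        subject_id="b",
        strand=strand,
        overlap_len=pairs,
        n_mismatch=mism,
        n_internal_gap=internal_gaps,
        flush_left=flush_left,
        flush_right=flush_right,
        score=float(score),
        verdict=verdict,
    )


def _index_library(lib: Sequence[Contig]) -> Mapping[str, Contig]:
    return {c.contig_id: c for c in lib}


def align_comparisons(
    comparisons: Iterable,
    library_a: Sequence[Contig],
    library_b: Sequence[Contig],
) -> list[PairAlignment]:
    """Align each candidate query/subject pair once, with verdicts.

    Pairs reported by several distinct hits are deduplicated on the
    unordered id pair; when hits exist on both strands the best-scoring
    strand is kept ('+' on ties). Deterministic order (query_id, subject_id).
    """
    a_idx = _index_library(library_a)
    b_idx = _index_library(library_b)
    strands: dict[tuple[str, str], set[str]] = {}
    for comp in comparisons:
        hit = getattr(comp, "hit", comp)
        key = (hit.query_id, hit.subject_id)
        if hit.query_id not in a_idx:
            raise DataIntegrityError(f"unknown query contig {hit.query_id!r}")
        if hit.subject_id not in b_idx:
            raise DataIntegrityError(f"unknown subject contig {hit.subject_id!r}")
        strands.setdefault(key, set()).add(hit.strand)
    out: list[PairAlignment] = []
    for (qid, sid) in sorted(strands):
        cand = []
        for strand in sorted(strands[(qid, sid)]):  # '+' before '-'
            pa = overlap_align(a_idx[qid].sequence, b_idx[sid].sequence, strand)
            cand.append(pa)
        best = max(cand, key=lambda p: (p.score, p.strand == "+"))
        out.append(
            PairAlignment(
                query_id=qid,
                subject_id=sid,
                strand=best.strand,
                overlap_len=best.overlap_len,
                n_mismatch=best.n_mismatch,
                n_internal_gap=best.n_internal_gap,
                flush_left=best.flush_left,
                flush_right=best.flush_right,
                score=best.score,
                verdict=best.verdict,
            )
        )
    return out


def verify_comparisons(
    comparisons: Iterable,
    library_a: Sequence[Contig],
    library_b: Sequence[Contig],
) -> list[PairAlignment]:
    """Accepted inter-genotype contig pairs (zero mismatch, zero gap, flush)."""
    return [
        pa
        for pa in align_comparisons(comparisons, library_a, library_b)
        if pa.verdict is Verdict.accepted
    ]


def summarize_candidates(
    accepted: Sequence[PairAlignment],
    read_counts: Optional[Mapping[str, int]] = None,
) -> CandidateSummary:
    """Exact arithmetic summary of the accepted pairs.

    ``read_counts`` optionally maps contig ids to read counts; the mean is
    taken over all pair members that have one.
    """
    if not accepted:
        return CandidateSummary(0, 0, 0, None, None, None, None)
    overlaps = [p.overlap_len for p in accepted]
    mean_rc = None
    if read_counts:
        vals = [
            read_counts[cid]
            for p in accepted
            for cid in (p.query_id, p.subject_id)
            if cid in read_counts and read_counts[cid] is not None
        ]
        if vals:
            mean_rc = float(np.mean(vals))
    return CandidateSummary(
        n_accepted_pairs=len(accepted),
        n_unique_query=len({p.query_id for p in accepted}),
        n_unique_subject=len({p.subject_id for p in accepted}),
        mean_overlap=float(np.mean(overlaps)),
        min_overlap=int(min(overlaps)),
        max_overlap=int(max(overlaps)),
        mean_read_count=mean_rc,
    )
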