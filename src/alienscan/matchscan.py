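"""Candidate identical-by-descent pair detection.

Finds every maximal exact common substring of length >= L between two contig
libraries (both strands), scores each with ungapped Karlin-Altschul
statistics, and filters by E-value / identity / length. Matches are located
by shared-k-mer seeding with k = min_len: any common substring of length >=
min_len contains at least one shared window of exactly min_len on its
diagonal, and maximal extension from any such seed recovers the same
maximal match, so the enumeration is exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import _dna
from .errors import ParameterError
from .seqio import Contig, MatchHit, PipelineConfig, ScoringParams

__all__ = [
    "find_exact_matches",
    "karlin_altschul_evalue",
    "filter_candidate_pairs",
    "CandidateComparison",
    "ScanSummary",
    "FilterResult",
    "mask_low_complexity",
]


def karlin_altschul_evalue(score: float, params: ScoringParams) -> float:
    """Expected number of chance local matches scoring >= S.

    E = K * m * n * exp(-lambda * S). Strictly decreasing in S; underflows
    to 0.0 for very high scores, which is harmless for thresholding.
    """
    if params.m <= 0 or params.n <= 0:
        raise ParameterError("effective lengths m and n must be positive")
    log_e = (
        math.log(params.k_const)
        + math.log(params.m)
        + math.log(params.n)
        - params.lambda_ * score
    )
    try:
        return math.exp(log_e)
    except OverflowError:
        return math.inf


def mask_low_complexity(seq: str, min_run: int = 12) -> str:
    """Mask homopolymer and dinucleotide repeats of >= min_run bp with N.

    A deliberately simple stand-in for BLAST's dust filter, available behind
    a flag for sensitivity analysis of the primary scan.
    """
    n = len(seq)
    out = list(seq)
    for period in (1, 2):
        i = 0
        while i + period < n:
            j = i + period
            while j < n and seq[j] == seq[j - period]:
                j += 1
            run = j - i
            if run >= min_run:
                for k in range(i, j):
                    out[k] = "N"
            i = max(i + 1, j - period + 1)
    return "".join(out)


def _maximal_matches_forward(
    qseq: str, sseq: str, min_len: int
) -> set[tuple[int, int, int]]:
    """All maximal exact common substrings >= min_len as (qstart, sstart, length).

    Plain forward-orientation comparison; N never matches (windows containing
    N are skipped and extension stops at N).
    """
    out: set[tuple[int, int, int]] = set()
    if len(qseq) < min_len or len(sseq) < min_len:
        return out
    index: dict[str, list[int]] = {}
    for p in range(len(sseq) - min_len + 1):
        w = sseq[p : p + min_len]
        if "N" in w:
            continue
        index.setdefault(w, []).append(p)
    if not index:
        return out
    seen_diag: set[tuple[int, int]] = set()  # (diagonal, extended qstart)
    for q in range(len(qseq) - min_len + 1):
        w = qseq[q : q + min_len]
        positions = index.get(w)
        if not positions:
            continue
        for p in positions:
            diag = q - p
            # extend left
            i, j = q - 1, p - 1
            while i >= 0 and j >= 0 and qseq[i] == sseq[j] and qseq[i] != "N":
                i -= 1
                j -= 1
            qs, ps = i + 1, j + 1
            key = (diag, qs)
            if key in seen_diag:
                continue
            # extend right
            i, j = q + min_len, p + min_len
            while (
                i < len(qseq) and j < len(sseq) and qseq[i] == sseq[j] and qseq[i] != "N"
            ):
                i += 1
                j += 1
            seen_diag.add(key)
            out.add((qs, ps, i - qs))
    return out


def find_exact_matches(
    queries: Sequence[Contig],
    subjects: Sequence[Contig],
    min_len: int,
    params: ScoringParams | None = None,
    mask: bool = False,
) -> list[MatchHit]:
    """Every maximal exact common substring >= min_len, both strands.

    Hits carry identity 1.0, score = length * reward, and a Karlin-Altschul
    E-value computed with m = query length and n = total subject-library
    length. Deterministic order: (query_id, subject_id, qstart, strand).
    """
    if min_len < 1:
        raise ParameterError("min_len must be >= 1")
    params = params or ScoringParams()
    total_n = sum(len(s) for s in subjects)
    hits: list[MatchHit] = []
    sub_seqs = []
    for s in subjects:
        seq = mask_low_complexity(s.sequence) if mask else s.sequence
        sub_seqs.append((s, seq, _dna.revcomp(seq)))
    for qc in queries:
        qseq = mask_low_complexity(qc.sequence) if mask else qc.sequence
        p = ScoringParams(
            reward=params.reward,
            penalty=params.penalty,
            lambda_=params.lambda_,
            k_const=params.k_const,
            m=len(qc.sequence),
            n=max(total_n, 1),
        )
        for sc, fwd, rev in sub_seqs:
            for strand, sseq in (("+", fwd), ("-", rev)):
                for qs, ps, length in _maximal_matches_forward(qseq, sseq, min_len):
                    if strand == "+":
                        sstart, send = ps, ps + length
                    else:
                        sstart, send = len(sc) - (ps + length), len(sc) - ps
                    score = float(length * params.reward)
                    hits.append(
                        MatchHit(
                            query_id=qc.contig_id,
                            subject_id=sc.contig_id,
                            qstart=qs,
                            qend=qs + length,
                            sstart=sstart,
                            send=send,
                            strand=strand,
                            length=length,
                            identity=1.0,
                            score=score,
                            evalue=karlin_altschul_evalue(score, p),
                        )
                    )
    hits.sort(key=lambda h: (h.query_id, h.subject_id, h.qstart, h.strand, h.sstart))
    return hits


@dataclass(frozen=True)
class CandidateComparison:
    """One retained query/subject match — the unit the paper calls a comparison."""

    hit: MatchHit

    @property
    def query_id(self) -> str:
        return self.hit.query_id

    @property
    def subject_id(self) -> str:
        return self.hit.subject_id


@dataclass(frozen=True)
class ScanSummary:
    n_comparisons: int
    n_unique_queries: int
    n_unique_subjects: int


@dataclass(frozen=True)
class FilterResult:
    comparisons: list[CandidateComparison]
    summary: ScanSummary


def filter_candidate_pairs(
    hits: Iterable[MatchHit], config: PipelineConfig
) -> FilterResult:
    """Apply the primary identity / length / E-value filter.

    Keeps hits with identity >= min_identity, length >= min_exact_len and
    evalue <= e_threshold_primary. A query-subject pair may yield several
    comparisons through distinct hits; distinct query and subject contig
    counts are reported alongside.
    """
    comparisons = [
        CandidateComparison(hit=h)
        for h in hits
        if h.identity >= config.min_identity
        and h.length >= config.min_exact_len
        and h.evalue <= config.e_threshold_primary
    ]
    summary = ScanSummary(
        n_comparisons=len(comparisons),
        n_unique_queries=len({c.query_id for c in comparisons}),
        n_unique_subjects=len({c.subject_id for c in comparisons}),
    )
    return FilterResult(comparisons=comparisons, summary=summary)
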