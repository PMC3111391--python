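"""Readers/writers for the pipeline's standard formats, plus shared config.

FASTA goes through Biopython; the tabular hit format is the conventional
12-column BLAST ``outfmt 6`` dialect (1-based inclusive coordinates,
minus-strand subject hits written with sstart > send). Internally all
coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import _dna
from .errors import FastaParseError, ParameterError

_READCOUNT_X = re.compile(r"_x(\d+)(?:\b|_|$)")
_READCOUNT_NUMREADS = re.compile(r"numreads=(\d+)")


@dataclass(frozen=True)
class Contig:
    """One assembled transcript fragment — the unit compared across genotypes."""

    contig_id: str
    library_id: str
    sequence: str
    read_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"contig {self.contig_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringParams:
    """Ungapped match/mismatch scoring with Karlin-Altschul statistics.

    Defaults (reward +1, penalty -2, lambda 1.28 nats, K 0.46) are the
    standard ungapped values for +1/-2 nucleotide scoring, the regime the
    primary E-value cutoff was applied in. ``m`` is the effective query
    length and ``n`` the effective database length in bp.
    """

    reward: int = 1
    penalty: int = -2
    lambda_: float = 1.28
    k_const: float = 0.46
    m: int = 0
    n: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ParameterError("lambda and K must be positive")
        if not (self.reward > 0 > self.penalty):
            raise ParameterError("need reward > 0 > penalty")


@dataclass
class PipelineConfig:
    """Thresholds for every stage of the comparison strategy.

    The primary scan keeps perfect matches of at least ``min_exact_len`` bp
    whose Karlin-Altschul E-value is at most ``e_threshold_primary``; the
    uniqueness screen uses the looser ``e_threshold_uniqueness``. Marker
    design constrains amplicon size and primer-tag geometry; ``fdr_level``
    applies to the two-library term comparison.
    """

    min_exact_len: int = 100
    min_identity: float = 1.0
    e_threshold_primary: float = 1e-100
    e_threshold_uniqueness: float = 1e-25
    scoring: ScoringParams = field(default_factory=ScoringParams)
    amplicon_size_range: tuple[int, int] = (100, 450)
    primer_tag_len: int = 20
    pcr_3prime_exact: int = 15
    pcr_max_other_mismatches: int = 2
    pcr_product_range: tuple[int, int] = (50, 2000)
    fdr_level: float = 0.01

    def __post_init__(self) -> None:
        if self.min_exact_len < 1:
            raise ParameterError("min_exact_len must be >= 1")
        if not (0.0 < self.min_identity <= 1.0):
            raise ParameterError("min_identity must be in (0, 1]")
        for name in ("e_threshold_primary", "e_threshold_uniqueness", "fdr_level"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        lo, hi = self.amplicon_size_range
        if not (0 < lo <= hi):
            raise ParameterError("invalid amplicon_size_range")
        if self.pcr_3prime_exact > self.primer_tag_len:
            raise ParameterError("pcr_3prime_exact cannot exceed primer_tag_len")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "scoring" in d:
            d["scoring"] = ScoringParams(**d["scoring"])
        for key in ("amplicon_size_range", "pcr_product_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class MatchHit:
    """A maximal exact (or near-exact) local match between two contigs.

    Coordinates are 0-based half-open on the forward strand of each contig;
    ``strand`` is the subject strand. ``score`` is in raw score units of the
    scoring scheme that produced the hit.
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    length: int
    identity: float
    score: float
    evalue: float
    mismatches: int = 0
    gapopens: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParameterError("strand must be '+' or '-'")
        if self.length != self.qend - self.qstart:
            raise ParameterError("length must equal qend - qstart (half-open)")
        if not (0.0 <= self.identity <= 1.0):
            raise ParameterError("identity must be in [0, 1]")


def _parse_read_count(header: str) -> Optional[int]:
    first = header.split()[0] if header.split() else header
    m = _READCOUNT_X.search(first)
    if m:
        return int(m.group(1))
    m = _READCOUNT_NUMREADS.search(header)
    if m:
        return int(m.group(1))
    return None


def read_fasta(path: str | Path, library_id: Optional[str] = None) -> list[Contig]:
    """Read a contig library from FASTA.

    Record ids are the first whitespace-delimited header token; sequences are
    upper-cased with every non-ACGT character collapsed to N. A read count is
    parsed from a ``_x<N>`` id suffix or a ``numreads=<N>`` header token when
    present. An empty file yields an empty list; text before the first header
    is a parse error naming the line.
    """
    path = Path(path)
    lib = library_id if library_id is not None else path.stem
    with open(path) as fh:
        # reject leading junk with a line number; Biopython would silently skip
        pos = fh.tell()
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line.strip()[:40]!r}"
                )
            break
        fh.seek(pos)
        contigs = []
        seen: set[str] = set()
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else header
            if not seq:
                raise FastaParseError(f"{path}: record {name!r} has an empty sequence")
            if name in seen:
                raise FastaParseError(f"{path}: duplicate contig id {name!r}")
            seen.add(name)
            contigs.append(
                Contig(
                    contig_id=name,
                    library_id=lib,
                    sequence=_dna.normalize(seq),
                    read_count=_parse_read_count(header),
                )
            )
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, wrap: int = 70) -> None:
    """Write contigs as FASTA wrapped at ``wrap`` columns (deterministic bytes)."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id}")
            if c.read_count is not None:
                fh.write(f" numreads={c.read_count}")
            fh.write("\n")
            for i in range(0, len(c.sequence), wrap):
                fh.write(c.sequence[i : i + wrap] + "\n")


def bitscore(score: float, params: ScoringParams) -> float:
    """Normalized bit score S' = (lambda*S - ln K) / ln 2."""
    return (params.lambda_ * score - math.log(params.k_const)) / math.log(2.0)


def write_hits_tabular(hits: Iterable[MatchHit], path: str | Path,
                       params: Optional[ScoringParams] = None) -> None:
    """Write hits in the 12-column tab-separated BLAST outfmt-6 dialect.

    Columns: qid, sid, %identity, length, mismatches, gapopens, qstart, qend,
    sstart, send, evalue, bitscore. Coordinates are converted to 1-based
    inclusive; minus-strand subject coordinates are written descending.
    """
    params = params or ScoringParams()
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                s1, s2 = h.sstart + 1, h.send
            else:
                s1, s2 = h.send, h.sstart + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity * 100:.2f}",
                        str(h.length),
                        str(h.mismatches),
                        str(h.gapopens),
                        str(h.qstart + 1),
                        str(h.qend),
                        str(s1),
                        str(s2),
                        repr(h.evalue),
                        f"{bitscore(h.score, params):.6g}",
                    ]
                )
                + "\n"
            )


def read_hits_tabular(path: str | Path,
                      params: Optional[ScoringParams] = None) -> list[MatchHit]:
    """Read hits written by :func:`write_hits_tabular` back losslessly.

    The raw score is reconstructed from length/mismatch counts under the
    ungapped scoring scheme, which is exact for the hits this package emits.
    """
    params = params or ScoringParams()
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ParameterError(f"{path}: line {lineno}: expected 12 columns")
            length = int(f[3])
            mism = int(f[4])
            s1, s2 = int(f[8]), int(f[9])
            if s1 <= s2:
                strand, sstart, send = "+", s1 - 1, s2
            else:
                strand, sstart, send = "-", s2 - 1, s1
            score = params.reward * (length - mism) + params.penalty * mism
            hits.append(
                MatchHit(
                    query_id=f[0],
                    subject_id=f[1],
                    qstart=int(f[6]) - 1,
                    qend=int(f[7]),
                    sstart=sstart,
                    send=send,
                    strand=strand,
                    length=length,
                    identity=float(f[2]) / 100.0,
                    score=float(score),
                    evalue=float(f[10]),
                    mismatches=mism,
                    gapopens=int(f[5]),
                )
            )
    return hits
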