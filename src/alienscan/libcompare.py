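"""Two-library annotation-term comparison.

For each term the 2x2 table (term / not-term x library A / library B) is
tested with a two-sided Fisher's exact test (the "probability <= observed"
convention) and the p-values are adjusted with the Benjamini-Hochberg
step-up procedure across all terms. Works on arbitrary term-count tables;
term ids in GO:NNNNNNN format are validated syntactically but not resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import DataIntegrityError, ParameterError

__all__ = [
    "TermCountTable",
    "EnrichmentRow",
    "fisher_exact_two_sided",
    "compare_term_libraries",
]

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass(frozen=True)
class TermCountTable:
    """Per-term annotation counts for two libraries plus library totals."""

    rows: tuple[tuple[str, str, int, int], ...]  # (term_id, label, count_a, count_b)
    total_a: int
    total_b: int

    def __post_init__(self) -> None:
        if self.total_a <= 0 or self.total_b <= 0:
            raise ParameterError("library totals must be positive")
        for term_id, _, a, b in self.rows:
            if a < 0 or b < 0:
                raise ParameterError(f"negative count for term {term_id!r}")
            if a > self.total_a or b > self.total_b:
                raise ParameterError(f"count exceeds library total for {term_id!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, total_a: int, total_b: int) -> "TermCountTable":
        rows = tuple(
            (str(r.term_id), str(getattr(r, "label", "")), int(r.count_a), int(r.count_b))
            for r in df.itertuples(index=False)
        )
        return cls(rows=rows, total_a=total_a, total_b=total_b)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TermCountTable":
        """TSV with columns term_id, label, count_a, count_b and a required
        leading comment line '# totals: <A> <B>'."""
        with open(path) as fh:
            first = fh.readline()
            m = re.match(r"#\s*totals:\s*(\d+)\s+(\d+)", first)
            if not m:
                raise ParameterError(f"{path}: missing '# totals: A B' header line")
            df = pd.read_csv(fh, sep="\t")
        return cls.from_frame(df, int(m.group(1)), int(m.group(2)))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# totals: {self.total_a} {self.total_b}\n")
            fh.write("term_id\tlabel\tcount_a\tcount_b\n")
            for term_id, label, a, b in self.rows:
                fh.write(f"{term_id}\t{label}\t{a}\t{b}\n")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    label: str
    a: int  # term, library A
    b: int  # term, library B
    c: int  # not-term, library A
    d: int  # not-term, library B
    p: float
    q: float
    direction: str  # over | under (relative frequency in A vs B)
    significant: bool


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sum of hypergeometric probabilities over all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ParameterError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ParameterError("all-zero table")
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return min(p, 1.0)


def validate_term_id(term_id: str) -> bool:
    """Syntactic check for GO:NNNNNNN ids; other id schemes pass unchecked."""
    if term_id.startswith("GO:"):
        return bool(_GO_RE.match(term_id))
    return True


def compare_term_libraries(
    table: TermCountTable, fdr_level: Optional[float] = None
) -> list[EnrichmentRow]:
    """Fisher + Benjamini-Hochberg comparison of every term.

    One test per term against the library totals; rows with q <= fdr_level
    are flagged. direction is 'over' when the term's relative frequency in
    library A exceeds that in library B. Input row order is preserved.
    """
    fdr = 0.01 if fdr_level is None else fdr_level
    if not (0 < fdr < 1):
        raise ParameterError("fdr_level must be in (0, 1)")
    ids = [r[0] for r in table.rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({t for t in ids if ids.count(t) > 1})
        raise DataIntegrityError(f"duplicate term ids: {dupes}")
    if not table.rows:
        return []
    pvals = []
    for term_id, _, a, b in table.rows:
        c = table.total_a - a
        d = table.total_b - b
        pvals.append(fisher_exact_two_sided(a, b, c, d))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for (term_id, label, a, b), p, q in zip(table.rows, pvals, qvals):
        c = table.total_a - a
        d = table.total_b - b
        freq_a = a / table.total_a
        freq_b = b / table.total_b
        out.append(
            EnrichmentRow(
                term_id=term_id,
                label=label,
                a=a,
                b=b,
                c=c,
                d=d,
                p=float(p),
                q=float(q),
                direction="over" if freq_a > freq_b else "under",
                significant=bool(q <= fdr),
            )
        )
    return out


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
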