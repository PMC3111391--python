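"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (enumeration, quadratic scans, full
dynamic programming) and shares no code with the package internals.
"""

from __future__ import annotations

import math
from fractions import Fraction


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


# --------------------------------------------------------------------------
# all maximal common substrings, quadratic diagonal walk
# --------------------------------------------------------------------------


def maximal_common_substrings(a: str, b: str, min_len: int):
    """All (a_start, b_start, length) maximal exact runs >= min_len.

    N never matches anything. Plain per-diagonal walk, O(len(a)*len(b)).
    """
    out = []
    for diag in range(-(len(b) - 1), len(a)):
        i = max(0, diag)
        j = i - diag
        run = 0
        while i < len(a) and j < len(b):
            if a[i] == b[j] and a[i] != "N":
                run += 1
            else:
                if run >= min_len:
                    out.append((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
        if run >= min_len:
            out.append((i - run, j - run, run))
    return out


def exact_match_hits(queries, subjects, min_len):
    """Expected hit tuples for find_exact_matches, via the quadratic walk.

    Returns a set of (query_id, subject_id, strand, qstart, qend, sstart,
    send) with subject coordinates on the forward strand.
    """
    expected = set()
    for q in queries:
        for s in subjects:
            for strand in "+-":
                sseq = s.sequence if strand == "+" else revcomp(s.sequence)
                for qs, ps, ln in maximal_common_substrings(q.sequence, sseq, min_len):
                    if strand == "+":
                        ss, se = ps, ps + ln
                    else:
                        ss, se = len(s.sequence) - (ps + ln), len(s.sequence) - ps
                    expected.add((q.contig_id, s.contig_id, strand, qs, qs + ln, ss, se))
    return expected


# --------------------------------------------------------------------------
# full overlap-alignment DP (free end gaps), match +1 / mismatch -2 / gap -4
# --------------------------------------------------------------------------


def overlap_dp_score(a: str, b: str, match=1, mismatch=-2, gap=-4) -> float:
    """Optimal end-gap-free global alignment score by full DP."""
    n, m = len(a), len(b)
    prev = [0.0] * (m + 1)
    best_last_col = 0.0 if n == 0 else -math.inf
    for i in range(1, n + 1):
        cur = [0.0] + [-math.inf] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if (ai == b[j - 1] and ai != "N") else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        best_last_col = max(best_last_col, cur[m])
        prev = cur
    return max(max(prev), best_last_col, 0.0)


def best_perfect_overlap(a: str, b: str) -> int:
    """Longest zero-mismatch ungapped flush overlay length (0 if none)."""
    best = 0
    for shift in range(-(len(b) - 1), len(a)):
        lo, hi = max(0, shift), min(len(a), shift + len(b))
        if hi <= lo:
            continue
        ok = True
        for k in range(lo, hi):
            x, y = a[k], b[k - shift]
            if x != y or x == "N":
                ok = False
                break
        if ok:
            best = max(best, hi - lo)
    return best


def overlap_verdict(a: str, b: str) -> tuple[bool, float, int]:
    """(accepted, optimal score, perfect overlap length) for a pair.

    Accepted iff a zero-mismatch flush ungapped overlay attains the optimal
    end-gap-free alignment score.
    """
    score = overlap_dp_score(a, b)
    perfect = best_perfect_overlap(a, b)
    return (perfect > 0 and perfect >= score), score, perfect


# --------------------------------------------------------------------------
# Fisher's exact test by full table enumeration
# --------------------------------------------------------------------------


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p by exact enumeration of all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(k: int) -> Fraction:
        # P(X = k) for hypergeometric with margins (r1, r2, c1)
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    p_obs = table_prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = table_prob(k)
        # float-tolerant "<=" like common implementations
        if p_k <= p_obs * Fraction(10_000_001, 10_000_000):  # 1 + 1e-7
            total += p_k
    return float(min(total, Fraction(1)))


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the direct step-up formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


# --------------------------------------------------------------------------
# in-silico PCR site scan, brute force
# --------------------------------------------------------------------------


def pcr_products_bruteforce(fwd, rev, template, three_exact, max_mm, size_range):
    """All (start, end) products by scanning every template position."""

    def mismatches(x: str, y: str) -> int:
        return sum(1 for p, q in zip(x, y) if p != q or p == "N" or q == "N")

    fsites = []
    for i in range(len(template) - len(fwd) + 1):
        win = template[i : i + len(fwd)]
        if mismatches(win[-three_exact:], fwd[-three_exact:]) == 0 and mismatches(
            win[:-three_exact], fwd[:-three_exact]
        ) <= max_mm:
            fsites.append(i)
    rmotif = revcomp(rev)
    rsites = []
    for i in range(len(template) - len(rmotif) + 1):
        win = template[i : i + len(rmotif)]
        if mismatches(win[:three_exact], rmotif[:three_exact]) == 0 and mismatches(
            win[three_exact:], rmotif[three_exact:]
        ) <= max_mm:
            rsites.append(i)
    lo, hi = size_range
    out = []
    for f in fsites:
        for r in rsites:
            end = r + len(rmotif)
            if lo <= end - f <= hi:
                out.append((f, end))
    return sorted(out)
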