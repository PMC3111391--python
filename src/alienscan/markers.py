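"""Marker design and in-silico validation for verified candidates.

Stages: (1) a uniqueness screen — a seeded, ungapped local similarity search
of each candidate against both contig libraries at a relaxed E-value cutoff,
which also yields the positions that distinguish the candidate from every
paralog; (2) SCAR-style primer-tag design over the candidate, preferring
discriminative positions inside the 3'-terminal window of each tag; (3) an
in-silico PCR surrogate across a genotype panel (exact 3' window, a small
mismatch allowance elsewhere); (4) CAPS restriction-digest comparison of
amplicons; (5) the linkage decision rules (carrier-chromosome linkage,
tight ASGR linkage, unlinked, uninformative) and a presence/absence
segregation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from . import _dna
from .errors import DataIntegrityError, ParameterError
from .seqio import Contig, PipelineConfig, ScoringParams
from .matchscan import karlin_altschul_evalue

__all__ = [
    "ParalogHit",
    "UniquenessReport",
    "Marker",
    "DesignFailure",
    "Amplicon",
    "AmplificationProfile",
    "LinkageClass",
    "LinkageCall",
    "SegregationResult",
    "uniqueness_screen",
    "design_marker",
    "insilico_pcr",
    "screen_panel",
    "classify_linkage",
    "find_caps_polymorphism",
    "segregation_check",
    "DEFAULT_ENZYMES",
]

UNIQUENESS_SEED_LEN = 16
XDROP = 20
_MAX_CONTEXT_CHECKS = 400  # bound on off-target screens per candidate

# small default panel; HaeIII and HpyCH4IV are the blunt 4-cutters used for
# CAPS genotyping of this material
DEFAULT_ENZYMES: tuple[tuple[str, str], ...] = (
    ("HaeIII", "GGCC"),
    ("HpyCH4IV", "ACGT"),
)


@dataclass(frozen=True)
class ParalogHit:
    contig_id: str
    library_id: str
    identity: float
    aligned_len: int
    evalue: float
    qstart: int  # on candidate, 0-based half-open
    qend: int
    sstart: int
    send: int
    strand: str
    mismatch_offsets: tuple[int, ...]  # candidate offsets differing inside the hit


@dataclass(frozen=True)
class UniquenessReport:
    candidate_id: str
    paralog_hits: tuple[ParalogHit, ...]
    discriminative_positions: tuple[int, ...]


@dataclass(frozen=True)
class Marker:
    """A primer-tag pair on a candidate contig."""

    marker_id: str
    source_candidate: str
    fwd_tag: str
    rev_tag: str
    fwd_start: int  # candidate coordinates, 0-based half-open
    rev_end: int
    expected_size: int  # on the transcript template


@dataclass(frozen=True)
class DesignFailure:
    source_candidate: str
    reason: str


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    locus_id: str
    start: int
    end: int
    size: int
    sequence: str


@dataclass(frozen=True)
class AmplificationProfile:
    marker_id: str
    calls: Mapping[str, str]  # genotype_id -> plus | minus | fail
    amplicon_sizes: Mapping[str, tuple[int, ...]]


class LinkageClass(str, Enum):
    carrier_linked = "carrier_linked"
    asgr_tight = "asgr_tight"
    unlinked = "unlinked"
    uninformative = "uninformative"


@dataclass(frozen=True)
class LinkageCall:
    marker_id: str
    call: LinkageClass
    evidence: Mapping[str, tuple[int, int]]  # class -> (n_plus, n_total)


@dataclass(frozen=True)
class SegregationResult:
    call: str  # linked | unlinked | uninformative
    n_present_apo: int
    n_apo: int
    n_present_sex: int
    n_sex: int


# --------------------------------------------------------------------------
# uniqueness screen
# --------------------------------------------------------------------------


def _ungapped_extend(q: str, s: str, qpos: int, spos: int, seed_len: int,
                     reward: int, penalty: int) -> tuple[int, int, int, int]:
    """X-drop ungapped extension of a seed; returns (qstart, qend, sstart, score)."""

    def step(direction: int, qi: int, si: int) -> int:
        best_gain, gain, ext, best_ext = 0, 0, 0, 0
        while True:
            qi2 = qi + direction * (ext + 1) if direction > 0 else qi - (ext + 1)
            si2 = si + direction * (ext + 1) if direction > 0 else si - (ext + 1)
            if not (0 <= qi2 < len(q) and 0 <= si2 < len(s)):
                break
            a, b = q[qi2], s[si2]
            gain += reward if (a == b and a != "N") else penalty
            ext += 1
            if gain > best_gain:
                best_gain, best_ext = gain, ext
            if best_gain - gain > XDROP:
                break
        return best_ext

    right = step(+1, qpos + seed_len - 1, spos + seed_len - 1)
    left = step(-1, qpos, spos)
    qs, qe = qpos - left, qpos + seed_len + right
    matches = sum(
        1 for a, b in zip(q[qs:qe], s[qs - (qpos - spos): qe - (qpos - spos)])
        if a == b and a != "N"
    )
    length = qe - qs
    score = reward * matches + penalty * (length - matches)
    return qs, qe, spos - left, score


def uniqueness_screen(
    candidate: Contig,
    library_a: Sequence[Contig],
    library_b: Sequence[Contig],
    config: PipelineConfig,
    partner_id: Optional[str] = None,
) -> UniquenessReport:
    """Estimate contig uniqueness within both transcriptomes.

    Seeded (16 bp exact) ungapped local search of the candidate against both
    libraries; hits with E <= e_threshold_uniqueness are reported, excluding
    the candidate itself and its verified partner. A candidate position is
    *discriminative* when every reported hit covering it carries a mismatch
    there (positions covered by no hit are trivially discriminative).
    """
    params = config.scoring
    q = candidate.sequence
    total_n = sum(len(c) for lib in (library_a, library_b) for c in lib)
    seed_index: dict[str, list[int]] = {}
    for p in range(len(q) - UNIQUENESS_SEED_LEN + 1):
        w = q[p : p + UNIQUENESS_SEED_LEN]
        if "N" not in w:
            seed_index.setdefault(w, []).append(p)

    hits: list[ParalogHit] = []
    for lib in (library_a, library_b):
        for subj in lib:
            if subj.contig_id in (candidate.contig_id, partner_id):
                continue
            for strand in "+-":
                s = subj.sequence if strand == "+" else _dna.revcomp(subj.sequence)
                found: set[tuple[int, int]] = set()
                for sp in range(len(s) - UNIQUENESS_SEED_LEN + 1):
                    w = s[sp : sp + UNIQUENESS_SEED_LEN]
                    qpositions = seed_index.get(w)
                    if not qpositions:
                        continue
                    for qp in qpositions:
                        qs, qe, ss, score = _ungapped_extend(
                            q, s, qp, sp, UNIQUENESS_SEED_LEN,
                            params.reward, params.penalty,
                        )
                        if (qs, ss) in found:
                            continue
                        found.add((qs, ss))
                        p2 = ScoringParams(
                            reward=params.reward, penalty=params.penalty,
                            lambda_=params.lambda_, k_const=params.k_const,
                            m=len(q), n=max(total_n, 1),
                        )
                        ev = karlin_altschul_evalue(score, p2)
                        if ev > config.e_threshold_uniqueness:
                            continue
                        length = qe - qs
                        diag = qp - sp
                        mism = tuple(
                            qs + k
                            for k, (a, b) in enumerate(
                                zip(q[qs:qe], s[qs - diag : qe - diag])
                            )
                            if a != b or a == "N"
                        )
                        if strand == "+":
                            sstart, send = ss, ss + length
                        else:
                            sstart, send = len(subj) - (ss + length), len(subj) - ss
                        hits.append(
                            ParalogHit(
                                contig_id=subj.contig_id,
                                library_id=subj.library_id,
                                identity=1.0 - len(mism) / length,
                                aligned_len=length,
                                evalue=ev,
                                qstart=qs,
                                qend=qe,
                                sstart=sstart,
                                send=send,
                                strand=strand,
                                mismatch_offsets=mism,
                            )
                        )

    # a position is discriminative unless some hit matches the candidate there
    matched = [False] * len(q)
    for h in hits:
        mm = set(h.mismatch_offsets)
        for pos in range(h.qstart, h.qend):
            if pos not in mm:
                matched[pos] = True
    discriminative = tuple(i for i, m in enumerate(matched) if not m)
    hits.sort(key=lambda h: (h.evalue, h.contig_id, h.qstart, h.strand))
    return UniquenessReport(
        candidate_id=candidate.contig_id,
        paralog_hits=tuple(hits),
        discriminative_positions=discriminative,
    )


# --------------------------------------------------------------------------
# marker design
# --------------------------------------------------------------------------


def design_marker(
    candidate: Contig,
    report: UniquenessReport,
    config: PipelineConfig,
    ortholog_context: Optional[Sequence[str]] = None,
    marker_id: Optional[str] = None,
) -> Marker | DesignFailure:
    """Place a discriminative primer-tag pair on the candidate.

    Scans all (forward start, reverse end) placements with amplicon size in
    ``amplicon_size_range`` and picks the one maximizing the number of
    discriminative positions inside the 3'-terminal ``pcr_3prime_exact``
    bases of the two tags (ties: smallest forward start, then smallest
    amplicon). When paralogs were reported, a placement must capture at
    least one such position; sequences in ``ortholog_context`` must not
    amplify. Returns a :class:`DesignFailure` when no placement qualifies.
    """
    L = len(candidate)
    tag = config.primer_tag_len
    lo, hi = config.amplicon_size_range
    lo = max(lo, 2 * tag)
    if L < lo:
        return DesignFailure(candidate.contig_id, "candidate too short for amplicon")
    seq = candidate.sequence
    disc = [False] * L
    for p in report.discriminative_positions:
        disc[p] = True
    prefix = [0]
    for d in disc:
        prefix.append(prefix[-1] + int(d))

    def disc_in(a: int, b: int) -> int:
        return prefix[b] - prefix[a]

    w = config.pcr_3prime_exact
    need_specific = len(report.paralog_hits) > 0
    # precompute which tag windows occur exactly once (and are N-free)
    window_count: dict[str, int] = {}
    for p in range(L - tag + 1):
        win = seq[p : p + tag]
        window_count[win] = window_count.get(win, 0) + 1
    ok_window = [
        "N" not in seq[p : p + tag] and window_count[seq[p : p + tag]] == 1
        for p in range(L - tag + 1)
    ]
    placements: list[tuple[int, int, int]] = []  # (score, fs, re)
    for fs in range(0, L - lo + 1):
        if not ok_window[fs]:
            continue
        re_min, re_max = fs + lo, min(L, fs + hi)
        for re_ in range(re_min, re_max + 1):
            if not ok_window[re_ - tag]:
                continue
            score = disc_in(fs + tag - w, fs + tag) + disc_in(re_ - tag, re_ - tag + w)
            if need_specific and score < 1:
                continue
            placements.append((score, fs, re_))
    if not placements:
        return DesignFailure(
            candidate.contig_id,
            "no placement achieves specificity" if need_specific
            else "no unique tag placement",
        )
    placements.sort(key=lambda t: (-t[0], t[1], t[2]))
    checked_off_target = False
    for score, fs, re_ in placements[:_MAX_CONTEXT_CHECKS]:
        marker = Marker(
            marker_id=marker_id or f"M_{candidate.contig_id}",
            source_candidate=candidate.contig_id,
            fwd_tag=seq[fs : fs + tag],
            rev_tag=_dna.revcomp(seq[re_ - tag : re_]),
            fwd_start=fs,
            rev_end=re_,
            expected_size=re_ - fs,
        )
        if ortholog_context and any(
            _scan_template(marker, ctx, config) for ctx in ortholog_context
        ):
            checked_off_target = True
            continue
        return marker
    return DesignFailure(
        candidate.contig_id,
        "all placements amplify an off-target sequence"
        if checked_off_target
        else "no unique tag placement",
    )


# --------------------------------------------------------------------------
# in-silico PCR
# --------------------------------------------------------------------------


def _binding_sites(primer: str, template: str, three_exact: int, max_mm: int,
                   orient: str) -> list[int]:
    """Start positions (on the template forward strand) where the primer binds.

    ``orient`` '+': primer as-is, 3' end rightmost; exact window is the
    rightmost ``three_exact`` bases. '-': the primer binds the minus strand;
    its plus-strand footprint is revcomp(primer) with the 3' end leftmost,
    so the exact window is the leftmost ``three_exact`` bases.
    """
    if orient == "+":
        motif = primer
        core = motif[len(motif) - three_exact :]
        core_off = len(motif) - three_exact
    else:
        motif = _dna.revcomp(primer)
        core = motif[:three_exact]
        core_off = 0
    if "N" in core:
        return []
    sites = []
    start = template.find(core)
    while start != -1:
        pos = start - core_off
        if 0 <= pos <= len(template) - len(motif):
            mm = sum(
                1
                for a, b in zip(motif, template[pos : pos + len(motif)])
                if a != b or a == "N"
            )
            # core is exact by construction; count only the remainder
            if mm <= max_mm:
                sites.append(pos)
        start = template.find(core, start + 1)
    return sites


def _scan_template(marker: Marker, template: str, config: PipelineConfig) -> list[tuple[int, int]]:
    """All convergent (start, end) products on one template sequence."""
    lo, hi = config.pcr_product_range
    fwd_sites = _binding_sites(
        marker.fwd_tag, template, config.pcr_3prime_exact,
        config.pcr_max_other_mismatches, "+",
    )
    rev_sites = _binding_sites(
        marker.rev_tag, template, config.pcr_3prime_exact,
        config.pcr_max_other_mismatches, "-",
    )
    tag = len(marker.rev_tag)
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + tag
            size = end - f
            if lo <= size <= hi:
                out.append((f, end))
    return sorted(out)


def insilico_pcr(marker: Marker, template, config: PipelineConfig) -> list[Amplicon]:
    """Enumerate every amplicon of the marker on a genotype genome.

    A primer binds iff its 3'-terminal ``pcr_3prime_exact`` bases match the
    template exactly and at most ``pcr_max_other_mismatches`` mismatches
    occur in the remainder. Products are reported for convergent site pairs
    with size in ``pcr_product_range``.
    """
    amps: list[Amplicon] = []
    for locus_id, seq in template.sequences:
        for start, end in _scan_template(marker, seq, config):
            amps.append(
                Amplicon(
                    template_id=template.genotype_id,
                    locus_id=locus_id,
                    start=start,
                    end=end,
                    size=end - start,
                    sequence=seq[start:end],
                )
            )
    return amps


def screen_panel(marker: Marker, panel: Sequence, config: PipelineConfig) -> AmplificationProfile:
    """+/- calls for the marker across every panel genotype."""
    if not panel:
        raise ParameterError("panel must be non-empty")
    calls: dict[str, str] = {}
    sizes: dict[str, tuple[int, ...]] = {}
    for genome in panel:
        if not genome.sequences:
            calls[genome.genotype_id] = "fail"
            sizes[genome.genotype_id] = ()
            continue
        amps = insilico_pcr(marker, genome, config)
        calls[genome.genotype_id] = "plus" if amps else "minus"
        sizes[genome.genotype_id] = tuple(a.size for a in amps)
    return AmplificationProfile(marker_id=marker.marker_id, calls=calls,
                                amplicon_sizes=sizes)


# --------------------------------------------------------------------------
# linkage rules
# --------------------------------------------------------------------------


def classify_linkage(
    profile: AmplificationProfile, panel_design: Mapping[str, str]
) -> LinkageCall:
    """Apply the decision rules behind the mapping table.

    carrier_linked: amplification from the donor and every apomictic
    addition-line segregant, none from the recurrent parent or any sexual
    segregant (the third relative may go either way). asgr_tight:
    additionally every apomictic F1 amplifies and no sexual F1 does.
    unlinked: presence in both F1 classes without carrier-linkage.
    uninformative: amplification from the recurrent parent, or no
    amplification anywhere.
    """
    for gid in panel_design:
        if gid not in profile.calls:
            raise DataIntegrityError(f"no amplification call for genotype {gid!r}")

    def members(label: str) -> list[str]:
        return [g for g, lab in panel_design.items() if lab == label]

    def plus(gid: str) -> bool:
        return profile.calls[gid] == "plus"

    evidence = {
        label: (sum(plus(g) for g in members(label)), len(members(label)))
        for label in (
            "donor", "recurrent", "relative",
            "addition_apo", "addition_sex", "f1_apo", "f1_sex",
        )
        if members(label)
    }

    def call(c: LinkageClass) -> LinkageCall:
        return LinkageCall(profile.marker_id, c, evidence)

    if any(plus(g) for g in members("recurrent")):
        return call(LinkageClass.uninformative)
    if not any(c == "plus" for c in profile.calls.values()):
        return call(LinkageClass.uninformative)

    carrier = (
        all(plus(g) for g in members("donor"))
        and all(plus(g) for g in members("addition_apo"))
        and not any(plus(g) for g in members("addition_sex"))
    )
    f1_apo, f1_sex = members("f1_apo"), members("f1_sex")
    if carrier:
        if f1_apo and f1_sex:
            if all(plus(g) for g in f1_apo) and not any(plus(g) for g in f1_sex):
                return call(LinkageClass.asgr_tight)
        return call(LinkageClass.carrier_linked)
    if any(plus(g) for g in f1_apo) and any(plus(g) for g in f1_sex):
        return call(LinkageClass.unlinked)
    return call(LinkageClass.uninformative)


# --------------------------------------------------------------------------
# CAPS + segregation
# --------------------------------------------------------------------------


def _digest(seq: str, site: str) -> tuple[int, ...]:
    """Fragment-size multiset after cutting at every site occurrence start."""
    cuts = []
    start = seq.find(site)
    while start != -1:
        cuts.append(start)
        start = seq.find(site, start + 1)
    bounds = [0] + cuts + [len(seq)]
    sizes = [b - a for a, b in zip(bounds, bounds[1:]) if b - a > 0]
    return tuple(sorted(sizes))


def find_caps_polymorphism(
    amplicon_a: str,
    amplicon_b: str,
    enzymes: Iterable[tuple[str, str]] = DEFAULT_ENZYMES,
) -> list[tuple[str, tuple[int, ...], tuple[int, ...]]]:
    """Enzymes whose fragment-size multisets differ between two amplicons.

    Cut position is the recognition-site start; fragment sizes always sum to
    the amplicon length.
    """
    if not amplicon_a or not amplicon_b:
        raise ParameterError("amplicons must be non-empty")
    out = []
    for name, site in enzymes:
        if not site or any(c not in "ACGT" for c in site):
            raise ParameterError(f"invalid recognition site {site!r} for {name}")
        fa = _digest(amplicon_a, site)
        fb = _digest(amplicon_b, site)
        if fa != fb:
            out.append((name, fa, fb))
    return out


def segregation_check(
    allele_presence: Mapping[str, bool],
    classes: Mapping[str, str],
) -> SegregationResult:
    """Presence/absence co-segregation with the apomictic class.

    linked: present in every apomictic and no sexual individual. unlinked:
    present in at least one individual of each class. uninformative: absent
    everywhere, or any remaining partial pattern.
    """
    apo = [i for i, c in classes.items() if c == "apo"]
    sex = [i for i, c in classes.items() if c == "sex"]
    if not apo or not sex:
        raise ParameterError("need at least one individual per class")
    unknown = set(classes.values()) - {"apo", "sex"}
    if unknown:
        raise ParameterError(f"unknown class labels: {sorted(unknown)}")
    n_apo = sum(bool(allele_presence.get(i, False)) for i in apo)
    n_sex = sum(bool(allele_presence.get(i, False)) for i in sex)
    if n_apo == 0 and n_sex == 0:
        call = "uninformative"
    elif n_apo >= 1 and n_sex >= 1:
        call = "unlinked"
    elif n_apo == len(apo) and n_sex == 0:
        call = "linked"
    else:
        call = "uninformative"
    return SegregationResult(call, n_apo, len(apo), n_sex, len(sex))
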