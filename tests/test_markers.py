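import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from alienscan.errors import DataIntegrityError, ParameterError
from alienscan.markers import (
    DEFAULT_ENZYMES,
    AmplificationProfile,
    DesignFailure,
    LinkageClass,
    Marker,
    classify_linkage,
    design_marker,
    find_caps_polymorphism,
    insilico_pcr,
    screen_panel,
    segregation_check,
    uniqueness_screen,
)
from alienscan.seqio import Contig, PipelineConfig
from alienscan.synthdata import GenotypeGenome
from conftest import random_dna


def genome(gid, label, **loci):
    return GenotypeGenome(gid, label, tuple(loci.items()))


# --------------------------------------------------------------------------
# uniqueness screen
# --------------------------------------------------------------------------


def test_unique_candidate_has_no_paralogs_and_all_positions_discriminative(rng, config):
    cand = Contig("cand", "A", random_dna(rng, 250))
    noise = [Contig(f"n{i}", "A", random_dna(rng, 250)) for i in range(5)]
    rep = uniqueness_screen(cand, [cand] + noise, [], config)
    assert rep.paralog_hits == ()
    assert rep.discriminative_positions == tuple(range(250))


def test_planted_paralog_flagged_with_exact_substitution_offsets(rng, config):
    seq = random_dna(rng, 200)
    offsets = [40, 90, 151]
    par = list(seq)
    for p in offsets:
        par[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[par[p]]
    cand = Contig("cand", "A", seq)
    paralog = Contig("par", "A", "".join(par))
    rep = uniqueness_screen(cand, [cand, paralog], [], config)
    assert [h.contig_id for h in rep.paralog_hits] == ["par"]
    assert rep.discriminative_positions == tuple(offsets)


def test_verified_partner_excluded_from_screen(rng, config):
    seq = random_dna(rng, 250)
    cand = Contig("cand", "A", seq)
    partner = Contig("partner", "B", seq)
    rep = uniqueness_screen(cand, [cand], [partner], config, partner_id="partner")
    assert rep.paralog_hits == ()


# --------------------------------------------------------------------------
# marker design
# --------------------------------------------------------------------------


def test_unique_candidate_designs_valid_marker(rng, config):
    cand = Contig("cand", "A", random_dna(rng, 300))
    rep = uniqueness_screen(cand, [cand], [], config)
    m = design_marker(cand, rep, config)
    assert isinstance(m, Marker)
    assert 100 <= m.expected_size <= 450
    assert cand.sequence[m.fwd_start : m.fwd_start + 20] == m.fwd_tag
    assert oracles.revcomp(cand.sequence[m.rev_end - 20 : m.rev_end]) == m.rev_tag


def test_too_short_candidate_fails_design(rng, config):
    cand = Contig("tiny", "A", random_dna(rng, 60))
    rep = uniqueness_screen(cand, [cand], [], config)
    res = design_marker(cand, rep, config)
    assert isinstance(res, DesignFailure)


def test_paralog_aware_design_is_specific(rng, config):
    """Tags cover a discriminative site and the paralog does not amplify."""
    seq = random_dna(rng, 300)
    offsets = [60, 150, 240]
    par = list(seq)
    for p in offsets:
        par[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[par[p]]
    cand = Contig("cand", "A", seq)
    paralog = Contig("par", "A", "".join(par))
    rep = uniqueness_screen(cand, [cand, paralog], [], config)
    m = design_marker(cand, rep, config)
    assert isinstance(m, Marker)
    w = config.pcr_3prime_exact
    fwd_window = set(range(m.fwd_start + 20 - w, m.fwd_start + 20))
    rev_window = set(range(m.rev_end - 20, m.rev_end - 20 + w))
    assert (fwd_window | rev_window) & set(offsets)
    assert insilico_pcr(m, genome("P", "donor", locus="".join(par)), config) == []
    # and the true template still amplifies
    assert len(insilico_pcr(m, genome("T", "donor", locus=seq), config)) == 1


# --------------------------------------------------------------------------
# in-silico PCR
# --------------------------------------------------------------------------


def test_self_template_gives_single_expected_amplicon(rng, config):
    cand = Contig("cand", "A", random_dna(rng, 300))
    rep = uniqueness_screen(cand, [cand], [], config)
    m = design_marker(cand, rep, config)
    amps = insilico_pcr(m, genome("self", "donor", locus=cand.sequence), config)
    assert len(amps) == 1
    assert amps[0].size == m.expected_size


def test_three_prime_terminal_mismatch_abolishes_binding(rng, config):
    cand = Contig("cand", "A", random_dna(rng, 300))
    rep = uniqueness_screen(cand, [cand], [], config)
    m = design_marker(cand, rep, config)
    t = list(cand.sequence)
    pos = m.fwd_start + 19  # 3'-terminal base of the forward tag
    t[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[pos]]
    assert insilico_pcr(m, genome("mut", "donor", locus="".join(t)), config) == []


def test_nonterminal_mismatches_tolerated(rng, config):
    cand = Contig("cand", "A", random_dna(rng, 300))
    rep = uniqueness_screen(cand, [cand], [], config)
    m = design_marker(cand, rep, config)
    t = list(cand.sequence)
    for off in (0, 2):  # 5' end of the forward tag, outside the exact window
        pos = m.fwd_start + off
        t[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[pos]]
    assert len(insilico_pcr(m, genome("mut", "donor", locus="".join(t)), config)) == 1


def test_multiple_sites_match_bruteforce_enumeration(rng, config):
    """Two forward sites + one reverse site -> two products, per the scan oracle."""
    fwd = random_dna(rng, 20)
    rev = random_dna(rng, 20)
    rmotif = oracles.revcomp(rev)
    template = (
        random_dna(rng, 50) + fwd + random_dna(rng, 100) + fwd
        + random_dna(rng, 80) + rmotif + random_dna(rng, 30)
    )
    m = Marker("m", "cand", fwd, rev, 0, 0, expected_size=0)
    amps = insilico_pcr(m, genome("t", "donor", locus=template), config)
    expected = oracles.pcr_products_bruteforce(
        fwd, rev, template, config.pcr_3prime_exact,
        config.pcr_max_other_mismatches, config.pcr_product_range,
    )
    assert [(a.start, a.end) for a in amps] == expected
    assert len(amps) == 2


def test_intron_spanning_amplicon_size_reflects_template(rng, config):
    """Genomic templates with an intron yield a larger product than the transcript."""
    exon1, intron, exon2 = random_dna(rng, 150), random_dna(rng, 120), random_dna(rng, 150)
    transcript = exon1 + exon2
    # tag pair straddling the exon junction (transcript coords 100..220)
    m = Marker(
        "m", "cand",
        fwd_tag=transcript[100:120],
        rev_tag=oracles.revcomp(transcript[200:220]),
        fwd_start=100, rev_end=220, expected_size=120,
    )
    on_transcript = insilico_pcr(m, genome("t", "donor", locus=transcript), config)
    assert [a.size for a in on_transcript] == [120]
    amps = insilico_pcr(m, genome("g", "donor", locus=exon1 + intron + exon2), config)
    assert [a.size for a in amps] == [m.expected_size + 120]


# --------------------------------------------------------------------------
# panel screening + linkage rules
# --------------------------------------------------------------------------


def synthetic_profile(calls):
    return AmplificationProfile("m", calls, {g: () for g in calls})


def panel_design_small():
    design = {"PS26": "donor", "IA4X": "recurrent", "N37": "relative"}
    for i in range(4):
        design[f"BA{i}"] = "addition_apo"
        design[f"BS{i}"] = "addition_sex"
    for i in range(10):
        design[f"FA{i}"] = "f1_apo"
    for i in range(12):
        design[f"FS{i}"] = "f1_sex"
    return design


def calls_for(design, plus_classes, minus_relative=False):
    calls = {}
    for gid, label in design.items():
        calls[gid] = "plus" if label in plus_classes else "minus"
    if minus_relative:
        calls["N37"] = "minus"
    return calls


def test_asgr_tight_pattern():
    """Donor/apomictic-only amplification incl. F1s: tight ASGR linkage."""
    design = panel_design_small()
    calls = calls_for(design, {"donor", "addition_apo", "f1_apo"}, minus_relative=True)
    call = classify_linkage(synthetic_profile(calls), design)
    assert call.call is LinkageClass.asgr_tight


def test_carrier_linked_when_both_f1_classes_amplify():
    design = panel_design_small()
    calls = calls_for(design, {"donor", "addition_apo", "f1_apo", "f1_sex"})
    call = classify_linkage(synthetic_profile(calls), design)
    assert call.call is LinkageClass.carrier_linked


def test_relative_plus_or_minus_both_stay_carrier_linked():
    design = panel_design_small()
    for minus_rel in (False, True):
        calls = calls_for(
            design, {"donor", "relative", "addition_apo", "f1_apo", "f1_sex"},
        )
        if minus_rel:
            calls["N37"] = "minus"
        call = classify_linkage(synthetic_profile(calls), design)
        assert call.call is LinkageClass.carrier_linked


def test_all_plus_pattern_is_uninformative():
    design = panel_design_small()
    calls = {g: "plus" for g in design}
    call = classify_linkage(synthetic_profile(calls), design)
    assert call.call is LinkageClass.uninformative


def test_missing_genotype_call_raises():
    design = panel_design_small()
    calls = {g: "plus" for g in design}
    calls.pop("N37")
    with pytest.raises(DataIntegrityError):
        classify_linkage(synthetic_profile(calls), design)


def test_end_to_end_marker_calls_on_synthetic_panel(experiment, config):
    """An alien-derived candidate yields donor+/apo+ but recurrent-/sex- calls."""
    truth = experiment.truth.set_index("contig_id")
    lib_a = experiment.library_a
    alien_ids = [
        c.contig_id for c in lib_a if truth.loc[c.contig_id, "origin"] == "alien_ibd"
    ]
    by_id = {c.contig_id: c for c in lib_a}
    design = {g.genotype_id: g.class_label for g in experiment.panel}
    partner_of = {}
    b_truth = truth[truth["origin"] == "alien_ibd"]
    for rb in b_truth.itertuples():
        if rb.library_id == experiment.config.library_b_id:
            for ra in b_truth.itertuples():
                if (
                    ra.library_id == experiment.config.library_a_id
                    and ra.gene_id == rb.gene_id
                ):
                    partner_of[ra.Index] = rb.Index
    context = [
        seq
        for g in experiment.panel
        if g.class_label == "recurrent"
        for _, seq in g.sequences
    ]
    tested = 0
    for cid in alien_ids:
        cand = by_id[cid]
        rep = uniqueness_screen(
            cand, lib_a, experiment.library_b, config,
            partner_id=partner_of.get(cid),
        )
        m = design_marker(cand, rep, config, ortholog_context=context)
        if isinstance(m, DesignFailure):
            continue
        profile = screen_panel(m, experiment.panel, config)
        assert profile.calls["PS26"] == "plus"
        assert profile.calls["IA4X"] == "minus"
        for g in experiment.panel:
            if g.class_label == "addition_apo":
                assert profile.calls[g.genotype_id] == "plus"
            if g.class_label == "addition_sex":
                assert profile.calls[g.genotype_id] == "minus"
        call = classify_linkage(profile, design)
        assert call.call in (LinkageClass.carrier_linked, LinkageClass.asgr_tight)
        tested += 1
        if tested >= 3:
            break
    assert tested > 0


# --------------------------------------------------------------------------
# CAPS + segregation
# --------------------------------------------------------------------------


def test_identical_amplicons_show_no_polymorphism(rng):
    seq = random_dna(rng, 200)
    assert find_caps_polymorphism(seq, seq) == []


def test_haeiii_site_gain_detected():
    backbone = ("ACTGAT" * 60)[:300]
    assert "GGCC" not in backbone
    with_site = backbone[:100] + "GGCC" + backbone[104:]
    out = find_caps_polymorphism(with_site, backbone, [("HaeIII", "GGCC")])
    assert out == [("HaeIII", (100, 200), (300,))]


def test_invalid_recognition_site_rejected():
    with pytest.raises(ParameterError):
        find_caps_polymorphism("ACGT", "ACGT", [("bad", "GGXC")])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_digest_fragments_sum_to_amplicon_length(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    seq = random_dna(rng, int(rng.integers(20, 400)))
    for name, site in DEFAULT_ENZYMES:
        from alienscan.markers import _digest

        assert sum(_digest(seq, site)) == len(seq)


def test_segregation_patterns():
    classes = {f"a{i}": "apo" for i in range(10)}
    classes.update({f"s{i}": "sex" for i in range(12)})
    # the published CAPS case: 5 of 10 apomictic and 7 of 12 sexual carriers
    presence = {f"a{i}": i < 5 for i in range(10)}
    presence.update({f"s{i}": i < 7 for i in range(12)})
    res = segregation_check(presence, classes)
    assert res.call == "unlinked"
    assert (res.n_present_apo, res.n_present_sex) == (5, 7)
    perfect = {f"a{i}": True for i in range(10)}
    perfect.update({f"s{i}": False for i in range(12)})
    assert segregation_check(perfect, classes).call == "linked"
    nobody = {k: False for k in classes}
    assert segregation_check(nobody, classes).call == "uninformative"
    with pytest.raises(ParameterError):
        segregation_check({"a": True}, {"a": "apo"})
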