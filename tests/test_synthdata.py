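import numpy as np
import pytest
from scipy import stats

from alienscan.errors import ConfigurationError
from alienscan.matchscan import find_exact_matches
from alienscan.seqio import write_fasta
from alienscan.synthdata import (
    PanelSpec,
    SimulationConfig,
    fragment_transcript,
    simulate_experiment,
)


def fasta_bytes(contigs, tmp_path, name):
    path = tmp_path / name
    write_fasta(contigs, path)
    return path.read_bytes()


def test_zero_genes_gives_empty_outputs():
    exp = simulate_experiment(SimulationConfig(n_genes=0, seed=1))
    assert exp.library_a == [] and exp.library_b == []
    assert len(exp.truth) == 0


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(d_species=1.5),
        dict(error_rate=-0.1),
        dict(n_genes=-1),
        dict(three_prime_bias=-2.0),
        dict(alien_chromosome_id="chr9", n_donor_chromosomes=4),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)


def test_same_seed_gives_byte_identical_fasta(tmp_path):
    cfg = SimulationConfig(n_genes=25, seed=11)
    e1 = simulate_experiment(cfg)
    e2 = simulate_experiment(SimulationConfig(n_genes=25, seed=11))
    assert fasta_bytes(e1.library_a, tmp_path, "a1") == fasta_bytes(
        e2.library_a, tmp_path, "a2"
    )
    assert fasta_bytes(e1.library_b, tmp_path, "b1") == fasta_bytes(
        e2.library_b, tmp_path, "b2"
    )
    assert e1.truth.equals(e2.truth)


def test_every_contig_has_exactly_one_truth_record(experiment):
    ids = [c.contig_id for c in experiment.library_a + experiment.library_b]
    assert sorted(experiment.truth["contig_id"]) == sorted(ids)
    assert experiment.truth["contig_id"].is_unique


def test_alien_contigs_share_identical_overlap_when_error_free():
    """Identity by descent: error-free alien contig pairs agree wherever they overlap."""
    cfg = SimulationConfig(
        n_genes=50, n_donor_chromosomes=1, alien_chromosome_id="chr1",
        error_rate=0.0, seed=5,
    )
    exp = simulate_experiment(cfg)
    truth = exp.truth
    alien = truth[truth["origin"] == "alien_ibd"]
    assert len(alien) > 0
    # all alien records come from copy 0 of chr1 genes
    assert set(alien["copy_id"]) == {"cp0"}
    seqs = {c.contig_id: c.sequence for c in exp.library_a + exp.library_b}
    a_side = alien[alien["library_id"] == cfg.library_a_id]
    b_side = alien[alien["library_id"] == cfg.library_b_id]
    checked = 0
    for ra in a_side.itertuples(index=False):
        for rb in b_side.itertuples(index=False):
            if ra.gene_id != rb.gene_id:
                continue
            lo = max(ra.frag_start, rb.frag_start)
            hi = min(ra.frag_end, rb.frag_end)
            if hi <= lo:
                continue
            sub_a = seqs[ra.contig_id][lo - ra.frag_start : hi - ra.frag_start]
            sub_b = seqs[rb.contig_id][lo - rb.frag_start : hi - rb.frag_start]
            assert sub_a == sub_b
            checked += 1
    assert checked > 0


def test_planted_signal_guarantee(experiment, config):
    """Every error-free alien pair overlapping >= L yields an exact match >= L."""
    L = 100
    truth = experiment.truth
    alien = truth[truth["origin"] == "alien_ibd"]
    by_id = {c.contig_id: c for c in experiment.library_a + experiment.library_b}
    cfg = experiment.config
    a_side = alien[alien["library_id"] == cfg.library_a_id]
    b_side = alien[alien["library_id"] == cfg.library_b_id]
    for ra in a_side.itertuples(index=False):
        for rb in b_side.itertuples(index=False):
            if ra.gene_id != rb.gene_id:
                continue
            ov = min(ra.frag_end, rb.frag_end) - max(ra.frag_start, rb.frag_start)
            if ov < L:
                continue
            hits = find_exact_matches([by_id[ra.contig_id]], [by_id[rb.contig_id]], L)
            assert any(h.length >= ov for h in hits)


def test_donor_recurrent_divergence_tracks_d_species():
    cfg = SimulationConfig(n_genes=40, d_species=0.08, seed=21)
    exp = simulate_experiment(cfg)
    diffs = total = 0
    for gene in exp.genes:
        ref = exp.genomes[(gene.gene_id, "cp0")]
        rec = exp.genomes[(gene.gene_id, "recurrent")]
        diffs += sum(1 for x, y in zip(ref, rec) if x != y)
        total += len(ref)
    rate = diffs / total
    se = np.sqrt(0.08 * 0.92 / total)
    assert abs(rate - 0.08) < 5 * se


def test_panel_genome_composition(experiment):
    cfg = experiment.config
    alien_genes = {
        g.gene_id for g in experiment.genes
        if g.chromosome_id == cfg.alien_chromosome_id
    }
    asgr_genes = {g.gene_id for g in experiment.genes if g.asgr}
    assert asgr_genes and asgr_genes < alien_genes
    by_class = {}
    for g in experiment.panel:
        by_class.setdefault(g.class_label, []).append(g)
    spec = cfg.panel_spec
    assert len(by_class["addition_apo"]) == spec.n_addition_apo
    assert len(by_class["addition_sex"]) == spec.n_addition_sex
    assert len(by_class["f1_apo"]) == spec.n_f1_apo
    assert len(by_class["f1_sex"]) == spec.n_f1_sex

    def alien_loci(genome):
        return {
            lid.split("|")[0]
            for lid, _ in genome.sequences
            if lid.endswith("|cp0") and lid.split("|")[0] in alien_genes
        }

    for g in by_class["addition_apo"]:
        assert alien_loci(g) == alien_genes
    for g in by_class["addition_sex"] + [by_class["recurrent"][0]]:
        assert alien_loci(g) == set()
    for g in by_class["f1_apo"]:
        assert asgr_genes <= alien_loci(g)
    for g in by_class["f1_sex"]:
        assert alien_loci(g) == alien_genes - asgr_genes


def test_fragment_start_uniform_when_unbiased():
    cfg = SimulationConfig(three_prime_bias=0.0, frag_len_sd=0.0, frag_mean_len=200)
    rng = np.random.default_rng(77)
    starts = [
        fragment_transcript(1000, cfg, rng)[0][0] for _ in range(10_000)
    ]
    # 800 feasible starts (0..800); chi-square GOF over 20 bins
    counts, _ = np.histogram(starts, bins=20, range=(0, 801))
    chi = stats.chisquare(counts)
    assert chi.pvalue > 0.01


def test_three_prime_bias_shifts_midpoints():
    cfg = SimulationConfig(three_prime_bias=3.0, frag_len_sd=0.0, frag_mean_len=200)
    rng = np.random.default_rng(78)
    mids = []
    for _ in range(3000):
        s, e = fragment_transcript(1000, cfg, rng)[0]
        mids.append((s + e) / 2)
    assert np.mean(mids) > 500


def test_three_prime_coverage_matches_discrete_expectation():
    """Empirical 3'-half coverage equals the exact discrete-mixture value."""
    beta = 2.0
    L, f = 500, 200
    cfg = SimulationConfig(
        three_prime_bias=beta, frag_len_sd=0.0, frag_mean_len=float(f)
    )
    smax = L - f
    s_vals = np.arange(smax + 1)
    w = np.exp(-beta * (smax - s_vals) / smax)
    w /= w.sum()
    # bp of the fragment falling in the 3' half [L/2, L)
    ov = np.minimum(s_vals + f, L) - np.maximum(s_vals, L // 2)
    expected = float((w * np.clip(ov, 0, None)).sum()) / f
    rng = np.random.default_rng(99)
    fracs = []
    for _ in range(20_000):
        s, e = fragment_transcript(L, cfg, rng)[0]
        fracs.append(max(0, min(e, L) - max(s, L // 2)) / f)
    assert abs(np.mean(fracs) - expected) < 0.01 * expected


def test_short_transcript_yields_no_fragments():
    cfg = SimulationConfig()
    rng = np.random.default_rng(1)
    assert fragment_transcript(cfg.frag_min_len - 1, cfg, rng) == []


def test_recurrent_pair_identical_stretch_rate_matches_monte_carlo():
    """Long identical stretches between species arise at the rate mutation
    placement predicts (Monte-Carlo oracle over substitution positions)."""
    cfg = SimulationConfig(n_genes=200, d_species=0.05, seed=1)
    exp = simulate_experiment(cfg)
    truth = exp.truth
    seqs = {c.contig_id: c.sequence for c in exp.library_a + exp.library_b}
    a_cp0 = truth[
        (truth["library_id"] == cfg.library_a_id) & (truth["copy_id"] == "cp0")
    ]
    b_rec = truth[truth["origin"] == "recurrent"]
    b_by_gene = {}
    for rb in b_rec.itertuples(index=False):
        b_by_gene.setdefault(rb.gene_id, []).append(rb)

    rng = np.random.default_rng(12345)
    observed = 0
    prob_sum = var_sum = 0.0
    n_pairs = 0
    for ra in a_cp0.itertuples(index=False):
        for rb in b_by_gene.get(ra.gene_id, []):
            lo = max(ra.frag_start, rb.frag_start)
            hi = min(ra.frag_end, rb.frag_end)
            w = hi - lo
            if w < 100:
                continue
            n_pairs += 1
            sub_a = seqs[ra.contig_id][lo - ra.frag_start : hi - ra.frag_start]
            sub_b = seqs[rb.contig_id][lo - rb.frag_start : hi - rb.frag_start]
            run = best = 0
            for x, y in zip(sub_a, sub_b):
                run = run + 1 if x == y else 0
                best = max(best, run)
            observed += best >= 100
            # Monte-Carlo: probability of a >=100 clean run in w Bernoulli sites
            hits = 0
            reps = 400
            for _ in range(reps):
                mut = rng.random(w) < cfg.d_species
                runlen = cur = 0
                for m in mut:
                    cur = 0 if m else cur + 1
                    runlen = max(runlen, cur)
                hits += runlen >= 100
            p = hits / reps
            prob_sum += p
            var_sum += p * (1 - p)
    assert n_pairs >= 20
    sd = max(np.sqrt(var_sum), 1.0)
    assert abs(observed - prob_sum) <= 4 * sd + 2
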