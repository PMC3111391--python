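"""Synthetic donor / recurrent-parent / addition-line transcriptomes.

The generator plants exactly the structure the comparison strategy assumes:

* a high-ploidy **donor** genotype with several homeologous copies per gene
  (copy 0 is the haplotype residing on the designated *alien* chromosome —
  the carrier chromosome);
* a **recurrent parent** whose orthologs diverge from the donor at
  ``d_species`` substitutions/site;
* an **addition line** = recurrent parent plus the alien chromosome's donor
  haplotype, copied without substitutions (identical by descent);
* short 3'-biased contig libraries from both genotypes (contig = fragment;
  no read-level assembly is simulated);
* a genotype panel (donor, recurrent, a third relative, apomictic/sexual
  backcross segregants, apomictic/sexual F1s) of intron-bearing genomic
  templates for in-silico PCR, with an ASGR-flagged subset of the alien
  chromosome's genes that only apomictic F1s carry.

Every contig is covered by exactly one ground-truth record, and identical
seed + config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _dna
from .errors import ConfigurationError, ParameterError
from .seqio import Contig

__all__ = [
    "PanelSpec",
    "SimulationConfig",
    "TruthRecord",
    "GenotypeGenome",
    "SimulatedExperiment",
    "fragment_transcript",
    "simulate_experiment",
]

ORIGIN_ALIEN = "alien_ibd"
ORIGIN_RECURRENT = "recurrent"
ORIGIN_DONOR_OTHER = "donor_non_alien"

TRUTH_COLUMNS = [
    "contig_id",
    "origin",
    "gene_id",
    "chromosome_id",
    "copy_id",
    "library_id",
    "frag_start",
    "frag_end",
]


@dataclass(frozen=True)
class PanelSpec:
    """Genotype-panel sizes: 4+4 backcross segregants, 10+12 F1s by default."""

    n_addition_apo: int = 4
    n_addition_sex: int = 4
    n_f1_apo: int = 10
    n_f1_sex: int = 12


@dataclass
class SimulationConfig:
    """Study conditions for one simulated comparison experiment.

    Rates are substitutions/site. ``three_prime_bias`` is the unitless rate
    beta of the exponential start-position weighting (0 = uniform).
    ``d_homeolog`` separates donor homeologous copies from the carrier
    haplotype; ``d_species`` separates the recurrent parent (and the third
    relative, independently) from the donor carrier haplotype, so donor
    copy-0 vs recurrent ortholog identity is ~ 1 - d_species.
    """

    n_genes: int = 120
    n_donor_chromosomes: int = 4
    alien_chromosome_id: str = "chr1"
    donor_ploidy_copies: int = 4
    d_homeolog: float = 0.02
    d_species: float = 0.05
    transcript_len: tuple[int, int] = (300, 1200)
    frag_mean_len: float = 250.0
    frag_len_sd: float = 60.0
    frag_min_len: int = 100
    three_prime_bias: float = 2.0
    error_rate: float = 0.0
    expressed_fraction_per_library: float = 0.6
    intron_prob: float = 0.7
    intron_len_range: tuple[int, int] = (80, 500)
    max_introns: int = 2
    asgr_fraction: float = 0.25
    panel_spec: PanelSpec = field(default_factory=PanelSpec)
    library_a_id: str = "PS26"
    library_b_id: str = "BC8"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "d_homeolog",
            "d_species",
            "error_rate",
            "expressed_fraction_per_library",
            "intron_prob",
            "asgr_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_donor_chromosomes < 1 or self.donor_ploidy_copies < 1:
            raise ConfigurationError("need >= 1 chromosome and >= 1 copy")
        if self.frag_mean_len <= 0 or self.frag_min_len <= 0:
            raise ConfigurationError("fragment lengths must be positive")
        if self.three_prime_bias < 0:
            raise ConfigurationError("three_prime_bias must be >= 0")
        lo, hi = self.transcript_len
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid transcript_len range")
        chroms = {f"chr{i + 1}" for i in range(self.n_donor_chromosomes)}
        if self.alien_chromosome_id not in chroms:
            raise ConfigurationError(
                f"alien_chromosome_id {self.alien_chromosome_id!r} not among {sorted(chroms)}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "panel_spec" in d:
            d["panel_spec"] = PanelSpec(**d["panel_spec"])
        for key in ("transcript_len", "intron_len_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted contig."""

    contig_id: str
    origin: str
    gene_id: str
    chromosome_id: str
    copy_id: str
    library_id: str
    frag_start: int
    frag_end: int


@dataclass(frozen=True)
class GenotypeGenome:
    """One panel individual: intron-bearing genomic templates per locus."""

    genotype_id: str
    class_label: str  # donor | recurrent | relative | addition_apo | addition_sex | f1_apo | f1_sex
    sequences: tuple[tuple[str, str], ...]  # (locus_id, sequence)


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    chromosome_id: str
    asgr: bool
    exon_intervals: tuple[tuple[int, int], ...]  # on the genomic template
    genomic_len: int


@dataclass
class SimulatedExperiment:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    library_a: list[Contig]
    library_b: list[Contig]
    panel: list[GenotypeGenome]
    truth: pd.DataFrame  # TRUTH_COLUMNS
    genes: list[_Gene]
    # genomic template per (gene_id, haplotype); haplotypes: cp0..cpK, recurrent, relative
    genomes: dict[tuple[str, str], str]

    def truth_records(self) -> list[TruthRecord]:
        return [TruthRecord(**row) for row in self.truth.to_dict("records")]

    def write_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def fragment_transcript(
    transcript_len: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_fragments: int = 1,
) -> list[tuple[int, int]]:
    """Sample 3'-biased fragment intervals from a transcript.

    Fragment length ~ Normal(frag_mean_len, frag_len_sd) clipped to
    [frag_min_len, transcript_len]. The start position s (0-based, 5'->3')
    is drawn with weight exp(-beta * u) where u = (S - s)/S is the
    normalized distance from the 3'-most feasible start S = L - f; beta = 0
    gives the uniform distribution and larger beta shifts mass to the 3'
    end. Transcripts shorter than frag_min_len yield an empty list.
    """
    L = int(transcript_len)
    if L < config.frag_min_len:
        return []
    out = []
    beta = config.three_prime_bias
    for _ in range(n_fragments):
        f = int(round(rng.normal(config.frag_mean_len, config.frag_len_sd)))
        f = max(config.frag_min_len, min(L, f))
        smax = L - f
        if smax == 0:
            s = 0
        elif beta == 0:
            s = int(rng.integers(0, smax + 1))
        else:
            u = (smax - np.arange(smax + 1)) / smax
            w = np.exp(-beta * u)
            s = int(rng.choice(smax + 1, p=w / w.sum()))
        out.append((s, s + f))
    return out


def _extract_transcript(genomic: str, exons: tuple[tuple[int, int], ...]) -> str:
    return "".join(genomic[a:b] for a, b in exons)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate both contig libraries, the genotype panel, and ground truth.

    Library A (donor) samples one contig per expressed gene copy; library B
    (addition line) samples recurrent-parent contigs for every gene plus
    contigs from the alien chromosome's donor haplotype, identical by
    descent before optional sequencing error. Reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_copies = config.donor_ploidy_copies

    genes: list[_Gene] = []
    genomes: dict[tuple[str, str], str] = {}
    alien_gene_ids: list[str] = []

    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        chrom = f"chr{(i % config.n_donor_chromosomes) + 1}"
        t_lo, t_hi = config.transcript_len
        t_len = int(rng.integers(t_lo, t_hi + 1))
        transcript = _dna.random_dna(rng, t_len)
        # intron placement on the reference (carrier) haplotype; positions are
        # shared across haplotypes (substitution-only divergence model)
        introns: list[tuple[int, str]] = []
        if rng.random() < config.intron_prob and t_len > 40:
            k = int(rng.integers(1, config.max_introns + 1))
            pos = sorted(rng.choice(np.arange(20, t_len - 20), size=k, replace=False))
            for p in pos:
                ilen = int(rng.integers(*config.intron_len_range))
                introns.append((int(p), _dna.random_dna(rng, ilen)))
        pieces = []
        exon_intervals = []
        cursor_t = 0
        cursor_g = 0
        for p, iseq in introns:
            pieces.append(transcript[cursor_t:p])
            exon_intervals.append((cursor_g, cursor_g + (p - cursor_t)))
            cursor_g += p - cursor_t
            pieces.append(iseq)
            cursor_g += len(iseq)
            cursor_t = p
        pieces.append(transcript[cursor_t:])
        exon_intervals.append((cursor_g, cursor_g + (t_len - cursor_t)))
        cursor_g += t_len - cursor_t
        genomic_ref = "".join(pieces)
        exons = tuple(exon_intervals)

        gene = _Gene(
            gene_id=gene_id,
            chromosome_id=chrom,
            asgr=False,  # flagged below
            exon_intervals=exons,
            genomic_len=len(genomic_ref),
        )
        genes.append(gene)
        if chrom == config.alien_chromosome_id:
            alien_gene_ids.append(gene_id)

        # haplotypes: copy 0 is the carrier-chromosome reference haplotype
        genomes[(gene_id, "cp0")] = genomic_ref
        for j in range(1, n_copies):
            genomes[(gene_id, f"cp{j}")] = _dna.mutate(
                genomic_ref, config.d_homeolog, rng
            )
        genomes[(gene_id, "recurrent")] = _dna.mutate(
            genomic_ref, config.d_species, rng
        )
        genomes[(gene_id, "relative")] = _dna.mutate(genomic_ref, config.d_species, rng)

    # ASGR subset of alien-chromosome genes
    n_asgr = int(round(config.asgr_fraction * len(alien_gene_ids)))
    asgr_ids = set()
    if alien_gene_ids and n_asgr > 0:
        asgr_ids = set(
            rng.choice(np.array(alien_gene_ids), size=n_asgr, replace=False).tolist()
        )
    genes = [dataclasses.replace(g, asgr=g.gene_id in asgr_ids) for g in genes]

    def transcript_of(gene: _Gene, hap: str) -> str:
        return _extract_transcript(genomes[(gene.gene_id, hap)], gene.exon_intervals)

    # --- contig libraries -------------------------------------------------
    library_a: list[Contig] = []
    library_b: list[Contig] = []
    truth_rows: list[dict] = []
    p_expr = config.expressed_fraction_per_library

    serial_a = 0
    for gene in genes:
        for j in range(n_copies):
            if rng.random() >= p_expr:
                continue
            tr = transcript_of(gene, f"cp{j}")
            for s, e in fragment_transcript(len(tr), config, rng):
                serial_a += 1
                cid = f"{config.library_a_id}_c{serial_a}"
                seq = _dna.mutate(tr[s:e], config.error_rate, rng)
                library_a.append(
                    Contig(cid, config.library_a_id, seq, read_count=None)
                )
                origin = (
                    ORIGIN_ALIEN
                    if (gene.chromosome_id == config.alien_chromosome_id and j == 0)
                    else ORIGIN_DONOR_OTHER
                )
                truth_rows.append(
                    dict(
                        contig_id=cid,
                        origin=origin,
                        gene_id=gene.gene_id,
                        chromosome_id=gene.chromosome_id,
                        copy_id=f"cp{j}",
                        library_id=config.library_a_id,
                        frag_start=s,
                        frag_end=e,
                    )
                )

    serial_b = 0
    for gene in genes:
        # recurrent-parent transcripts (all genes)
        if rng.random() < p_expr:
            tr = transcript_of(gene, "recurrent")
            for s, e in fragment_transcript(len(tr), config, rng):
                serial_b += 1
                cid = f"{config.library_b_id}_c{serial_b}"
                seq = _dna.mutate(tr[s:e], config.error_rate, rng)
                library_b.append(
                    Contig(cid, config.library_b_id, seq, read_count=None)
                )
                truth_rows.append(
                    dict(
                        contig_id=cid,
                        origin=ORIGIN_RECURRENT,
                        gene_id=gene.gene_id,
                        chromosome_id=gene.chromosome_id,
                        copy_id="recurrent",
                        library_id=config.library_b_id,
                        frag_start=s,
                        frag_end=e,
                    )
                )
        # alien-chromosome donor haplotype, identical by descent
        if gene.chromosome_id == config.alien_chromosome_id and rng.random() < p_expr:
            tr = transcript_of(gene, "cp0")
            for s, e in fragment_transcript(len(tr), config, rng):
                serial_b += 1
                cid = f"{config.library_b_id}_c{serial_b}"
                seq = _dna.mutate(tr[s:e], config.error_rate, rng)
                library_b.append(
                    Contig(cid, config.library_b_id, seq, read_count=None)
                )
                truth_rows.append(
                    dict(
                        contig_id=cid,
                        origin=ORIGIN_ALIEN,
                        gene_id=gene.gene_id,
                        chromosome_id=gene.chromosome_id,
                        copy_id="cp0",
                        library_id=config.library_b_id,
                        frag_start=s,
                        frag_end=e,
                    )
                )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    # --- genotype panel ---------------------------------------------------
    def loci(haps: dict[str, str]) -> tuple[tuple[str, str], ...]:
        """haps maps gene_id -> haplotype name; deterministic locus order."""
        out = []
        for gene in genes:
            hap = haps.get(gene.gene_id)
            if hap is None:
                continue
            out.append((f"{gene.gene_id}|{hap}", genomes[(gene.gene_id, hap)]))
        return tuple(out)

    def donor_loci() -> tuple[tuple[str, str], ...]:
        out = []
        for gene in genes:
            for j in range(n_copies):
                out.append((f"{gene.gene_id}|cp{j}", genomes[(gene.gene_id, f"cp{j}")]))
        return tuple(out)

    recurrent_map = {g.gene_id: "recurrent" for g in genes}
    alien_map = {
        g.gene_id: "cp0"
        for g in genes
        if g.chromosome_id == config.alien_chromosome_id
    }
    alien_nonasgr_map = {
        g.gene_id: "cp0"
        for g in genes
        if g.chromosome_id == config.alien_chromosome_id and not g.asgr
    }

    panel: list[GenotypeGenome] = [
        GenotypeGenome("PS26", "donor", donor_loci()),
        GenotypeGenome("IA4X", "recurrent", loci(recurrent_map)),
        GenotypeGenome("N37", "relative", loci({g.gene_id: "relative" for g in genes})),
    ]
    ps = config.panel_spec
    for i in range(ps.n_addition_apo):
        panel.append(
            GenotypeGenome(
                f"BC8_apo_{i + 1}",
                "addition_apo",
                loci({**recurrent_map, **alien_map}),
            )
        )
    for i in range(ps.n_addition_sex):
        panel.append(
            GenotypeGenome(f"BC8_sex_{i + 1}", "addition_sex", loci(recurrent_map))
        )
    for i in range(ps.n_f1_apo):
        panel.append(
            GenotypeGenome(
                f"F1_apo_{i + 1}", "f1_apo", loci({**recurrent_map, **alien_map})
            )
        )
    for i in range(ps.n_f1_sex):
        panel.append(
            GenotypeGenome(
                f"F1_sex_{i + 1}",
                "f1_sex",
                loci({**recurrent_map, **alien_nonasgr_map}),
            )
        )

    return SimulatedExperiment(
        config=config,
        library_a=library_a,
        library_b=library_b,
        panel=panel,
        truth=truth,
        genes=genes,
        genomes=genomes,
    )
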