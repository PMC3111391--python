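# Methods

## The comparison strategy

A chromosome addition line carries one whole donor chromosome in the genomic
background of a recurrent parent. Transcripts expressed from that alien
chromosome are present in both the donor's and the addition line's
transcriptome and — being identical by descent (IBD) — should be *identical
in sequence*, whereas orthologous transcripts of the two species differ by
ordinary interspecific divergence. `alienscan` operationalizes this as a
funnel:

1. **scan** (`matchscan`): every maximal exact common substring of length
   ≥ `min_exact_len` (default 100 bp) between the donor contig library
   (queries) and the addition-line library (subjects), on both strands.
   Matches are found by shared-window seeding with window size equal to
   `min_exact_len`; any qualifying common substring necessarily contains a
   shared window on its diagonal, so the enumeration is exhaustive (a
   property the test suite checks against a quadratic oracle). Each hit is
   scored under ungapped match/mismatch scoring (+1/−2) and assigned a
   Karlin–Altschul E-value, E = K·m·n·e^(−λS), with λ = 1.28 nats, K = 0.46
   (the standard ungapped values for +1/−2), m = query length and n = total
   subject-library length. Hits are kept when identity ≥ `min_identity`
   (1.0), length ≥ 100 bp and E ≤ `e_threshold_primary` (10⁻¹⁰⁰; "e^-100"
   is read as 1e-100, the standard notation — at default library sizes this
   E-cutoff, not the 100 bp rule, is the binding constraint, admitting
   perfect matches of roughly ≥ 190 bp).
2. **verify** (`pairverify`): each candidate pair (deduplicated over
   multiple HSPs; best-scoring strand kept, '+' on ties) is aligned
   end-gap-free over the full contigs (match +1, mismatch −2, gap −4; N
   mismatches everything, including N). A pair is *accepted* only when a
   zero-mismatch, zero-internal-gap, flush overlay attains the optimal
   alignment score — i.e. the contigs agree over their entire mutual
   overlap. This criterion is traceback-independent; the particular scoring
   values do not affect it. `rejected_nonextension` is reserved for
   degenerate alignments with no positive-scoring overlap; under
   free-end-gap global alignment every non-degenerate optimum is flush.
3. **markers** (`markers`): each verified candidate is screened for
   uniqueness within both transcriptomes (16 bp exact seeds, ungapped
   X-drop extension, E ≤ 10⁻²⁵), which also yields its *discriminative
   positions* — candidate offsets at which every similar contig differs. A
   SCAR-style primer-tag pair (20 bp tags) is placed maximizing
   discriminative positions inside the 3′-terminal 15 bases of each tag,
   with amplicon size within 100–450 bp on the transcript; when an
   off-target context (the recurrent-parent genome, if available) is
   supplied, placements are tried in score order and the first one that
   does not amplify any context sequence is kept. In-silico PCR uses a
   deliberately simple surrogate binding model: a primer binds iff its
   3′-terminal 15 bases match exactly and at most 2 mismatches occur in the
   remaining 5; convergent site pairs with products of 50–2000 bp are
   reported. Panel screening produces +/− calls per genotype, and the
   linkage rules are: *carrier-linked* — amplification from the donor and
   every apomictic addition-line segregant but neither the recurrent parent
   nor any sexual segregant (the third relative may go either way);
   *ASGR-tight* — additionally every apomictic F1 amplifies and no sexual
   F1 does; *unlinked* — presence in both F1 classes without
   carrier-linkage; *uninformative* — amplification from the recurrent
   parent or nowhere. CAPS polymorphisms are detected by comparing
   fragment-size multisets after cutting amplicons at every recognition-site
   occurrence (cut at site start; HaeIII GGCC and HpyCH4IV ACGT by
   default); presence/absence co-segregation with the apomictic class is
   tested separately (`segregation_check`).
4. **libcompare**: annotation-term counts of the two libraries are compared
   per term with a two-sided Fisher's exact test ("probability ≤ observed"
   convention, via scipy) and Benjamini–Hochberg step-up FDR (via
   statsmodels); the FDR variant is pluggable in principle but BH is the
   default and only shipped method.

## The synthetic experiment

`synthdata.simulate_experiment` plants exactly the structure the strategy
assumes, so every stage can be exercised without external data.

Per gene, a reference genomic template is built: a transcript of uniform
random length (default 300–1200 bp) with 0–2 introns of 80–500 bp inserted
with probability 0.7 (intron-bearing templates matter because real marker
work favors intron-spanning primers; amplicon sizes on genomic templates
exceed transcript expectations accordingly). The reference is the **carrier
haplotype** (copy 0). Other donor homeologs are derived from it at
`d_homeolog` = 0.02 substitutions/site; the recurrent parent and a third
relative species at `d_species` = 0.05 each, independently. Substitutions
are i.i.d. per site and always change the base, so donor-copy-0 vs
recurrent identity is 1 − d_species in expectation. No indels are simulated
by default: the funnel's filters are substitution-sensitive and indel
statistics for this material are not established.

Contigs are single 3′-biased fragments of expressed transcripts (each
gene-copy is expressed in a library with probability 0.6): length ~
Normal(250, 60) clipped to [100, transcript length], start position drawn
with weight e^(−βu) where u is the normalized distance from the 3′-most
feasible start and β = 2 (β = 0 recovers the uniform distribution). The
250 bp scale emulates the *contig* length regime of the verified set
(≈180–450 bp) rather than the raw ~145 bp read length, because contigs —
not reads — are the unit of analysis here and no read-level assembly is
simulated. Optional i.i.d. substitution errors (`error_rate`, default 0)
model residual consensus errors.

Library A (donor) samples all homeolog copies; library B (addition line)
samples the recurrent orthologs of every gene plus the alien chromosome's
copy-0 transcripts *verbatim* — the planted IBD signal. Every contig gets
one truth record (origin alien_ibd / recurrent / donor_non_alien, gene,
chromosome, copy, fragment interval).

The genotype panel holds genomic templates: donor (all copies), recurrent
parent, relative, 4 apomictic + 4 sexual addition-line segregants
(apomictic ones carry the alien chromosome's copy-0 loci), and 10 apomictic
+ 12 sexual F1s. A configurable fraction (default 0.25) of alien-chromosome
genes is flagged as the ASGR subset: apomictic F1s carry the whole carrier
haplotype, sexual F1s carry it minus the ASGR subset. This reproduces the
observed phenomenology — markers from non-ASGR carrier genes amplify both
F1 classes (carrier-linked only), ASGR-subset markers co-segregate with
apomixis (ASGR-tight).

What the generator does **not** emulate: read-level 454 error structure
(homopolymer errors), assembly chimeras and allele splitting, paralog
families beyond the fixed homeolog count, expression-level variation,
length-dependent expression sampling, and real primer thermodynamics.
Passing tests therefore certify the *logic* of the funnel and rule engine
under the stated divergence model, not robustness to assembler artifacts or
PCR chemistry.

## Detectability and recovery metrics

`evaluate_against_truth` calls an IBD contig pair *detectable* when its
fragment-interval overlap passes **both** primary scan thresholds: overlap
≥ `min_exact_len` and Karlin–Altschul E (at the pair's query length and
subject-library size) ≤ `e_threshold_primary`. With error-free contigs,
every detectable pair is found by the scan and accepted by verification, so
sensitivity is 1.0 by construction — the tests check exactly this, across
20 seeds. A carrier-linked call counts as a false positive when the
verified partner contig is of recurrent origin (chance identity between
species orthologs — the error mode the zero-mismatch rule controls). A
donor *homeolog* that happens to be identical to the carrier haplotype over
the whole overlap is counted as a true carrier call: its marker genuinely
detects carrier-chromosome sequence.

## Numerical and interface choices

- Internal coordinates are 0-based half-open; the tabular hit format is the
  12-column BLAST outfmt-6 dialect with 1-based inclusive coordinates and
  descending subject coordinates on the minus strand.
- E-values are computed in log space and underflow to 0.0 for very high
  scores, which is harmless for thresholding.
- FASTA input is normalized: upper-case, every non-ACGT character becomes
  N, and N never participates in any exact match or perfect overlay.
- A simple homopolymer/dinucleotide mask (≥12 bp runs → N) is available
  behind the `mask` flag of the scan for sensitivity analysis of
  low-complexity inflation; it is off by default.
- Deterministic orderings everywhere: hits by (query, subject, qstart,
  strand), pair verdicts by (query, subject), marker placements by
  (score desc, forward start, amplicon size).
- All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical seed + config give byte-identical
  FASTA/TSV outputs (timestamps live in a separate manifest field).

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run synthetic experiments of
60–200 genes (a few hundred contigs, tens of kb per library), 1000
small random instances for the scan-vs-enumeration equivalence, 150 random
pairs for the alignment-oracle comparison, and 100-replicate calibration
studies for the FDR stage. These sizes were chosen so each check carries
clear statistical power while the whole suite remains quick to run on a
laptop; the pipeline itself is routinely run on libraries of tens of
thousands of contigs (tens of Mb), for which the published-data funnel
check in `tests/test_acceptance.py` is the reference configuration.

## Known limitations

- The surrogate PCR binding model (exact 3′ window + ≤2 mismatches
  elsewhere) is an invention; real annealing behavior depends on primer
  thermodynamics that are out of scope, so in-silico +/− calls should be
  read as best-case locus logic, not assay predictions.
- The published-data funnel counts (118/115/116) depend on the original
  BLAST's exact filter semantics (possible dust masking, E-value edge
  effects); the zero-mismatch verification counts are the robust targets.
- One recurrent haplotype is modeled per gene although the recurrent parent
  is tetraploid; within-species allelic variation is ignored.
- `compare_term_libraries` tests each term independently; terms related
  through an ontology graph are not propagated or decorrelated.
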