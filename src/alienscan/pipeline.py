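"""End-to-end orchestration: simulate -> scan -> verify -> markers -> report.

Each stage reads and writes plain files (FASTA/TSV/JSON) under the run's
output directory so any stage can be re-run standalone; the manifest records
the funnel counts (comparisons -> verified inter-genotype contigs -> linkage
classes), input digests and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import markers as mk
from . import matchscan, pairverify, synthdata
from .errors import DataIntegrityError
from .seqio import (
    Contig,
    PipelineConfig,
    ScoringParams,
    read_fasta,
    write_fasta,
    write_hits_tabular,
)

__all__ = [
    "RunManifest",
    "RunResult",
    "run_all",
    "evaluate_against_truth",
    "minimum_detectable_overlap",
]


@dataclass
class RunManifest:
    config_hash: str
    seed: Optional[int]
    input_digests: dict = field(default_factory=dict)
    stage_outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self, include_timestamps: bool = True) -> str:
        d = dataclasses.asdict(self)
        if not include_timestamps:
            d.pop("timestamps")
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class RunResult:
    manifest: RunManifest
    library_a: list[Contig]
    library_b: list[Contig]
    hits: list
    comparisons: list
    scan_summary: matchscan.ScanSummary
    alignments: list[pairverify.PairAlignment]
    accepted: list[pairverify.PairAlignment]
    candidate_summary: pairverify.CandidateSummary
    markers: list[mk.Marker]
    design_failures: list[mk.DesignFailure]
    profiles: list[mk.AmplificationProfile]
    linkage: list[mk.LinkageCall]
    experiment: Optional[synthdata.SimulatedExperiment] = None
    report_text: str = ""


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_alignments_tsv(alignments, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "query_id\tsubject_id\tstrand\toverlap_len\tn_mismatch\t"
            "n_internal_gap\tflush_left\tflush_right\tscore\tverdict\n"
        )
        for p in alignments:
            fh.write(
                f"{p.query_id}\t{p.subject_id}\t{p.strand}\t{p.overlap_len}\t"
                f"{p.n_mismatch}\t{p.n_internal_gap}\t{int(p.flush_left)}\t"
                f"{int(p.flush_right)}\t{p.score:g}\t{p.verdict.value}\n"
            )


def _funnel_report(scan_summary, cand_summary, linkage) -> str:
    lines = [
        "alien-transcript discovery funnel",
        "=================================",
        f"comparisons (100% identity, length/E filter): {scan_summary.n_comparisons}",
        f"  unique query contigs:   {scan_summary.n_unique_queries}",
        f"  unique subject contigs: {scan_summary.n_unique_subjects}",
        f"verified inter-genotype contigs (zero mismatches): {cand_summary.n_accepted_pairs}",
    ]
    if cand_summary.n_accepted_pairs:
        lines.append(
            f"  overlap bp: mean {cand_summary.mean_overlap_bp} "
            f"(range {cand_summary.min_overlap}-{cand_summary.max_overlap})"
        )
    if linkage:
        by_class: dict[str, int] = {}
        for call in linkage:
            by_class[call.call.value] = by_class.get(call.call.value, 0) + 1
        lines.append("linkage calls:")
        for cls in ("carrier_linked", "asgr_tight", "unlinked", "uninformative"):
            if cls in by_class:
                lines.append(f"  {cls}: {by_class[cls]}")
    return "\n".join(lines) + "\n"


def run_all(
    config: PipelineConfig,
    sim_config: Optional[synthdata.SimulationConfig] = None,
    fasta_a: Optional[str | Path] = None,
    fasta_b: Optional[str | Path] = None,
    panel: Optional[Sequence] = None,
    out_dir: Optional[str | Path] = None,
    expected_counts: Optional[tuple[int, int]] = None,
) -> RunResult:
    """Execute the full strategy on synthetic or on-disk libraries.

    Provide either ``sim_config`` (synthetic run; the panel comes from the
    simulation) or ``fasta_a``/``fasta_b`` paths (+ optional ``panel``).
    ``expected_counts`` optionally asserts the two libraries' record counts
    on load. Marker stages are skipped when no panel genomes are available.
    """
    t0 = time.time()
    manifest = RunManifest(config_hash=config.config_hash(),
                           seed=sim_config.seed if sim_config else None)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    experiment = None
    if sim_config is not None:
        experiment = synthdata.simulate_experiment(sim_config)
        library_a, library_b = experiment.library_a, experiment.library_b
        panel = experiment.panel
        if out is not None:
            write_fasta(library_a, out / "library_A.fasta")
            write_fasta(library_b, out / "library_B.fasta")
            experiment.write_truth_tsv(out / "truth.tsv")
            (out / "sim_config.json").write_text(sim_config.to_json())
            manifest.stage_outputs["library_a"] = "library_A.fasta"
            manifest.stage_outputs["library_b"] = "library_B.fasta"
            manifest.stage_outputs["truth"] = "truth.tsv"
    else:
        if fasta_a is None or fasta_b is None:
            raise DataIntegrityError("need either sim_config or two FASTA paths")
        library_a = read_fasta(fasta_a)
        library_b = read_fasta(fasta_b)
        manifest.input_digests["library_a"] = _digest_file(Path(fasta_a))
        manifest.input_digests["library_b"] = _digest_file(Path(fasta_b))
        if expected_counts is not None:
            exp_a, exp_b = expected_counts
            if len(library_a) != exp_a or len(library_b) != exp_b:
                raise DataIntegrityError(
                    f"record counts {len(library_a)}/{len(library_b)} do not match "
                    f"expected {exp_a}/{exp_b}"
                )
    manifest.counts["contigs_a"] = len(library_a)
    manifest.counts["contigs_b"] = len(library_b)

    # --- scan -------------------------------------------------------------
    hits = matchscan.find_exact_matches(
        library_a, library_b, config.min_exact_len, config.scoring
    )
    filt = matchscan.filter_candidate_pairs(hits, config)
    comparisons, scan_summary = filt.comparisons, filt.summary
    manifest.counts["comparisons"] = scan_summary.n_comparisons
    manifest.counts["unique_queries"] = scan_summary.n_unique_queries
    manifest.counts["unique_subjects"] = scan_summary.n_unique_subjects
    if out is not None:
        write_hits_tabular([c.hit for c in comparisons], out / "comparisons.tsv",
                           config.scoring)
        (out / "scan_summary.json").write_text(
            json.dumps(dataclasses.asdict(scan_summary), indent=2)
        )
        manifest.stage_outputs["comparisons"] = "comparisons.tsv"

    # --- verify -----------------------------------------------------------
    alignments = pairverify.align_comparisons(comparisons, library_a, library_b)
    accepted = [p for p in alignments if p.verdict is pairverify.Verdict.accepted]
    read_counts = {
        c.contig_id: c.read_count
        for c in (*library_a, *library_b)
        if c.read_count is not None
    }
    cand_summary = pairverify.summarize_candidates(accepted, read_counts or None)
    manifest.counts["verified_pairs"] = cand_summary.n_accepted_pairs
    if out is not None:
        _write_alignments_tsv(alignments, out / "alignments.tsv")
        a_index = {c.contig_id: c for c in library_a}
        write_fasta(
            [a_index[p.query_id] for p in accepted
             if p.query_id in a_index],
            out / "verified_candidates.fasta",
        )
        (out / "verify_summary.json").write_text(
            json.dumps(dataclasses.asdict(cand_summary), indent=2)
        )
        manifest.stage_outputs["alignments"] = "alignments.tsv"
        manifest.stage_outputs["verified_candidates"] = "verified_candidates.fasta"

    # --- markers ----------------------------------------------------------
    designed: list[mk.Marker] = []
    failures: list[mk.DesignFailure] = []
    profiles: list[mk.AmplificationProfile] = []
    linkage: list[mk.LinkageCall] = []
    if panel:
        a_index = {c.contig_id: c for c in library_a}
        panel_design = {g.genotype_id: g.class_label for g in panel}
        # markers must not amplify the recurrent parent: its genome (when in
        # the panel) is the off-target context for primer placement
        context = [
            seq
            for g in panel
            if g.class_label == "recurrent"
            for _, seq in g.sequences
        ]
        for pa in accepted:
            candidate = a_index[pa.query_id]
            report = mk.uniqueness_screen(
                candidate, library_a, library_b, config, partner_id=pa.subject_id
            )
            result = mk.design_marker(
                candidate, report, config, ortholog_context=context or None
            )
            if isinstance(result, mk.DesignFailure):
                failures.append(result)
                continue
            designed.append(result)
            profile = mk.screen_panel(result, panel, config)
            profiles.append(profile)
            linkage.append(mk.classify_linkage(profile, panel_design))
        manifest.counts["markers_designed"] = len(designed)
        by_class: dict[str, int] = {}
        for call in linkage:
            by_class[call.call.value] = by_class.get(call.call.value, 0) + 1
        manifest.counts["linkage_by_class"] = by_class
        if out is not None:
            with open(out / "markers.tsv", "w") as fh:
                fh.write(
                    "marker_id\tsource_candidate\tfwd_tag\trev_tag\t"
                    "fwd_start\trev_end\texpected_size\n"
                )
                for m in designed:
                    fh.write(
                        f"{m.marker_id}\t{m.source_candidate}\t{m.fwd_tag}\t"
                        f"{m.rev_tag}\t{m.fwd_start}\t{m.rev_end}\t{m.expected_size}\n"
                    )
            genotype_ids = [g.genotype_id for g in panel]
            with open(out / "profiles.tsv", "w") as fh:
                fh.write("marker_id\t" + "\t".join(genotype_ids) + "\n")
                sym = {"plus": "+", "minus": "-", "fail": "pf"}
                for profile in profiles:
                    fh.write(
                        profile.marker_id
                        + "\t"
                        + "\t".join(sym[profile.calls[g]] for g in genotype_ids)
                        + "\n"
                    )
            with open(out / "linkage.tsv", "w") as fh:
                fh.write("marker_id\tcall\n")
                for call in linkage:
                    fh.write(f"{call.marker_id}\t{call.call.value}\n")
            manifest.stage_outputs["markers"] = "markers.tsv"
            manifest.stage_outputs["profiles"] = "profiles.tsv"
            manifest.stage_outputs["linkage"] = "linkage.tsv"

    report_text = _funnel_report(scan_summary, cand_summary, linkage)
    manifest.timestamps["started"] = t0
    manifest.timestamps["finished"] = time.time()
    if out is not None:
        (out / "report.txt").write_text(report_text)
        (out / "manifest.json").write_text(manifest.to_json())
        (out / "pipeline_config.json").write_text(config.to_json())
        manifest.stage_outputs["report"] = "report.txt"

    return RunResult(
        manifest=manifest,
        library_a=library_a,
        library_b=library_b,
        hits=hits,
        comparisons=comparisons,
        scan_summary=scan_summary,
        alignments=alignments,
        accepted=accepted,
        candidate_summary=cand_summary,
        markers=designed,
        design_failures=failures,
        profiles=profiles,
        linkage=linkage,
        experiment=experiment,
        report_text=report_text,
    )


def minimum_detectable_overlap(
    query_len: int, subject_total_len: int, config: PipelineConfig
) -> int:
    """Smallest perfect-match length passing both primary scan thresholds.

    The E-value cutoff, not the raw length rule, is usually binding: a
    perfect match of length l scores l*reward, so it passes when
    K*m*n*exp(-lambda*l*reward) <= E_threshold.
    """
    p = config.scoring
    l_e = (
        math.log(p.k_const * max(query_len, 1) * max(subject_total_len, 1))
        - math.log(config.e_threshold_primary)
    ) / (p.lambda_ * p.reward)
    return max(config.min_exact_len, math.ceil(l_e))


def evaluate_against_truth(
    result: RunResult,
    truth: Optional[pd.DataFrame] = None,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Per-stage recovery metrics of a run against the simulation ground truth.

    A pair of contigs (one per library) from the same gene's carrier
    haplotype is *detectable* when its fragment-interval overlap passes both
    primary scan thresholds (length and E-value). Sensitivity is the
    fraction of detectable identical-by-descent pairs that end up verified;
    precision is the identical-by-descent fraction of reported pairs
    at each stage. Also reports carrier-linkage confusion when the marker
    stage ran.
    """
    if truth is None:
        if result.experiment is None:
            raise DataIntegrityError("no truth table available for this run")
        truth = result.experiment.truth
    config = config or PipelineConfig()
    known = set(truth["contig_id"])
    for contig in (*result.library_a, *result.library_b):
        if contig.contig_id not in known:
            raise DataIntegrityError(f"contig {contig.contig_id!r} absent from truth")

    lib_a_ids = {c.contig_id for c in result.library_a}
    subject_total = sum(len(c) for c in result.library_b)
    lengths = {c.contig_id: len(c) for c in (*result.library_a, *result.library_b)}

    t = truth.set_index("contig_id")
    alien = truth[truth["origin"] == synthdata.ORIGIN_ALIEN]
    alien_a = alien[alien["contig_id"].isin(lib_a_ids)]
    alien_b = alien[~alien["contig_id"].isin(lib_a_ids)]

    detectable: set[tuple[str, str]] = set()
    for ra in alien_a.itertuples(index=False):
        for rb in alien_b.itertuples(index=False):
            if ra.gene_id != rb.gene_id:
                continue
            ov = min(ra.frag_end, rb.frag_end) - max(ra.frag_start, rb.frag_start)
            if ov < config.min_exact_len:
                continue
            need = minimum_detectable_overlap(
                lengths[ra.contig_id], subject_total, config
            )
            if ov >= need:
                detectable.add((ra.contig_id, rb.contig_id))

    def is_ibd_pair(qid: str, sid: str) -> bool:
        return (
            t.loc[qid, "origin"] == synthdata.ORIGIN_ALIEN
            and t.loc[sid, "origin"] == synthdata.ORIGIN_ALIEN
            and t.loc[qid, "gene_id"] == t.loc[sid, "gene_id"]
        )

    scan_pairs = {(c.query_id, c.subject_id) for c in result.comparisons}
    accepted_pairs = {(p.query_id, p.subject_id) for p in result.accepted}

    scan_tp = sum(1 for q, s in scan_pairs if is_ibd_pair(q, s))
    acc_tp = sum(1 for q, s in accepted_pairs if is_ibd_pair(q, s))

    metrics = {
        "n_detectable_ibd_pairs": len(detectable),
        "n_scan_pairs": len(scan_pairs),
        "n_accepted_pairs": len(accepted_pairs),
        "scan_precision": scan_tp / len(scan_pairs) if scan_pairs else None,
        "verify_precision": acc_tp / len(accepted_pairs) if accepted_pairs else None,
        "sensitivity": (
            len(detectable & accepted_pairs) / len(detectable) if detectable else None
        ),
        "missed_detectable": sorted(detectable - accepted_pairs),
    }

    if result.linkage:
        # a carrier-linked call is false when the verified partner contig is
        # of recurrent (inter-species) origin: chance identity between
        # orthologs, the error mode the zero-mismatch rule exists to control.
        # A donor-homeolog partner identical to the carrier haplotype over
        # the whole overlap yields a marker that genuinely detects carrier-
        # chromosome sequence, so it counts as true.
        partners: dict[str, list[str]] = {}
        for p in result.accepted:
            partners.setdefault(p.query_id, []).append(p.subject_id)
        marker_source = {m.marker_id: m.source_candidate for m in result.markers}
        fp_carrier = 0
        tp_carrier = 0
        for call in result.linkage:
            src = marker_source[call.marker_id]
            carrierish = call.call in (
                mk.LinkageClass.carrier_linked,
                mk.LinkageClass.asgr_tight,
            )
            if not carrierish:
                continue
            subject_origins = {
                t.loc[s, "origin"] for s in partners.get(src, [])
            }
            if subject_origins <= {synthdata.ORIGIN_RECURRENT}:
                fp_carrier += 1
            else:
                tp_carrier += 1
        metrics["carrier_linked_true"] = tp_carrier
        metrics["carrier_linked_false"] = fp_carrier
    return metrics
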