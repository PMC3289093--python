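"""End-to-end orchestration of the comparative-transcriptomics pipeline.

Stage order: simulate (or load) → trim → rRNA screen → EST screen and
assembly → read alignment to EST-unigenes → de novo assembly of unaligned
reads → meta-assembly → counting and RPKM → differential expression →
target overlap (when a target set is configured).  Every stage writes its
artifact under the run directory, and the run report restates all
parameter values so a run can be reproduced from the report alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, de, overlap as overlap_mod, qc, quantify, seqio, synthetic
from .config import RunConfig, validate_config
from .synthetic import LIB_REFERENCE, LIB_TEST

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute every stage on a simulated dataset and return the run report."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(config.seed).spawn(8)]
    report: dict = {"config": _config_dict(config), "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - report failing stage
                raise StageError(name, exc) from exc
        return wrap

    # --- simulate ------------------------------------------------------
    s = config.simulate

    def _simulate():
        transcripts = synthetic.generate_transcriptome(
            s.n_genes, s.len_min, s.len_max, s.gc, seed=seeds[0]
        )
        contaminants = synthetic.generate_contaminants(
            s.n_rrna, s.n_vector, s.n_bacterial, s.contaminant_len, seed=seeds[1]
        )
        ests, est_origins = synthetic.simulate_ests(
            transcripts, s.n_ests, s.est_len_mean, s.est_error_rate, seed=seeds[2]
        )
        design = synthetic.DEDesign(
            fraction_up=s.fraction_up,
            fraction_down=s.fraction_down,
            fold_values=tuple(s.fold_values),
            depth=s.depth,
        )
        lib1, lib2, truth = synthetic.simulate_libraries(
            transcripts, design,
            read_len=s.read_len, error_rate=s.read_error_rate,
            rrna_fraction=s.rrna_fraction, contaminants=contaminants,
            adaptor=s.adaptor, adaptor_rate=s.adaptor_rate, seed=seeds[3],
        )
        seqio.write_fasta(transcripts.records, outdir / "transcripts.fasta")
        seqio.write_fasta(ests, outdir / "ests.fasta")
        seqio.write_fastq(lib1, outdir / f"reads_{LIB_REFERENCE}.fastq")
        seqio.write_fastq(lib2, outdir / f"reads_{LIB_TEST}.fastq")
        synthetic.write_truth_ledger(
            truth, outdir / "truth_genes.tsv", outdir / "truth_reads.tsv"
        )
        return transcripts, contaminants, ests, est_origins, lib1, lib2, truth

    transcripts, contaminants, ests, _, lib1, lib2, truth = stage("simulate")(_simulate)
    report["stages"]["simulate"] = {
        "n_genes": len(transcripts),
        "n_ests": len(ests),
        "reads_" + LIB_REFERENCE: len(lib1),
        "reads_" + LIB_TEST: len(lib2),
    }

    # --- QC ------------------------------------------------------------
    def _qc():
        out = {}
        for lib, reads in ((LIB_REFERENCE, lib1), (LIB_TEST, lib2)):
            trimmed, tstats = qc.trim_reads(
                reads, config.qc.quality_min, s.adaptor, config.qc.min_len
            )
            kept, removed, _ = qc.screen_rrna(
                trimmed, contaminants.rrna, config.qc.max_mismatch
            )
            seqio.write_fastq(kept, outdir / f"clean_{lib}.fastq")
            out[lib] = (kept, tstats, len(removed))
        return out

    cleaned = stage("qc")(_qc)
    report["stages"]["qc"] = {
        lib: {
            "kept": len(kept),
            "adaptor_trimmed": tstats.n_adaptor_trimmed,
            "discarded_short": tstats.n_discarded,
            "rrna_removed": n_rrna,
        }
        for lib, (kept, tstats, n_rrna) in cleaned.items()
    }

    # --- assembly ------------------------------------------------------
    a = config.assembly

    def _assemble():
        clean_ests = assembly.screen_ests(
            ests, contaminants.vector, contaminants.bacterial, contaminants.rrna,
            a.min_clean_len,
        )
        est_unigenes = assembly.assemble_ests(clean_ests, a.min_overlap, a.min_identity)
        all_clean = cleaned[LIB_REFERENCE][0] + cleaned[LIB_TEST][0]
        _, unaligned = assembly.align_reads(all_clean, est_unigenes, a.max_mismatch)
        denovo = assembly.denovo_assemble(unaligned, a.kmer, a.min_contig_len)
        final, id_map = assembly.merge_assemblies(
            est_unigenes, denovo, a.min_overlap, a.min_identity
        )
        seqio.write_fasta(final, outdir / "unigenes.fasta")
        pd.Series(id_map, name="final_id").rename_axis("input_id").to_csv(
            outdir / "id_map.tsv", sep="\t"
        )
        return final

    unigenes = stage("assembly")(_assemble)
    mean_len = (
        round(float(np.mean([u.length for u in unigenes])), 1) if unigenes else 0.0
    )
    report["stages"]["assembly"] = {
        "n_unigenes": len(unigenes),
        "mean_unigene_length": mean_len,
    }

    # --- quantification ------------------------------------------------
    def _quantify():
        hits_by_lib = {}
        for lib in (LIB_REFERENCE, LIB_TEST):
            hits, _ = assembly.align_reads(cleaned[lib][0], unigenes, a.max_mismatch)
            hits_by_lib[lib] = hits
        counts = quantify.count_reads(
            hits_by_lib, unigenes, config.de.counting_policy, seed=seeds[4]
        )
        lengths = {u.unigene_id: u.length for u in unigenes}
        rpkm = quantify.compute_rpkm(counts, lengths)
        quantify.write_expression_table(counts, rpkm, outdir / "expression.tsv")
        return counts, rpkm

    counts, rpkm = stage("quantify")(_quantify)
    report["stages"]["quantify"] = {
        "library_sizes": {k: int(v) for k, v in counts.library_sizes.items()}
    }

    # --- differential expression --------------------------------------
    def _detest():
        result, summary = de.call_de(
            counts, rpkm,
            fdr_max=config.de.fdr_max, min_fold=config.de.min_fold,
            ref_lib=LIB_REFERENCE, test_lib=LIB_TEST,
            pvalue_method=config.de.pvalue_method, n_boot=config.de.n_boot,
            seed=seeds[5],
        )
        table = result.copy()
        table.insert(0, "rpkm_" + LIB_REFERENCE, rpkm.rpkm[LIB_REFERENCE])
        table.insert(1, "rpkm_" + LIB_TEST, rpkm.rpkm[LIB_TEST])
        table.to_csv(outdir / "de_results.tsv", sep="\t")
        return result, summary

    de_result, de_summary = stage("detest")(_detest)
    report["stages"]["detest"] = {
        "n_unigenes": de_summary.n_total,
        "n_tested": de_summary.n_tested,
        "n_up": de_summary.n_up,
        "n_down": de_summary.n_down,
        "pct_up": de_summary.pct_up,
        "pct_down": de_summary.pct_down,
    }

    # --- target overlap (optional inputs) ------------------------------
    o = config.overlap
    if o.targets_path and o.reference_path:
        def _overlap():
            reference = seqio.read_fasta(o.reference_path)
            targets = overlap_mod.TargetSet.from_tsv(o.targets_path)
            homologs = overlap_mod.map_homologs(
                unigenes, reference, o.min_score, o.max_eval
            )
            de_up = set(de_result.index[de_result["call"] == "up"])
            de_down = set(de_result.index[de_result["call"] == "down"])
            summary = overlap_mod.venn_counts(
                de_up, de_down, homologs, targets,
                known_unigenes={u.unigene_id for u in unigenes},
            )
            return summary.as_dict()

        report["stages"]["overlap"] = stage("overlap")(_overlap)

    # --- report ---------------------------------------------------------
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(format_report(report))
    return report


def _config_dict(config: RunConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def format_report(report: dict) -> str:
    """Human-readable run report."""
    lines = ["curdseq run report", "=" * 40]
    for stage_name, info in report["stages"].items():
        lines.append(f"[{stage_name}]")
        for key, val in info.items():
            lines.append(f"  {key}: {val}")
    lines.append("[parameters]")
    lines.append(json.dumps(report["config"], indent=2, sort_keys=True))
    return "\n".join(lines) + "\n"
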