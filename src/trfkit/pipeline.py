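"""End-to-end orchestration: reference construction, mapping, fragment
calling, catalog classification, differential expression and (optionally)
the qPCR biomarker analysis, behind a single run configuration.

Outputs are plain TSV/JSON written under one output directory; a run report
records per-stage counts and the effective parameters so that a run is fully
reproducible from its report. Re-running with the same configuration and
seed overwrites every output identically (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import analyze_cohort
from .caller import CallerParams, call_fragments, quantify_calls, write_calls_tsv
from .catalog import (
    catalog_to_frame,
    classify_catalog,
    counts_matrix,
    merge_identical_sequences,
    summarize,
)
from .de import call_differential, common_de
from .mapping import (
    build_profiles,
    map_two_pass,
    pool_profiles,
    size_filter,
    write_alignments_tsv,
)
from .reference import write_gene_set, write_reference_fasta, write_source_map
from .simulate import (
    SimConfig,
    simulate_fragment_truth,
    simulate_libraries,
    simulate_qpcr_cohort,
    simulate_trna_genes,
    truth_to_json,
    write_reads_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one full (synthetic-preset) pipeline run."""

    out_dir: str = "trf_run"
    seed: int = 0
    flank: int = 50
    min_read_len: int = 15
    max_read_len: int = 35
    caller: CallerParams = field(default_factory=CallerParams)
    alpha: float = 0.05
    strong_fc: float = 4.0
    control_group: str = "NAP"
    cutoff_policy: str = "median"
    sim: SimConfig = field(default_factory=SimConfig)
    write_reads: bool = False
    run_biomarker: bool = True

    def parameters(self) -> dict:
        """Config as a dict, excluding the output location (so that two runs
        of one configuration into different directories are byte-identical)."""
        params = asdict(self)
        params.pop("out_dir")
        return params

    def config_hash(self) -> str:
        payload = json.dumps(self.parameters(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    truth: Any
    truth_counts: pd.DataFrame
    calls: list
    records: list
    summaries: dict
    de_results: dict[str, pd.DataFrame]
    common: pd.DataFrame
    report: dict
    biomarker: Any = None


def _float_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full synthetic-study analysis and write its outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed
    rng = np.random.default_rng(config.seed)
    report: dict[str, Any] = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": config.parameters(),
    }

    # --- stage 1: synthetic cohort -------------------------------------
    genes = simulate_trna_genes(config.sim, rng)
    truth = simulate_fragment_truth(genes, config.sim, rng)
    reads_by_lib, truth_counts = simulate_libraries(truth, config.sim, rng)
    write_gene_set(genes, out / "genes.fa", out / "genes.tsv")
    truth_to_json(truth, out / "truth.json")
    _float_tsv(truth_counts, out / "truth_counts.tsv")
    report["n_genes"] = len(genes)
    report["n_planted_fragments"] = len(truth.fragments)

    # --- stage 2: references -------------------------------------------
    mature, extended = truth.mature_refs, truth.extended_refs
    write_reference_fasta(mature, out / "mature_ref.fa")
    write_reference_fasta(extended, out / "extended_ref.fa")
    write_source_map(mature, out / "mature_sources.tsv")
    report["n_mature_refs"] = len(mature)
    report["n_extended_refs"] = len(extended)

    # --- stage 3: size filter + two-pass mapping ------------------------
    mature_seqs = {r.ref_id: r.sequence for r in mature}
    extended_seqs = {r.ref_id: r.sequence for r in extended}
    all_reads = []
    reads_in = {}
    for lib in sorted(reads_by_lib):
        lib_reads = size_filter(reads_by_lib[lib], config.min_read_len, config.max_read_len)
        reads_in[lib] = {"reads_in": len(reads_by_lib[lib]), "reads_kept": len(lib_reads)}
        all_reads.extend(lib_reads)
        if config.write_reads:
            write_reads_fasta(reads_by_lib[lib], out / f"reads_{lib}.fa")
    mature_aln, extended_aln, unmapped = map_two_pass(all_reads, mature_seqs, extended_seqs)
    unmapped_per_lib: dict[str, int] = {lib: 0 for lib in reads_in}
    for r in unmapped:
        unmapped_per_lib[r.library_id] += 1
    for lib in reads_in:
        reads_in[lib]["reads_unmapped"] = unmapped_per_lib[lib]
        reads_in[lib]["reads_mapped"] = reads_in[lib]["reads_kept"] - unmapped_per_lib[lib]
    report["libraries"] = reads_in
    write_alignments_tsv(mature_aln + extended_aln, out / "alignments.tsv")

    # library totals = total mapped read weight per library (for ppm)
    library_totals: dict[str, float] = {lib: 0.0 for lib in reads_in}
    for aln in mature_aln + extended_aln:
        library_totals[aln.library_id] += aln.weight

    # --- stage 4: fragment calling --------------------------------------
    ref_lengths = {rid: len(s) for rid, s in {**mature_seqs, **extended_seqs}.items()}
    profiles = build_profiles(mature_aln + extended_aln, ref_lengths)
    pooled = pool_profiles(profiles)
    params = config.caller
    params.min_len = config.min_read_len
    params.max_len = config.max_read_len
    calls = call_fragments(pooled, mature_aln + extended_aln, {**mature_seqs, **extended_seqs}, params)
    write_calls_tsv(calls, out / "calls.tsv")
    call_counts = quantify_calls(calls, all_reads)
    report["n_fragment_calls"] = len(calls)

    # --- stage 5: catalog merge + classification ------------------------
    records = merge_identical_sequences(calls, call_counts)
    ext_index = {r.ref_id: r for r in extended}
    records = classify_catalog(records, ext_index)
    summaries = summarize(records)
    catalog_df = catalog_to_frame(records)
    _float_tsv(catalog_df, out / "catalog.tsv", index=False)
    for name, df in summaries.items():
        _float_tsv(df, out / f"summary_{name}.tsv", index=not df.empty and df.index.name is not None)
    report["n_unique_trfs"] = len(records)

    # --- stage 6: differential expression -------------------------------
    counts = counts_matrix(records)
    groups = {lib: lib for lib in counts.columns}  # one pooled library per group
    case_groups = [g for g in config.sim.groups if g != config.control_group]
    de_results: dict[str, pd.DataFrame] = {}
    de_report = {}
    for case in case_groups:
        res = call_differential(
            counts, library_totals, groups, config.control_group, case,
            alpha=config.alpha, strong_fc=config.strong_fc,
        )
        de_results[case] = res
        _float_tsv(res, out / f"de_{config.control_group}_vs_{case}.tsv")
        de_report[case] = {
            "n_tested": int(res["tested"].sum()),
            "n_significant": int(res["significant"].sum()),
            "n_significant_strong": int((res["significant"] & res["strong"]).sum()),
        }
    report["differential_expression"] = de_report
    if len(de_results) >= 2:
        common = common_de(de_results)
        _float_tsv(common, out / "common_de.tsv", index=False)
    else:
        common = pd.DataFrame()

    # --- stage 7: biomarker ---------------------------------------------
    bio = None
    if config.run_biomarker:
        cohort = simulate_qpcr_cohort(config.sim.qpcr, rng)
        _float_tsv(cohort, out / "cohort.tsv", index=False)
        assays = sorted(config.sim.qpcr.dct_base)
        up_assay = "tRF-315" if "tRF-315" in assays else assays[0]
        down_assay = "tRF-544" if "tRF-544" in assays else assays[-1]
        bio = analyze_cohort(
            cohort, up_assay, down_assay, config.sim.qpcr.reference_assay,
            control_group=config.sim.qpcr.groups[0].name,
            cutoff_policy=config.cutoff_policy,
        )
        _float_tsv(bio.expression, out / "biomarker_expression.tsv", index=False)
        _float_tsv(bio.group_tests, out / "biomarker_tests.tsv", index=False)
        _float_tsv(bio.survival, out / "biomarker_survival.tsv", index=False)
        if not bio.survival.empty:
            report["biomarker"] = {
                "logrank_chi_square": float(bio.survival.loc[0, "chi_square"]),
                "logrank_p": float(bio.survival.loc[0, "p"]),
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline complete: %d unique tRFs", report["n_unique_trfs"])
    return RunResult(
        truth=truth,
        truth_counts=truth_counts,
        calls=calls,
        records=records,
        summaries=summaries,
        de_results=de_results,
        common=common,
        report=report,
        biomarker=bio,
    )
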