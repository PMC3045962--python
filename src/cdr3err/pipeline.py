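"""End-to-end orchestration: simulate → extract → profile → model → filter → report.

Two entry points mirror the two study designs:

* :func:`run_monoclonal_audit` — a monoclonal control amplicon sequenced over
  a trifurcating sample×lane design; every deviant read is an error, so the
  full error-profiling battery applies (per-cutoff summaries, substitution
  matrix, lane effects, complementation, direction skew, mismatch culling).
* :func:`run_polyclonal_filter` — a synthetic polyclonal repertoire; no truth
  sequence is assumed and the outputs are clone tables, neighbor tallies over
  a cutoff grid, and ACE richness before/after quality filtering.

All randomness flows from the single ``RunConfig.seed``; rerunning a config
reproduces every output byte for byte. Reports are TSV/JSON only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import richness_report
from .extract import FlankSpec, extract_all, phred_filter, records_to_table, rejections_to_table
from .fastq import write_fastq
from .filtering import (
    DEFAULT_CUTOFF_GRID,
    build_clone_table,
    cull_monoclonal,
    cull_polyclonal,
    direction_skew_screen,
)
from .models import complementation_test
from .profiling import lane_anova, lane_cv, per_nt_substitution_rates, substitution_matrix, summarize
from .simulate import (
    ErrorModel,
    default_error_model,
    example_template,
    preset_study_design,
    random_polyclonal_templates,
    simulate_reads,
    write_truth,
    zipf_abundances,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible run.

    With no input FASTQ the run simulates its own data: a monoclonal audit
    uses the built-in template under the 27-reaction study design; a
    polyclonal run uses a power-law mixture of random clonotypes. ``model``
    overrides the default error process (e.g. ``ErrorModel(sub_rate=0)``
    for a zero-error control run).
    """

    out_dir: Path
    seed: int = 0
    n_reads: int = 27000
    cdr3_length: int = 36
    q_cutoffs: tuple[int, ...] = (0, 10, 20, 30)
    mono_cull_cutoffs: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    poly_cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID
    n_clones: int = 300
    zipf_exponent: float = 1.0
    rare_cutoff: int = 10
    model: ErrorModel | None = None
    save_fastq: bool = False


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_json(data, path: Path) -> None:
    path.write_text(json.dumps(_jsonify(data), indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return len(df)


def run_monoclonal_audit(config: RunConfig) -> dict:
    """Full error audit of a (simulated) monoclonal control; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, int] = {}

    stage = "simulate"
    try:
        template = example_template(config.cdr3_length)
        design = preset_study_design(config.seed)
        model = config.model or default_error_model(template, seed=config.seed)
        reads, truth = simulate_reads(
            template, model, config.n_reads, seed=config.seed, design=design
        )
        if config.save_fastq:
            write_fastq(reads, out / "reads.fastq")
            write_truth(truth, out / "truth.tsv")
            outputs["reads.fastq"] = len(reads)
            outputs["truth.tsv"] = len(truth)

        stage = "extract"
        flanks = FlankSpec.from_template(template)
        records, rejections = extract_all(reads, flanks)
        outputs["records.tsv"] = _write_tsv(records_to_table(records), out / "records.tsv")
        outputs["rejections.tsv"] = _write_tsv(
            rejections_to_table(rejections), out / "rejections.tsv"
        )

        stage = "profile"
        reference = template.cdr3
        summaries = summarize(records, reference, config.q_cutoffs)
        _write_json({q: s.to_dict() for q, s in summaries.items()}, out / "profile_summary.json")
        outputs["profile_summary.json"] = len(summaries)

        per_reaction = []
        frame = records_to_table(records)
        frame["is_error"] = frame["cdr3_nt"] != reference
        for (sample, lane), g in frame.groupby(["sample_path", "lane"]):
            for q in config.q_cutoffs:
                sub = g[g["min_q"] >= q]
                per_reaction.append(
                    (
                        sample,
                        lane,
                        q,
                        len(sub),
                        int(sub["is_error"].sum()),
                        100.0 * sub["is_error"].mean() if len(sub) else np.nan,
                    )
                )
        per_reaction_df = pd.DataFrame(
            per_reaction,
            columns=["sample_path", "lane", "q_cutoff", "n_total", "n_error", "error_percent"],
        )
        outputs["per_reaction.tsv"] = _write_tsv(per_reaction_df, out / "per_reaction.tsv")

        matrix = substitution_matrix(records, reference, by=("lane", "direction"))
        outputs["substitution_matrix.tsv"] = _write_tsv(
            matrix.data, out / "substitution_matrix.tsv"
        )
        rates = per_nt_substitution_rates(matrix)
        outputs["per_nt_rates.tsv"] = _write_tsv(rates, out / "per_nt_rates.tsv")

        stage = "lane_effects"
        by_sample = substitution_matrix(records, reference, by=("lane", "sample_path"))
        cv = lane_cv(by_sample)
        anova = lane_anova(by_sample)
        _write_json(
            {
                "lane_cv_mean": cv.lane_cv_mean,
                "lane_cv_sd": cv.lane_cv_sd,
                "pooled_cv_mean": cv.pooled_cv_mean,
                "pooled_cv_sd": cv.pooled_cv_sd,
                "n_undefined_lane": cv.n_undefined_lane,
                "anova_fraction_significant": anova.fraction_significant,
                "anova_alpha": anova.alpha,
            },
            out / "lane_effects.json",
        )
        outputs["lane_effects.json"] = 1
        outputs["lane_anova.tsv"] = _write_tsv(anova.table, out / "lane_anova.tsv")

        stage = "models"
        comp_frames = []
        for q in (0, 30):
            if q in summaries and summaries[q].multi_error_freq:
                ct = complementation_test(
                    summaries[q].multi_error_freq,
                    n=len(reference),
                    m_values=range(2, 11) if q == 0 else range(2, 5),
                )
                ct.insert(0, "q_cutoff", q)
                comp_frames.append(ct)
        if comp_frames:
            outputs["complementation.tsv"] = _write_tsv(
                pd.concat(comp_frames, ignore_index=True), out / "complementation.tsv"
            )

        stage = "filter"
        table_q0 = build_clone_table(records)
        skew = direction_skew_screen(table_q0, exclude=(reference,))
        outputs["direction_skew.tsv"] = _write_tsv(skew.table, out / "direction_skew.tsv")
        _write_json(
            {"fraction_within": skew.fraction_within, "p_fwd": skew.p_fwd},
            out / "direction_skew.json",
        )
        outputs["direction_skew.json"] = 1

        cull_rows = []
        for q in (0, 30):
            passing, _ = phred_filter(records, q)
            if not passing:
                continue
            tbl = build_clone_table(passing)
            if reference not in tbl:
                continue
            for cutoff in config.mono_cull_cutoffs:
                report = cull_monoclonal(tbl, reference, cutoff)
                cull_rows.append(
                    (q, cutoff, len(report.culled), 100.0 * report.residual_error_fraction)
                )
        cull_df = pd.DataFrame(
            cull_rows, columns=["q_cutoff", "cutoff", "n_culled", "residual_error_percent"]
        )
        outputs["monoclonal_culling.tsv"] = _write_tsv(cull_df, out / "monoclonal_culling.tsv")
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "mode": "monoclonal_audit",
        "package_version": __version__,
        "seed": config.seed,
        "n_reads": config.n_reads,
        "cdr3_length": config.cdr3_length,
        "template": template.name,
        "n_records": len(records),
        "n_rejections": len(rejections),
        "q_cutoffs": list(config.q_cutoffs),
        "outputs": outputs,
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def run_polyclonal_filter(config: RunConfig) -> dict:
    """Clone tables, neighbor tallies and ACE for a (simulated) polyclonal repertoire."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, int] = {}

    stage = "simulate"
    try:
        templates = random_polyclonal_templates(
            config.n_clones, seed=config.seed, cdr3_length=config.cdr3_length
        )
        abundances = zipf_abundances(config.n_clones, config.zipf_exponent)
        model = config.model or default_error_model(templates[0], seed=config.seed, n_lanes=1)
        reads, truth = simulate_reads(
            templates, model, config.n_reads, n_lanes=1, seed=config.seed, abundances=abundances
        )
        if config.save_fastq:
            write_fastq(reads, out / "reads.fastq")
            write_truth(truth, out / "truth.tsv")
            outputs["reads.fastq"] = len(reads)

        stage = "extract"
        flanks = FlankSpec.from_template(templates[0])
        records, rejections = extract_all(reads, flanks)
        outputs["rejections.tsv"] = _write_tsv(
            rejections_to_table(rejections), out / "rejections.tsv"
        )

        stage = "filter"
        q30_records, _ = phred_filter(records, 30)
        table_q0 = build_clone_table(records)
        table_q30 = build_clone_table(q30_records)
        table_q0.to_tsv(out / "clones_q0.tsv")
        table_q30.to_tsv(out / "clones_q30.tsv")
        outputs["clones_q0.tsv"] = len(table_q0)
        outputs["clones_q30.tsv"] = len(table_q30)

        tally_rows = []
        reports = {}
        for q, tbl in ((0, table_q0), (30, table_q30)):
            rep = cull_polyclonal(tbl, cutoffs=config.poly_cutoff_grid)
            reports[q] = rep
            for cutoff, total in rep.per_cutoff_totals.items():
                tally_rows.append((q, cutoff, total))
        tallies = pd.DataFrame(tally_rows, columns=["q_cutoff", "cutoff", "total_tally"])
        outputs["neighbor_tallies.tsv"] = _write_tsv(tallies, out / "neighbor_tallies.tsv")

        stage = "diversity"
        report = richness_report(table_q0, table_q30, config.rare_cutoff)
        report["global_tally_q0"] = reports[0].global_tally
        report["global_tally_q30"] = reports[30].global_tally
        _write_json(report, out / "richness.json")
        outputs["richness.json"] = 1
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "mode": "polyclonal_filter",
        "package_version": __version__,
        "seed": config.seed,
        "n_reads": config.n_reads,
        "n_clones": config.n_clones,
        "zipf_exponent": config.zipf_exponent,
        "n_records": len(records),
        "n_rejections": len(rejections),
        "outputs": outputs,
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
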