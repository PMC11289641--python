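"""End-to-end orchestration: simulate -> quantify -> call/classify ->
decay -> compare, with per-stage logging and a JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rdio
from .decay import fit_decay_table, normalize_course, relative_half_life_table, stratify_by_sites
from .intervals import (
    PeakSet,
    assign_to_genes,
    binding_ability,
    call_peaks_windowed,
    classify_targets,
    intersect,
    metagene_distribution,
    overlap_fraction,
)
from .normalization import CountTable, calibrate_spikein, corrected_m6a_levels, cpm
from .stats import compare_many, wilcoxon_rank_sum
from .synthetic import (
    DECAY_TIMES,
    METH_SPIKE,
    SimConfig,
    simulate_clip_coverage,
    simulate_decay_course,
    simulate_genome,
    simulate_m6a_experiment,
    simulate_truth,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("readerdecay")


@dataclass
class PipelineConfig:
    """Thresholds, time points and bookkeeping for a full synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    fold_min: float = 2.0
    fdr_max: float = 0.05
    min_overlap: int = 1
    merge_gap: int = 50
    timepoints: Sequence[float] = DECAY_TIMES
    n_reps: int = 2
    ip_efficiency: Sequence[float] | None = None
    outdir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.validate()
        if self.fold_min <= 0 or self.fdr_max <= 0 or self.min_overlap <= 0:
            raise ValueError("thresholds must be positive")
        if 0 not in [float(t) for t in self.timepoints]:
            raise ValueError("timepoints must include 0")
        if self.n_reps < 1:
            raise ValueError("need at least one replicate")

    def hash(self) -> str:
        blob = json.dumps(
            {
                "sim": self.sim.to_dict(),
                "fold_min": self.fold_min,
                "fdr_max": self.fdr_max,
                "min_overlap": self.min_overlap,
                "merge_gap": self.merge_gap,
                "timepoints": [float(t) for t in self.timepoints],
                "n_reps": self.n_reps,
                "ip_efficiency": list(self.ip_efficiency) if self.ip_efficiency else None,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _call_stranded(tracks_ip, tracks_in, cfg: PipelineConfig, label: str) -> PeakSet:
    """Call peaks independently per strand and pool the results."""
    parts = []
    for strand in "+-":
        parts.append(
            call_peaks_windowed(
                tracks_ip[strand],
                tracks_in[strand],
                bin_size=cfg.sim.bin_size,
                fold_min=cfg.fold_min,
                fdr_max=cfg.fdr_max,
                merge_gap=cfg.merge_gap,
                strand=strand,
                label=label,
            )
        )
    a, b = parts
    return PeakSet(
        a.intervals + b.intervals,
        np.concatenate([a.enrichment, b.enrichment]),
        np.concatenate([a.fdr, b.fdr]),
        label,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic analysis and return the report dict.

    Stages: genome/truth simulation; m6A quantification (spike calibration
    and corrected levels); CLIP + m6A peak calling, target classification
    and metagene distribution; decay fitting per genotype with log2
    half-life contrasts stratified by binding-site count; Wilcoxon group
    comparisons. Deterministic given the simulation seed. Stage outputs are
    written under ``config.outdir`` when set.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.sim.seed, "stages": {}}

    def _stage(name: str, **counts) -> None:
        report["stages"][name] = counts
        log.info("stage %s: %s", name, counts)

    try:
        # --- simulate ---------------------------------------------------
        models, sizes = simulate_genome(config.sim)
        truth = simulate_truth(config.sim, models)
        _stage("simulate", genes=len(models),
               m6a_genes=int(truth.genes["m6a"].sum()),
               reader_targets=int(truth.genes["target"].sum()),
               true_sites=len(truth.sites))
        if outdir:
            rdio.write_gtf(models, outdir / "genes.gtf")
            truth.genes.to_csv(outdir / "truth.tsv", sep="\t")

        # --- m6A quantification -----------------------------------------
        eff = list(config.ip_efficiency) if config.ip_efficiency else [1.0] * config.n_reps
        m6a_table = simulate_m6a_experiment(
            config.sim, models, truth, n_reps=config.n_reps, ip_efficiency=eff
        )
        vals = cpm(m6a_table)
        roles = m6a_table.samples["role"]
        ip_samples = list(roles.index[roles == "IP"])
        input_samples = list(roles.index[roles == "input"])
        pairs = dict(zip(ip_samples, input_samples))
        calib = calibrate_spikein(vals, vals, METH_SPIKE, pairs, ip_samples)
        levels = corrected_m6a_levels(vals, vals, calib, pairs)
        _stage("m6a_quant", samples=len(m6a_table.sample_ids),
               mean_nf_reference=float(calib.nf.loc[ip_samples].mean()))
        if outdir:
            rdio.write_counts(m6a_table, outdir / "m6a_counts.tsv")
            levels.to_csv(outdir / "m6a_levels.tsv", sep="\t")

        # --- CLIP / m6A peaks and classification ------------------------
        clip_tracks, true_sites = simulate_clip_coverage(
            config.sim, models, truth, sizes, condition="mock"
        )
        clip_peaks = _call_stranded(
            clip_tracks["reader"], clip_tracks["input"], config, "reader_mock"
        )
        m6a_tracks, _ = simulate_clip_coverage(
            config.sim, models, truth, sizes, condition="mock",
            site_intervals=truth.m6a_regions, site_fold=config.sim.clip_site_fold,
            stream=7,
        )
        m6a_peaks = _call_stranded(
            m6a_tracks["reader"], m6a_tracks["input"], config, "m6a_mock"
        )
        mock_overlap = (
            overlap_fraction(clip_peaks, m6a_peaks, config.min_overlap)
            if len(clip_peaks)
            else float("nan")
        )
        pairs_ab, clip_hits = intersect(clip_peaks, m6a_peaks, config.min_overlap)
        clip_m6a_peaks = clip_peaks.subset(clip_hits)

        per_gene, site_counts, intergenic = assign_to_genes(
            clip_peaks, models, config.min_overlap
        )
        m6a_hit_genes, _, _ = assign_to_genes(clip_m6a_peaks, models, config.min_overlap)
        universe = [m.gene_id for m in models]
        classification = classify_targets(
            set(per_gene), set(m6a_hit_genes), universe, site_counts
        )
        metagene = metagene_distribution(clip_peaks, models, config.min_overlap)
        ability = binding_ability(
            _flatten(clip_tracks["reader"]), _flatten(clip_tracks["impaired"]),
            _flatten(clip_tracks["input"]), clip_peaks, config.sim.bin_size,
        )
        _stage("clip", clip_peaks=len(clip_peaks), m6a_peaks=len(m6a_peaks),
               clip_and_m6a_peaks=len(clip_m6a_peaks), intergenic_peaks=len(intergenic),
               targeted_genes=len(classification.reader_targets),
               m6a_targeted_genes=len(classification.reader_m6a_targets),
               non_targeted_genes=len(classification.non_targets))
        if outdir:
            rdio.write_bed(clip_peaks, outdir / "clip_peaks.bed")
            rdio.write_bed(m6a_peaks, outdir / "m6a_peaks.bed")

        # --- decay kinetics ----------------------------------------------
        fits = {}
        for geno in ("WT", "ect8"):
            course = simulate_decay_course(
                config.sim, truth, geno, n_reps=config.n_reps, times=config.timepoints
            )
            curves = normalize_course(course)
            fits[geno] = fit_decay_table(curves)
            if outdir:
                rdio.write_counts(course, outdir / f"decay_{geno}.tsv")
                fits[geno].to_csv(outdir / f"decay_fits_{geno}.tsv", sep="\t")
        ratios = relative_half_life_table(fits["ect8"], fits["WT"])
        strata = stratify_by_sites(ratios, classification)
        _stage("decay", fitted_WT=int((fits["WT"]["status"] == "ok").sum()),
               fitted_ect8=int((fits["ect8"]["status"] == "ok").sum()),
               ratio_genes=len(ratios))

        # --- group comparisons -------------------------------------------
        groups = {
            "m6a_targeted": ratios.loc[sorted(set(ratios.index)
                                              & classification.reader_m6a_targets)],
            "targeted": ratios.loc[sorted(set(ratios.index)
                                          & classification.reader_targets)],
            "non_targeted": ratios.loc[sorted(set(ratios.index)
                                              & classification.non_targets)],
        }
        comparisons = compare_many(groups, reference="non_targeted")
        strata_medians = {k: float(np.median(v)) if len(v) else float("nan")
                          for k, v in strata.items()}
        strata_n = {k: int(len(v)) for k, v in strata.items()}
        p_target = (
            wilcoxon_rank_sum(groups["m6a_targeted"], groups["non_targeted"])[1]
            if len(groups["m6a_targeted"]) and len(groups["non_targeted"])
            else float("nan")
        )
        _stage("compare", **{f"n_{k}": len(v) for k, v in groups.items()})

        report.update(
            {
                "mock_overlap_fraction": float(mock_overlap),
                "metagene_distribution": metagene,
                "median_binding_ability": float(np.median(ability)) if len(ability) else None,
                "stratum_medians_log2_halflife_ratio": strata_medians,
                "stratum_sizes": strata_n,
                "wilcoxon_p_m6a_targets_vs_non": float(p_target),
                "comparisons": {
                    g: {"pvalue": float(r["pvalue"]), "median": float(r["median"]),
                        "n": int(r["n"])}
                    for g, r in comparisons.iterrows()
                },
            }
        )
    except Exception as err:
        if outdir:
            (outdir / "FAILED").write_text(f"{type(err).__name__}: {err}\n")
        raise
    if outdir:
        rdio.write_report(report, outdir / "report.json")
    return report


def _flatten(stranded: dict) -> dict:
    """Pool strands into one track per chromosome (peak enrichment over an
    interval reads the matching strand's signal; strands share no bins with
    signal because genes are strand-exclusive in the simulation)."""
    out: dict[str, np.ndarray] = {}
    for strand in stranded:
        for chrom, arr in stranded[strand].items():
            out[chrom] = out.get(chrom, 0) + np.asarray(arr, float)
    return out
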