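"""End-to-end pipeline: simulate → score → call → compare → gsea → integrate.

Every stage is a pure function over in-memory objects; :func:`run_pipeline`
chains them and (optionally) writes each stage's tables into a run
directory together with a manifest (parameter hash, seed, versions), so a
rerun with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import assign_regions_to_tss, write_intervals
from .cmr import call_candidate_regions, filter_cmrs
from .compare import (
    SampleRoles,
    categorize_commonality,
    cmr_count_table,
    commonality_summary,
    extract_tdmrs,
    island_methylation_table,
    tss_profile,
    zone_table,
)
from .config import PipelineConfig
from .gsea import EnrichmentResult, permutation_test, testis_score, write_gmt
from .integrate import (
    assign_histone_state,
    compare_expression,
    gene_methylation_calls,
    methylation_by_state,
    transition_table,
)
from .scoring import estimate_fdr, null_scores, score_probes, standardize_arrays
from .simulate import SimulatedStudy, simulate_study

_FLOAT_FMT = "%.6g"


def _log(msg: str) -> None:
    print(f"[promethylome] {msg}", file=sys.stderr)


@dataclass
class PipelineResult:
    """All in-memory products of one pipeline run."""

    config: PipelineConfig
    study: SimulatedStudy
    score_table: pd.DataFrame            # probe meta + score_<sample> columns
    fdr_curves: dict[str, pd.DataFrame]  # per-sample threshold/FDR% tables
    cmrs: pd.DataFrame                   # with per-sample scores/states + category
    commonality: pd.DataFrame
    tdmrs: pd.DataFrame
    tdmr_contrast: pd.DataFrame
    profiles: dict[str, pd.DataFrame]
    cmr_counts: pd.DataFrame
    island_table: pd.DataFrame
    zones: pd.DataFrame
    ranked: pd.DataFrame
    gene_set: list[str]
    enrichment: EnrichmentResult | None
    histone_states: dict[str, pd.Series]
    meth_by_state: dict[str, pd.DataFrame]
    transitions: dict[tuple[str, str], pd.DataFrame]
    expression_by_zone: dict[str, dict] = field(default_factory=dict)

    @property
    def roles(self) -> SampleRoles:
        sim = self.config.sim
        return SampleRoles(
            es=sim.es_samples,
            germ_layers=sim.germ_layers,
            adult_somatic=sim.adult_somatic,
            sperm=sim.sperm_sample,
        )


def build_score_table(study: SimulatedStudy, cfg: PipelineConfig) -> pd.DataFrame:
    """Standardise the arrays and score every sample's probes."""
    std = standardize_arrays(study.intensities)
    table = study.annotation.probes.copy()
    for sample in cfg.sim.samples:
        tr = score_probes(std, sample, cfg.window_bp, cfg.trim_frac, cfg.min_probes)
        table[f"score_{sample}"] = tr["score"].to_numpy()
    return table


def build_fdr_curves(study: SimulatedStudy, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    std = standardize_arrays(study.intensities)
    curves = {}
    for sample in cfg.sim.samples:
        obs = score_probes(std, sample, cfg.window_bp, cfg.trim_frac, cfg.min_probes)
        nul = null_scores(std, sample, cfg.window_bp, cfg.trim_frac, cfg.min_probes)
        curves[sample] = estimate_fdr(obs, nul, cfg.fdr_thresholds).to_frame()
    return curves


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis on a freshly simulated study.

    When ``out_dir`` is given, every stage's tables are written there along
    with ``manifest.json``; outputs are byte-identical across reruns with
    the same configuration.
    """
    sim = cfg.sim
    samples = list(sim.samples)
    _log(f"simulate: {sim.n_genes} genes, {len(samples)} arrayed samples, seed {sim.seed}")
    study = simulate_study(sim)

    _log("score: standardise arrays, window scores, FDR curves")
    score_table = build_score_table(study, cfg)
    fdr_curves = build_fdr_curves(study, cfg)

    _log("call: candidate regions, CpG gate, tri-state calls")
    regions = call_candidate_regions(score_table, samples, cfg.call_threshold, cfg.max_gap_bp)
    cmrs = filter_cmrs(
        regions,
        score_table,
        samples,
        min_cpg_density=cfg.min_cpg_density,
        hc_threshold=cfg.hc_threshold,
        call_threshold=cfg.call_threshold,
        hypo_threshold=cfg.hypo_threshold,
        density_stat=cfg.region_density_stat,
    )
    _log(f"call: {len(regions)} candidate regions, {len(cmrs)} CMRs after gates")

    roles = SampleRoles(
        es=sim.es_samples,
        germ_layers=sim.germ_layers,
        adult_somatic=sim.adult_somatic,
        sperm=sim.sperm_sample,
    )
    _log("compare: profiles, tables, commonality, T-DMRs")
    categories = categorize_commonality(cmrs, roles)
    cmrs = cmrs.copy()
    cmrs["category"] = categories.to_numpy()
    commonality = commonality_summary(cmrs, categories, study.annotation.genes, cfg.core_zone)
    tdmrs, contrast = extract_tdmrs(cmrs, samples)
    profiles = {}
    for sample in samples:
        track = score_table[["offset"]].copy()
        track["score"] = score_table[f"score_{sample}"]
        profiles[sample] = tss_profile(
            track,
            threshold=cfg.call_threshold,
            bin_bp=cfg.profile_bin_bp,
            smooth_bp=cfg.profile_smooth_bp,
            span=sim.promoter_span,
        )
    cmr_counts = cmr_count_table(cmrs, samples, cfg.island_thresholds)
    island_table = island_methylation_table(
        cmrs, study.annotation.cpg_islands, samples, cfg.island_thresholds
    )
    zones = zone_table(cmrs, study.annotation.genes, samples, cfg.core_zone)

    _log("gsea: testis-specificity ranking, permutation test")
    ranked = testis_score(
        study.expression,
        somatic_columns=list(roles.somatic),
        testis_column=sim.testis_sample,
        floor=cfg.expr_floor,
    )
    assigned = assign_regions_to_tss(cmrs[["chrom", "start", "end"]], study.annotation.genes, cfg.core_zone)
    common_mask = (cmrs["category"] == "somatic_common").to_numpy()
    gene_set = sorted(set(assigned["gene_id"].to_numpy()[common_mask]))
    enrichment = None
    if 0 < len(gene_set) < len(ranked):
        enrichment = permutation_test(
            ranked,
            gene_set,
            n_permutations=cfg.n_perm,
            seed=cfg.seed,
            weight_exponent=cfg.gsea_weight,
        )
        _log(
            f"gsea: set of {len(gene_set)} commonly methylated genes, "
            f"NES={enrichment.nes:.2f}, p={enrichment.p_value:.4g}"
        )

    _log("integrate: histone states, cross-tabs, transitions, expression")
    genes = study.annotation.genes
    histone_states: dict[str, pd.Series] = {}
    meth_by_state = {}
    gene_calls = {}
    for sample in sim.histone_samples:
        k4 = study.histone_peaks[(sample, "K4")]
        k27 = study.histone_peaks[(sample, "K27")]
        histone_states[sample] = assign_histone_state(k4, k27, genes, cfg.histone_window)
        gene_calls[sample] = gene_methylation_calls(cmrs, genes, sample, cfg.core_promoter)
        meth_by_state[sample] = methylation_by_state(histone_states[sample], gene_calls[sample])
    transitions = {}
    hs = list(sim.histone_samples)
    for a, b in [(x, y) for i, x in enumerate(hs) for y in hs[i + 1 :]]:
        transitions[(a, b)] = transition_table(
            histone_states[a], histone_states[b], gene_calls[b]
        )

    expression_by_zone = {}
    for sample in sim.histone_samples:
        meth_mask = (cmrs[f"state_{sample}"] == "methylated").to_numpy()
        zones_for_sample = assigned["zone"].to_numpy()
        core_genes = sorted(set(assigned["gene_id"].to_numpy()[meth_mask & (zones_for_sample == "core")]))
        flank_genes = sorted(
            set(assigned["gene_id"].to_numpy()[meth_mask & (zones_for_sample != "core")]) - set(core_genes)
        )
        if len(core_genes) >= 2 and len(flank_genes) >= 2:
            expression_by_zone[sample] = compare_expression(
                study.expression, core_genes, flank_genes, sample
            )

    result = PipelineResult(
        config=cfg,
        study=study,
        score_table=score_table,
        fdr_curves=fdr_curves,
        cmrs=cmrs,
        commonality=commonality,
        tdmrs=tdmrs,
        tdmr_contrast=contrast,
        profiles=profiles,
        cmr_counts=cmr_counts,
        island_table=island_table,
        zones=zones,
        ranked=ranked,
        gene_set=gene_set,
        enrichment=enrichment,
        histone_states=histone_states,
        meth_by_state=meth_by_state,
        transitions=transitions,
        expression_by_zone=expression_by_zone,
    )
    if out_dir is not None:
        write_run(result, out_dir)
    return result


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def write_run(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every stage's outputs plus the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    study = result.study
    ann = study.annotation

    simdir = out / "simulate"
    simdir.mkdir(exist_ok=True)
    _tsv(ann.genes, simdir / "genes.tsv")
    write_intervals(ann.cpg_islands, simdir / "cpg_islands.bed", "BED")
    write_intervals(ann.icrs, simdir / "icrs.bed", "BED")
    _tsv(ann.probes, simdir / "probes.tsv")
    inten = pd.DataFrame(
        study.intensities.values, columns=study.intensities.arrays["name"].to_numpy()
    )
    inten.insert(0, "probe_id", study.intensities.probes["probe_id"].to_numpy())
    _tsv(inten, simdir / "intensities.tsv")
    _tsv(study.expression.rename_axis("gene_id"), simdir / "expression.tsv", index=True)
    _tsv(study.truth.regions, simdir / "truth_regions.tsv")
    _tsv(study.truth.levels.rename_axis("region_id"), simdir / "truth_levels.tsv", index=True)
    _tsv(study.histone_states.rename_axis("gene_id"), simdir / "histone_states.tsv", index=True)
    peakdir = simdir / "peaks"
    peakdir.mkdir(exist_ok=True)
    for (sample, mark), peaks in study.histone_peaks.items():
        write_intervals(peaks, peakdir / f"{sample}_{mark}.bed", "BED")

    scoredir = out / "scores"
    scoredir.mkdir(exist_ok=True)
    _tsv(result.score_table, scoredir / "score_table.tsv")
    for sample in cfg.sim.samples:
        bg = result.score_table[["chrom", "start", "end", f"score_{sample}"]].dropna()
        bg.to_csv(
            scoredir / f"{sample}.bedgraph",
            sep="\t",
            index=False,
            header=False,
            float_format=_FLOAT_FMT,
        )
        _tsv(result.fdr_curves[sample], scoredir / f"fdr_{sample}.tsv")

    cmrdir = out / "cmr"
    cmrdir.mkdir(exist_ok=True)
    _tsv(result.cmrs, cmrdir / "cmr.tsv")
    bed = result.cmrs[["chrom", "start", "end"]].copy()
    bed["name"] = [f"CMR{i:05d}" for i in range(len(bed))]
    write_intervals(bed, cmrdir / "cmr.bed", "BED")

    compdir = out / "compare"
    compdir.mkdir(exist_ok=True)
    _tsv(result.commonality, compdir / "commonality_summary.tsv")
    _tsv(result.tdmrs, compdir / "tdmr.tsv")
    _tsv(result.tdmr_contrast.rename_axis("meth_sample"), compdir / "tdmr_contrast.tsv", index=True)
    _tsv(result.cmr_counts, compdir / "cmr_counts.tsv", index=True)
    _tsv(result.island_table, compdir / "island_methylation.tsv", index=True)
    _tsv(result.zones, compdir / "zone_table.tsv", index=True)
    for sample, prof in result.profiles.items():
        _tsv(prof, compdir / f"tss_profile_{sample}.tsv")

    gseadir = out / "gsea"
    gseadir.mkdir(exist_ok=True)
    _tsv(result.ranked, gseadir / "ranked.tsv")
    write_gmt({"commonly_methylated": result.gene_set}, gseadir / "sets.gmt")
    if result.enrichment is not None:
        e = result.enrichment
        _tsv(
            pd.DataFrame(
                [
                    {
                        "set": "commonly_methylated",
                        "size": e.set_size,
                        "es": e.es,
                        "nes": e.nes,
                        "p_value": e.p_value,
                        "n_permutations": e.n_permutations,
                    }
                ]
            ),
            gseadir / "enrichment.tsv",
        )

    intdir = out / "integrate"
    intdir.mkdir(exist_ok=True)
    for sample, df in result.meth_by_state.items():
        _tsv(df, intdir / f"methylation_by_state_{sample}.tsv")
    for (a, b), df in result.transitions.items():
        _tsv(df, intdir / f"transitions_{a}_to_{b}.tsv")
    for sample, states in result.histone_states.items():
        _tsv(states.rename_axis("gene_id").to_frame(), intdir / f"histone_states_{sample}.tsv", index=True)
    if result.expression_by_zone:
        rows = []
        for sample, d in result.expression_by_zone.items():
            rows.append(
                {
                    "sample": sample,
                    "t": d["t"],
                    "p_value": d["p_value"],
                    "n_core": d["n_a"],
                    "n_flank": d["n_b"],
                    "median_core": d["a"]["median"],
                    "median_flank": d["b"]["median"],
                }
            )
        _tsv(pd.DataFrame(rows), intdir / "expression_core_vs_flank.tsv")

    manifest = {
        "package": "promethylome",
        "version": __version__,
        "param_hash": cfg.param_hash,
        "seed": cfg.seed,
        "sim_seed": cfg.sim.seed,
        "config": cfg.to_dict(),
        "n_cmrs": int(len(result.cmrs)),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    cfg.to_yaml(out / "config.yaml")
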