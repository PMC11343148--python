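"""Stage orchestration: simulate -> quantify -> score -> differential ->
integrate, with deterministic TSV/JSON outputs and a run manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import diffstats, integrate, quantify, scoring
from .config import PipelineConfig
from .io import (
    CountMatrix,
    QuantTable,
    lengths_of,
    read_gtf,
    read_tags_bed,
    transcript_gene_map,
    write_results,
    write_table,
)
from .simulate import GeneratorParams, SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    dataset: SyntheticDataset
    ribo_ip_tpm: dict[str, QuantTable]
    clip_tpm: dict[str, QuantTable]
    representative: pd.Series
    scores: scoring.ClipScoreTable
    tiers: pd.DataFrame
    cross_classes: pd.Series
    clip_diff: pd.DataFrame
    ribo_diff: pd.DataFrame
    ip_vs_input: pd.DataFrame
    enrichment: pd.DataFrame
    marker_report: pd.DataFrame
    bc_profile: quantify.BCProfile
    quadrants: pd.DataFrame
    summary: dict


def quantify_stage(
    clip_counts: CountMatrix,
    ribo_counts: CountMatrix,
    lengths: pd.Series,
    gene_map: pd.Series,
    config: PipelineConfig,
):
    """TPM for both assays, representative-transcript selection, and the
    CLIP restriction to the RiboTag-expressed universe."""
    ribo_all_ip = ribo_counts.select(assay="RiboTag-IP")
    ribo_tpm_all = quantify.compute_tpm(ribo_all_ip, lengths)
    representative = quantify.select_representative_transcripts(
        ribo_tpm_all, gene_map, config.expression_floor)
    clip_sel = quantify.restrict_clip_to_expressed(clip_counts, representative)

    selected = list(representative.values)
    ribo_ip_tpm, clip_tpm = {}, {}
    for cond in ("Control", "Opto"):
        ip = ribo_counts.select(assay="RiboTag-IP", condition=cond).restrict(selected)
        ribo_ip_tpm[cond] = quantify.compute_tpm(ip, lengths)
        cl = clip_sel.select(condition=cond)
        clip_tpm[cond] = quantify.compute_tpm(cl, lengths)
    return representative, clip_sel, ribo_ip_tpm, clip_tpm


def run_all(
    config: PipelineConfig,
    params: GeneratorParams | None = None,
    dataset: SyntheticDataset | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a (generated or supplied) dataset.

    When ``outdir`` is given, all result tables, a JSON summary and a
    run manifest are written there deterministically.
    """
    t0 = time.time()
    if dataset is None:
        params = params or GeneratorParams(seed=config.rng_seed)
        dataset = generate_dataset(params)
        log.info("simulate: %d transcripts [%.1fs]",
                 dataset.truth.shape[0], time.time() - t0)
    lengths = dataset.lengths
    gene_map = dataset.gene_map

    representative, clip_sel, ribo_ip_tpm, clip_tpm = quantify_stage(
        dataset.clip_counts, dataset.ribo_counts, lengths, gene_map, config)
    log.info("quantify: %d representative transcripts", representative.size)

    # biological complexity on the selected CLIP universe (gene level)
    bc = quantify.biological_complexity(
        clip_sel.select(condition="Control"), config.bc_min_tags,
        level="gene", gene_map=gene_map)

    # RiboTag IP vs Input differential (Control condition), enrichment, markers
    ribo_ctrl = dataset.ribo_counts.select(condition="Control")
    ipinput_design = ribo_ctrl.samples["assay"].astype("category").cat.set_categories(
        ["RiboTag-Input", "RiboTag-IP"])
    ip_vs_input = diffstats.nb_wald_test(ribo_ctrl, ipinput_design,
                                         alpha=config.ribo_diff_alpha)
    gene_ipinput = ip_vs_input.copy()
    gene_ipinput.index = gene_map.loc[gene_ipinput.index].values
    inp_tpm = quantify.compute_tpm(
        ribo_ctrl.select(assay="RiboTag-Input"), lengths)
    ip_tpm_ctrl = quantify.compute_tpm(
        ribo_ctrl.select(assay="RiboTag-IP"), lengths)
    enr = quantify.ribotag_enrichment(ip_tpm_ctrl, inp_tpm,
                                      pseudocount=config.pseudocount)
    enr.index = gene_map.loc[enr.index].values
    enr = enr.join(gene_ipinput[["p", "padj"]], how="left")
    marker_report = quantify.marker_panel_check(
        enr, concordance=config.marker_concordance)

    # CLIP scores, tiers, cross-condition classes
    scores = scoring.score_table(clip_tpm, ribo_ip_tpm, config)
    tiers = scoring.classify_targets(scores, config)
    cross = scoring.cross_condition_classes(tiers)
    log.info("score: %d transcripts scored", scores.means.shape[0])

    # differential FMRP binding (moderated t on per-replicate scores)
    clip_diff = diffstats.moderated_t(
        scores.scores["Control"], scores.scores["Opto"],
        alpha=config.clip_diff_alpha)

    # differential ribosome association (NB Wald, Opto vs Control on IP)
    ip_all = dataset.ribo_counts.select(assay="RiboTag-IP").restrict(
        list(representative.values))
    cond_design = ip_all.samples["condition"].astype("category").cat.set_categories(
        ["Control", "Opto"])
    ribo_diff = diffstats.nb_wald_test(ip_all, cond_design,
                                       alpha=config.ribo_diff_alpha)

    quadrants = integrate.quadrant_classify(clip_diff, ribo_diff, config)
    summary = integrate.quadrant_summary(quadrants)
    summary["n_stringent"] = {
        cond: int((tiers[cond] == "stringent").sum()) for cond in tiers.columns}
    summary["cross_classes"] = {
        k: int(v) for k, v in cross.value_counts().items()}
    summary["n_ribo_up"] = int((ribo_diff["direction"] == "up").sum())
    summary["n_ribo_down"] = int((ribo_diff["direction"] == "down").sum())
    summary["n_representative"] = int(representative.size)
    summary["n_bc_pass"] = int(len(bc.passing(min(config.bc_required,
                                                  bc.n_replicates))))
    summary["config_hash"] = config.config_hash()
    log.info("integrate: %s", summary["counts"])

    result = PipelineResult(
        dataset=dataset, ribo_ip_tpm=ribo_ip_tpm, clip_tpm=clip_tpm,
        representative=representative, scores=scores, tiers=tiers,
        cross_classes=cross, clip_diff=clip_diff, ribo_diff=ribo_diff,
        ip_vs_input=ip_vs_input, enrichment=enr, marker_report=marker_report,
        bc_profile=bc, quadrants=quadrants, summary=summary)
    if outdir is not None:
        write_outputs(result, config, Path(outdir))
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> dict:
    """Write every stage table plus summary JSON and a manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.rng_seed

    flat_scores = result.scores.scores.copy()
    flat_scores.columns = [f"score_{c}_{r}" for c, r in flat_scores.columns]
    for cond in result.scores.means.columns:
        flat_scores[f"mean_{cond}"] = result.scores.means[cond]
    fits = pd.DataFrame(
        [dataclasses.asdict(f) for f in result.scores.fits.values()])

    class_table = result.tiers.copy()
    class_table.columns = [f"tier_{c}" for c in class_table.columns]
    class_table["cross_class"] = result.cross_classes

    tables = {
        "regression_fits": fits.set_index(["condition", "replicate"]),
        "clip_scores": flat_scores,
        "target_classes": class_table,
        "clip_differential": result.clip_diff,
        "ribo_differential": result.ribo_diff,
        "ip_vs_input": result.ip_vs_input,
        "ribotag_enrichment": result.enrichment,
        "marker_panel": result.marker_report,
        "bc_support": result.bc_profile.support.to_frame("n_replicates_supporting"),
        "representative_transcripts": result.representative.to_frame(),
        "quadrants": result.quadrants,
        "truth": result.dataset.truth,
    }
    written = write_results(tables, outdir, config_hash=chash, seed=seed)
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config_hash": chash,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "outputs": {k: str(v.name) for k, v in written.items()},
    }
    digest = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
    manifest["manifest_hash"] = digest
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def annotate_stage(
    bed_paths: list[str | Path],
    gtf_path: str | Path,
    outdir: str | Path | None = None,
    site_merge_window: int = 0,
    allow_unstranded: bool = False,
) -> _annotate.BCDistribution:
    """Annotate genome-mapped tags from BED6 files against a GTF and
    tabulate the BC-stratified feature distribution."""
    models = read_gtf(gtf_path)
    tags = pd.concat(
        [read_tags_bed(p, allow_unstranded=allow_unstranded) for p in bed_paths],
        ignore_index=True)
    ann = _annotate.annotate_tags(tags, models)
    dist = _annotate.bc_distribution(ann, site_merge_window)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(ann, outdir / "tag_annotation.tsv", index=False)
        write_table(dist.fractions, outdir / "bc_feature_fractions.tsv")
    return dist
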