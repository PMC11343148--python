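"""Genomic annotation of CLIP tags and biological-complexity-stratified
feature distributions.

Each tag is assigned one feature label by maximal base overlap with
strand-matched annotation, with the fixed precedence
CDS > 3'UTR > 5'UTR > noncoding_exon > intron > intergenic breaking
ties. Intervals are 0-based half-open throughout.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import TranscriptModel

log = logging.getLogger(__name__)

FEATURE_PRECEDENCE = ("CDS", "3UTR", "5UTR", "noncoding_exon", "intron", "intergenic")


def _feature_trees(models: list[TranscriptModel]) -> dict[tuple[str, str, str], IntervalTree]:
    """(chrom, strand, label) -> interval tree of annotation intervals."""
    trees: dict[tuple[str, str, str], IntervalTree] = defaultdict(IntervalTree)
    for m in models:
        labeled = [f for f in m.features if f.label in ("CDS", "5UTR", "3UTR")]
        exons = sorted((f for f in m.features if f.label == "exon"),
                       key=lambda f: f.start)
        for f in labeled:
            trees[(m.chrom, m.strand, f.label)].addi(f.start, f.end, m.gene_id)
        if not labeled:
            # transcript without CDS/UTR structure: exons are noncoding
            for f in exons:
                trees[(m.chrom, m.strand, "noncoding_exon")].addi(f.start, f.end, m.gene_id)
        # introns: gaps between consecutive exons
        for a, b in zip(exons, exons[1:]):
            if a.end < b.start:
                trees[(m.chrom, m.strand, "intron")].addi(a.end, b.start, m.gene_id)
    return dict(trees)


def annotate_tags(tags: pd.DataFrame, models: list[TranscriptModel]) -> pd.DataFrame:
    """Assign a feature label and gene to every tag.

    ``tags`` needs chrom/start/end/strand (+ replicate). A tag on a
    chromosome absent from the models is labeled intergenic (counted in
    a warning).
    """
    trees = _feature_trees(models)
    known_chroms = {c for c, _, _ in trees}
    labels = np.empty(len(tags), dtype=object)
    genes = np.empty(len(tags), dtype=object)
    n_unknown_chrom = 0
    rows = tags[["chrom", "start", "end", "strand"]].itertuples(index=False)
    for i, (chrom, start, end, strand) in enumerate(rows):
        if chrom not in known_chroms:
            n_unknown_chrom += 1
            labels[i], genes[i] = "intergenic", ""
            continue
        best_label, best_gene, best_ov = "intergenic", "", 0
        for label in FEATURE_PRECEDENCE[:-1]:
            tree = trees.get((chrom, strand, label))
            if tree is None:
                continue
            ov_len = 0
            ov_gene = ""
            for iv in tree.overlap(start, end):
                ov = min(end, iv.end) - max(start, iv.begin)
                if ov > ov_len:
                    ov_len, ov_gene = ov, iv.data
            # strict > keeps the precedence order on overlap ties
            if ov_len > best_ov:
                best_label, best_gene, best_ov = label, ov_gene, ov_len
        labels[i], genes[i] = best_label, best_gene
    if n_unknown_chrom:
        log.warning("%d tag(s) on chromosomes absent from the models "
                    "labeled intergenic", n_unknown_chrom)
    out = tags.copy()
    out["feature"] = labels
    out["gene_id"] = genes
    return out


@dataclass
class BCDistribution:
    """Feature fractions of tag sites at increasing replicate support."""

    fractions: pd.DataFrame   # rows: BC floor 1..N; columns: feature labels
    site_counts: pd.Series    # BC floor -> number of sites


def bc_distribution(
    annotated: pd.DataFrame,
    site_merge_window: int = 0,
) -> BCDistribution:
    """Collapse tags to sites and tabulate feature fractions per BC floor.

    A site is a (chrom, strand, 5'-start) triple; starts within
    ``site_merge_window`` nt collapse together (0 = exact match). A
    site's biological complexity is the number of replicates containing
    it; the sets at floors BC >= 1, 2, ... are nested by construction.
    """
    if "replicate" not in annotated.columns or "feature" not in annotated.columns:
        raise ValueError("bc_distribution needs annotated tags with replicate labels")
    n_reps = annotated["replicate"].nunique()
    if n_reps < 2:
        log.warning("single replicate: biological complexity is trivially 1")
    df = annotated.copy()
    five_prime = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    if site_merge_window > 0:
        five_prime = (five_prime // (site_merge_window + 1)) * (site_merge_window + 1)
    df["site"] = list(zip(df["chrom"], df["strand"], five_prime))
    per_site = df.groupby("site").agg(
        bc=("replicate", "nunique"),
        feature=("feature", "first"),
    )
    rows, counts = [], {}
    for floor in range(1, n_reps + 1):
        sub = per_site[per_site["bc"] >= floor]
        counts[floor] = len(sub)
        frac = sub["feature"].value_counts(normalize=True)
        rows.append(frac.reindex(FEATURE_PRECEDENCE, fill_value=0.0))
    fractions = pd.DataFrame(rows, index=pd.Index(range(1, n_reps + 1), name="bc_floor"))
    return BCDistribution(fractions, pd.Series(counts, name="n_sites"))
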